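"""Model/Results interface for the FJC elastomer fit.

:class:`ForceExtensionModel` is built from per-force pulling summaries (a
DataFrame or an assembled :class:`~elastochain.curves.ForceExtensionCurve`)
plus, optionally, the zero-force replicate statistics. Its :meth:`fit`
returns an :class:`ElastomerResults` holding the fitted link length, derived
chain quantities and a ``summary()`` table.

Example
-------
>>> model = ForceExtensionModel.from_dataframe(df, fragment=MASP1A)
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .curves import (
    ElastomerReport,
    ForceExtensionCurve,
    analyze_fragment,
    build_curve,
    fit_link_length_joint,
    normalize_curve,
    theoretical_curve,
)
from .fjc import ChainModel
from .fragments import FragmentSpec
from .trajectory import EquilibriumSummary

__all__ = ["ForceExtensionModel", "ElastomerResults"]


class ForceExtensionModel:
    """FJC elastomer model of a chain fragment under constant-force pulling.

    Parameters
    ----------
    curve : ForceExtensionCurve
        Validated per-force summaries for one fragment.
    equilibrium : EquilibriumSummary, optional
        Zero-force replicate statistics; required for measured hidden-length
        quantities in the results.
    temperature : float
        Simulation temperature in K.
    """

    def __init__(
        self,
        curve: ForceExtensionCurve,
        equilibrium: Optional[EquilibriumSummary] = None,
        temperature: float = 298.0,
    ) -> None:
        self.curve = curve
        self.equilibrium = equilibrium
        self.temperature = float(temperature)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        fragment: FragmentSpec,
        equilibrium: Optional[EquilibriumSummary] = None,
        temperature: float = 298.0,
    ) -> "ForceExtensionModel":
        """Build from a DataFrame with columns force_pN, mean_L_A, sd_L_A, n_frames."""
        return cls(build_curve(data, fragment), equilibrium=equilibrium, temperature=temperature)

    @property
    def fragment(self) -> FragmentSpec:
        return self.curve.fragment

    def fit(
        self,
        bounds: Tuple[float, float] = (2.0, 20.0),
        link_length: Optional[float] = None,
    ) -> "ElastomerResults":
        """Fit the link length (or pin it with ``link_length``) and derive the report."""
        report = analyze_fragment(
            self.curve,
            self.equilibrium,
            temperature=self.temperature,
            link_length=link_length,
            bounds=bounds,
        )
        return ElastomerResults(self, report)

    @staticmethod
    def fit_joint(
        models: Sequence["ForceExtensionModel"],
        bounds: Tuple[float, float] = (2.0, 20.0),
    ) -> Tuple["ElastomerResults", ...]:
        """Fit one shared link length across several fragments' curves.

        Residuals are pooled over all curves; each returned results object
        carries the common ``a_fit`` with its own fragment's derived
        quantities.
        """
        temps = {m.temperature for m in models}
        if len(temps) != 1:
            raise ValueError("joint fit requires a common temperature")
        fit = fit_link_length_joint(
            [m.curve for m in models], temperature=temps.pop(), bounds=bounds
        )
        return tuple(m.fit(link_length=fit.a_fit) for m in models)

    def predict(self, forces: Sequence[float], link_length: float) -> np.ndarray:
        """Mean extensions (Å) predicted by the FJC closed form at the given forces."""
        from .fjc import langevin
        from .constants import thermal_energy

        f = np.asarray(forces, dtype=float)
        kT = thermal_energy(self.temperature)
        return self.fragment.l_max * langevin(f * link_length / kT)


class ElastomerResults:
    """Fitted FJC elastomer characterisation; see :class:`ElastomerReport` for fields."""

    def __init__(self, model: ForceExtensionModel, report: ElastomerReport) -> None:
        self.model = model
        self.report = report

    @property
    def a_fit(self) -> float:
        """Fitted (or pinned) link length in Å."""
        return self.report.a_fit

    @property
    def n_links(self) -> int:
        return self.report.n_links

    @property
    def chain_model(self) -> ChainModel:
        return ChainModel(
            n_links=self.report.n_links,
            link_length=self.report.a_fit,
            temperature=self.report.temperature,
        )

    def fittedvalues(self) -> np.ndarray:
        """Model extensions at the curve's nonzero forces."""
        forces = self.model.curve.forces
        return self.model.predict(forces[forces > 0], self.a_fit)

    def resid(self) -> np.ndarray:
        """Extension residuals (observed − model) at nonzero forces, Å."""
        forces = self.model.curve.forces
        mask = forces > 0
        return self.model.curve.mean_l[mask] - self.fittedvalues()

    def theoretical_overlay(self, n_grid: int = 200) -> pd.DataFrame:
        """Theoretical F vs L/L_max curve of the fitted chain for plotting."""
        grid = np.linspace(0.0, 0.995, n_grid)
        pairs = theoretical_curve(self.chain_model, grid)
        return pd.DataFrame(pairs, columns=["fraction", "force_pN"])

    def normalized_data(self) -> pd.DataFrame:
        return normalize_curve(self.model.curve)

    def to_frame(self) -> pd.DataFrame:
        """One-row DataFrame of the report fields (CSV-ready)."""
        r = self.report
        return pd.DataFrame(
            [
                {
                    "fragment": r.fragment_name,
                    "a_fit_A": r.a_fit,
                    "n_links": r.n_links,
                    "n_links_exact": r.n_links_exact,
                    "l_max_A": r.l_max,
                    "l_eq_measured_A": r.l_eq_measured,
                    "l_eq_theory_A": r.l_eq_theory,
                    "l_hidden_A": r.l_hidden,
                    "hidden_ratio": r.hidden_ratio,
                    "f_at_lmax_pN": r.f_at_lmax,
                    "fit_residual_A": r.fit_residual,
                    "temperature_K": r.temperature,
                }
            ]
        )

    def summary(self) -> str:
        """Human-readable report table."""
        r = self.report
        rows = [
            ("link length a (fit)", f"{r.a_fit:.3f} Å"),
            ("number of links N", f"{r.n_links} (L_max/a = {r.n_links_exact:.2f})"),
            ("contour length L_max", f"{r.l_max:.1f} Å"),
            ("equilibrium <L> (FJC, √N·a)", f"{r.l_eq_theory:.1f} Å"),
        ]
        if r.l_eq_measured is not None:
            rows += [
                ("equilibrium <L> (measured)", f"{r.l_eq_measured:.1f} Å"),
                ("hidden length L_hl", f"{r.l_hidden:.1f} Å"),
                ("hidden-length ratio L_hl/<L>", f"{r.hidden_ratio:.2f}"),
            ]
        if r.f_at_lmax is not None:
            rows.append(("force reaching L_max", f"{r.f_at_lmax:.0f} pN"))
        if r.fit_residual is not None:
            rows.append(("weighted RMS extension residual", f"{r.fit_residual:.2f} Å"))
        rows.append(("temperature", f"{r.temperature:.0f} K"))
        width = max(len(k) for k, _ in rows)
        title = f"FJC elastomer fit — {r.fragment_name}"
        bar = "=" * (width + 24)
        lines = [bar, title.center(width + 24), bar]
        lines += [f"{k.ljust(width)}  {v}" for k, v in rows]
        lines.append(bar)
        return "\n".join(lines)

    def plot(self, normalized: bool = True, ax=None):
        """Force–extension data with the fitted theoretical overlay."""
        from .plotting import plot_force_extension

        return plot_force_extension(self, normalized=normalized, ax=ax)

    def __repr__(self) -> str:
        r = self.report
        return (
            f"<ElastomerResults {r.fragment_name}: a={r.a_fit:.2f} Å, "
            f"N={r.n_links}, L_max={r.l_max} Å>"
        )
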