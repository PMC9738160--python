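"""Force–extension curves and the FJC link-length fit.

A curve is a set of per-force summaries (F in pN, mean L in Å, SD, frame
count) for one fragment. The link length ``a`` is fitted by weighted least
squares in the extension domain — the pulling protocol controls force and
measures length — minimising

    Σᵢ wᵢ (Lᵢ − L_max·L(Fᵢ·a/(k_B·T)))²   over a,

with wᵢ = 1/sdᵢ² when all SDs are positive, else unit weights. The zero-force
point is excluded: the model's mean end-to-end *vector* vanishes at F = 0
while the measured zero-force ⟨L⟩ is a magnitude mean. Minimisation is a
coarse grid (0.05 Å) followed by bounded refinement to 1e-4 Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .constants import thermal_energy
from .fjc import (
    ChainModel,
    equilibrium_end_to_end,
    fjc_force,
    hidden_length,
    hidden_length_ratio,
    langevin,
    link_count,
    link_count_exact,
)
from .fragments import FragmentSpec
from .trajectory import EquilibriumSummary

__all__ = [
    "ForceExtensionPoint",
    "ForceExtensionCurve",
    "ElastomerReport",
    "LinkLengthFit",
    "build_curve",
    "normalize_curve",
    "fit_link_length",
    "fit_link_length_joint",
    "analyze_fragment",
    "theoretical_curve",
]

#: a curve point may exceed L_max by at most this relative tolerance
_LMAX_TOLERANCE = 0.02

#: fraction of L_max at which the chain counts as fully extended
_FULL_EXTENSION_FRACTION = 0.995


@dataclass(frozen=True)
class ForceExtensionPoint:
    """One per-force summary: force (pN), mean L (Å), SD of L (Å), frame count."""

    force: float
    mean_l: float
    sd_l: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.force < 0 or self.mean_l < 0 or self.sd_l < 0 or self.n_frames < 1:
            raise ValueError(f"invalid force–extension point: {self}")


@dataclass(frozen=True)
class ForceExtensionCurve:
    """Per-force summaries for one fragment, strictly ascending in force."""

    fragment: FragmentSpec
    points: Tuple[ForceExtensionPoint, ...]

    def __post_init__(self) -> None:
        forces = [p.force for p in self.points]
        if any(b <= a for a, b in zip(forces, forces[1:])):
            raise ValueError("curve forces must be strictly increasing")
        limit = self.fragment.l_max * (1.0 + _LMAX_TOLERANCE)
        for p in self.points:
            if p.mean_l > limit:
                raise ValueError(
                    f"mean L={p.mean_l} Å exceeds L_max={self.fragment.l_max} Å "
                    f"beyond the {_LMAX_TOLERANCE:.0%} tolerance"
                )

    @property
    def forces(self) -> np.ndarray:
        return np.array([p.force for p in self.points])

    @property
    def mean_l(self) -> np.ndarray:
        return np.array([p.mean_l for p in self.points])

    @property
    def sd_l(self) -> np.ndarray:
        return np.array([p.sd_l for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "force_pN": self.forces,
                "mean_L_A": self.mean_l,
                "sd_L_A": self.sd_l,
                "n_frames": [p.n_frames for p in self.points],
            }
        )


class LinkLengthFit(NamedTuple):
    a_fit: float
    fit_residual: float
    at_boundary: bool


@dataclass(frozen=True)
class ElastomerReport:
    """Full elastomer characterisation of one fragment.

    ``l_eq_measured`` is the zero-force grand mean from the replicate
    trajectories; ``l_eq_theory`` the FJC prediction √N·a; the hidden length
    and its ratio use the (unrounded) measured value. ``f_at_lmax`` is the
    smallest ladder force whose mean extension reaches 99.5% of L_max, if
    observed.
    """

    fragment_name: str
    a_fit: float
    n_links: int
    n_links_exact: float
    l_max: float
    l_eq_measured: Optional[float]
    l_eq_theory: float
    l_hidden: Optional[float]
    hidden_ratio: Optional[float]
    f_at_lmax: Optional[float]
    fit_residual: Optional[float]
    temperature: float


CurveRecords = Union[pd.DataFrame, Sequence[Tuple[float, float, float, int]]]


def build_curve(summaries: CurveRecords, fragment: FragmentSpec) -> ForceExtensionCurve:
    """Assemble a validated, force-sorted curve from per-force summary records.

    ``summaries`` is a DataFrame with columns force_pN/mean_L_A/sd_L_A/n_frames
    or a sequence of (force, mean, sd, n) tuples. Duplicate force levels are
    merged by pooled mean and pooled (within + between) variance.
    """
    if isinstance(summaries, pd.DataFrame):
        records = [
            (row.force_pN, row.mean_L_A, row.sd_L_A, int(row.n_frames))
            for row in summaries.itertuples()
        ]
    else:
        records = [(f, m, s, int(n)) for f, m, s, n in summaries]
    if len({f for f, *_ in records}) < 2:
        raise ValueError("need at least 2 distinct force levels")
    merged: dict = {}
    for f, m, s, n in records:
        merged.setdefault(float(f), []).append((m, s, n))
    points: List[ForceExtensionPoint] = []
    for f in sorted(merged):
        group = merged[f]
        n_tot = sum(n for _, _, n in group)
        mean = sum(m * n for m, _, n in group) / n_tot
        # pooled variance: within-group + between-group contributions
        ss = sum((n - 1) * s**2 + n * (m - mean) ** 2 for m, s, n in group)
        sd = np.sqrt(ss / (n_tot - 1)) if n_tot > 1 else group[0][1]
        points.append(ForceExtensionPoint(f, float(mean), float(sd), n_tot))
    return ForceExtensionCurve(fragment=fragment, points=tuple(points))


def normalize_curve(curve: ForceExtensionCurve) -> pd.DataFrame:
    """Fractional-extension view of the curve: F vs L/L_max.

    Returns a DataFrame with columns ``force_pN``, ``fraction``,
    ``sd_fraction``; multiplying by L_max recovers the input exactly.
    """
    l_max = curve.fragment.l_max
    return pd.DataFrame(
        {
            "force_pN": curve.forces,
            "fraction": curve.mean_l / l_max,
            "sd_fraction": curve.sd_l / l_max,
        }
    )


def _fit_objective(
    a: float,
    curves: Sequence[ForceExtensionCurve],
    temperature: float,
) -> Tuple[float, float]:
    """(weighted SSR, weighted RMS residual) of the FJC extension model at link length a."""
    kT = thermal_energy(temperature)
    ssr = 0.0
    wsum = 0.0
    for curve in curves:
        mask = curve.forces > 0
        f = curve.forces[mask]
        l_obs = curve.mean_l[mask]
        sd = curve.sd_l[mask]
        w = 1.0 / sd**2 if np.all(sd > 0) else np.ones_like(f)
        l_pred = curve.fragment.l_max * langevin(f * a / kT)
        ssr += float(np.sum(w * (l_obs - l_pred) ** 2))
        wsum += float(np.sum(w))
    return ssr, np.sqrt(ssr / wsum)


def fit_link_length(
    curve: ForceExtensionCurve,
    temperature: float = 298.0,
    bounds: Tuple[float, float] = (2.0, 20.0),
) -> LinkLengthFit:
    """Weighted least-squares FJC link length for one curve (see module docstring)."""
    return fit_link_length_joint([curve], temperature=temperature, bounds=bounds)


def fit_link_length_joint(
    curves: Sequence[ForceExtensionCurve],
    temperature: float = 298.0,
    bounds: Tuple[float, float] = (2.0, 20.0),
) -> LinkLengthFit:
    """Single shared link length fitted to several curves by pooling residuals."""
    a_lo, a_hi = bounds
    if not (0 < a_lo < a_hi):
        raise ValueError(f"bounds must satisfy 0 < a_lo < a_hi, got {bounds}")
    for curve in curves:
        if int(np.sum(curve.forces > 0)) < 3:
            raise ValueError("need at least 3 points with force > 0 to fit")
    grid = np.arange(a_lo, a_hi + 0.05, 0.05)
    ssr = [_fit_objective(a, curves, temperature)[0] for a in grid]
    best = grid[int(np.argmin(ssr))]
    lo = max(a_lo, best - 0.05)
    hi = min(a_hi, best + 0.05)
    res = minimize_scalar(
        lambda a: _fit_objective(a, curves, temperature)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-5},
    )
    a_fit = float(res.x)
    residual = _fit_objective(a_fit, curves, temperature)[1]
    at_boundary = a_fit - a_lo < 1e-3 or a_hi - a_fit < 1e-3
    if at_boundary:
        warnings.warn(
            f"fitted link length a={a_fit:.4f} Å lies at a bound of {bounds}",
            stacklevel=2,
        )
    return LinkLengthFit(a_fit=a_fit, fit_residual=float(residual), at_boundary=at_boundary)


def analyze_fragment(
    curve: ForceExtensionCurve,
    equilibrium: Optional[EquilibriumSummary],
    temperature: float = 298.0,
    link_length: Optional[float] = None,
    bounds: Tuple[float, float] = (2.0, 20.0),
) -> ElastomerReport:
    """Full elastomer report for one fragment.

    The link length is fitted from the curve unless ``link_length`` pins it.
    The hidden length uses the *unrounded* measured zero-force grand mean;
    without an equilibrium summary the measured-equilibrium fields are None.
    """
    if link_length is None:
        fit = fit_link_length(curve, temperature=temperature, bounds=bounds)
        a_fit, residual = fit.a_fit, fit.fit_residual
    else:
        a_fit = float(link_length)
        residual = _fit_objective(a_fit, [curve], temperature)[1]
    l_max = curve.fragment.l_max
    n = link_count(l_max, a_fit)
    model = ChainModel(n_links=n, link_length=a_fit, temperature=temperature)
    l_eq_theory = equilibrium_end_to_end(model)
    l_eq_measured = l_hidden = ratio = None
    if equilibrium is not None:
        l_eq_measured = equilibrium.grand_mean
        l_hidden = hidden_length(l_max, l_eq_measured)
        ratio = hidden_length_ratio(l_hidden, l_eq_measured)
    f_at_lmax = None
    reached = curve.forces[curve.mean_l >= _FULL_EXTENSION_FRACTION * l_max]
    if len(reached):
        f_at_lmax = float(reached[0])
    return ElastomerReport(
        fragment_name=curve.fragment.name,
        a_fit=a_fit,
        n_links=n,
        n_links_exact=link_count_exact(l_max, a_fit),
        l_max=l_max,
        l_eq_measured=l_eq_measured,
        l_eq_theory=l_eq_theory,
        l_hidden=l_hidden,
        hidden_ratio=ratio,
        f_at_lmax=f_at_lmax,
        fit_residual=residual,
        temperature=temperature,
    )


def theoretical_curve(
    model: ChainModel, fractional_grid: Sequence[float]
) -> List[Tuple[float, float]]:
    """FJC force law on a fractional-extension grid: (L/L_max, F in pN) pairs."""
    out = []
    for frac in fractional_grid:
        if not 0 <= frac < 1:
            raise ValueError(f"fractional extension must be in [0, 1), got {frac}")
        out.append((float(frac), fjc_force(frac * model.contour_length, model)))
    return out
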