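"""Freely-jointed-chain (FJC) elasticity.

The FJC idealises a polymer as ``N`` rigid links of length ``a`` that rotate
freely at the joints. Its force–extension law is

    F = (k_B T / a) · L⁻¹(L / (N a))

where ``L⁻¹`` is the inverse of the Langevin function
``L(x) = coth(x) − 1/x`` and ``L`` the end-to-end distance. At zero force the
root-mean-square end-to-end distance of the chain is ``√N · a`` (random-walk
statistics), the contour length is ``L_max = N·a``, and the difference
``L_hl = L_max − ⟨L⟩`` is the *hidden length*: chain contour that bears no
load at equilibrium but can be recruited on stretching.

Units: forces in pN, lengths in Å, temperatures in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .constants import thermal_energy

__all__ = [
    "ChainModel",
    "DerivedQuantities",
    "FullExtensionError",
    "langevin",
    "inverse_langevin",
    "fjc_force",
    "fjc_extension",
    "equilibrium_end_to_end",
    "link_count",
    "link_count_exact",
    "hidden_length",
    "hidden_length_ratio",
]

#: below this |x| the Taylor series x/3 − x³/45 replaces coth(x) − 1/x
_SERIES_THRESHOLD = 1e-4


class FullExtensionError(ValueError):
    """The chain is at (or beyond) full extension, where the FJC force diverges."""


@dataclass(frozen=True)
class ChainModel:
    """An ideal chain of ``n_links`` rigid links of ``link_length`` Å at ``temperature`` K."""

    n_links: int
    link_length: float
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.n_links < 1 or int(self.n_links) != self.n_links:
            raise ValueError(f"n_links must be a positive integer, got {self.n_links}")
        if not (self.link_length > 0 and math.isfinite(self.link_length)):
            raise ValueError(f"link_length must be positive and finite, got {self.link_length}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def contour_length(self) -> float:
        """Maximum end-to-end distance N·a in Å."""
        return self.n_links * self.link_length

    @property
    def kT(self) -> float:
        """Thermal energy k_B·T in pN·Å."""
        return thermal_energy(self.temperature)


@dataclass(frozen=True)
class DerivedQuantities:
    """Lengths derived from an FJC fit: contour, equilibrium, hidden length and its ratio."""

    l_max: float
    l_eq_theory: float
    l_hidden: float
    hidden_ratio: float

    def __post_init__(self) -> None:
        if not 0 <= self.l_eq_theory <= self.l_max:
            raise ValueError(
                f"l_eq_theory={self.l_eq_theory} outside [0, l_max={self.l_max}]"
            )
        if self.l_hidden < 0:
            raise ValueError(f"l_hidden must be >= 0, got {self.l_hidden}")


def langevin(x):
    """Langevin function L(x) = coth(x) − 1/x.

    Odd, strictly increasing, bounded in (−1, 1). Near zero the closed form
    suffers catastrophic cancellation, so |x| < 1e-4 is evaluated by the
    Taylor series x/3 − x³/45. Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SERIES_THRESHOLD
    # avoid 0/0 in the masked branch
    safe = np.where(small, 1.0, x)
    exact = 1.0 / np.tanh(safe) - 1.0 / safe
    series = x / 3.0 - x**3 / 45.0
    out = np.where(small, series, exact)
    return float(out) if out.ndim == 0 else out


def _langevin_scalar(x: float) -> float:
    if abs(x) < _SERIES_THRESHOLD:
        return x / 3.0 - x**3 / 45.0
    return 1.0 / math.tanh(x) - 1.0 / x


def inverse_langevin(y: float, tol: float = 1e-10) -> float:
    """Inverse Langevin function: the x with coth(x) − 1/x = y, for |y| < 1.

    Root-bracketing (Brent) around a Padé initial guess; the result satisfies
    |langevin(x) − y| ≤ tol.

    Raises
    ------
    FullExtensionError
        If |y| >= 1: the FJC force diverges at full extension.
    """
    y = float(y)
    if not abs(y) < 1.0:
        raise FullExtensionError(
            f"inverse Langevin is defined only for |y| < 1, got {y} (full extension)"
        )
    if y == 0.0:
        return 0.0
    sign = 1.0 if y > 0 else -1.0
    ay = abs(y)
    if ay < 1e-6:
        # series inversion of x/3 − x³/45; residual O(y³) is far below tol
        return sign * (3.0 * ay + 1.8 * ay**3)
    # Padé guess x ~ y(3 − y²)/(1 − y²), exact to O(y³) and ~1/(1−y) near 1
    guess = ay * (3.0 - ay * ay) / (1.0 - ay * ay)
    hi = max(2.0 * guess, 1.0)
    while _langevin_scalar(hi) < ay:  # expand bracket; terminates since L → 1
        hi *= 2.0
    x = brentq(lambda t: _langevin_scalar(t) - ay, 1e-12, hi, xtol=1e-14, rtol=8.9e-16)
    # polish to the requested residual tolerance with Newton (L'(x) = 1/x² − csch²x)
    for _ in range(3):
        r = _langevin_scalar(x) - ay
        if abs(r) <= tol:
            break
        d = 1.0 / x**2 - 1.0 / math.sinh(x) ** 2 if x < 350 else 1.0 / x**2
        x -= r / d
    return sign * x


def fjc_force(l_dist: float, model: ChainModel) -> float:
    """FJC restoring force (pN) at end-to-end distance ``l_dist`` (Å).

    F = (k_B·T/a)·L⁻¹(L/(N·a)); zero at L = 0, diverging as L → N·a
    (elastomeric stiffening — the slope never decreases).
    """
    if l_dist < 0:
        raise ValueError(f"l_dist must be >= 0, got {l_dist}")
    if l_dist >= model.contour_length:
        raise FullExtensionError(
            f"l_dist={l_dist} Å >= contour length {model.contour_length} Å; "
            "the chain cannot extend beyond N·a"
        )
    return model.kT / model.link_length * inverse_langevin(l_dist / model.contour_length)


def fjc_extension(force: float, model: ChainModel) -> float:
    """Mean end-to-end extension (Å) of the FJC under constant force (pN).

    The closed form N·a·L(F·a/(k_B·T)): zero at F = 0, saturating at N·a.
    Exact inverse of :func:`fjc_force`.
    """
    if force < 0:
        raise ValueError(f"force must be >= 0, got {force}")
    return model.contour_length * langevin(force * model.link_length / model.kT)


def equilibrium_end_to_end(model: ChainModel) -> float:
    """Equilibrium (zero-force) end-to-end distance √N·a in Å.

    This is the random-walk root-mean-square end-to-end distance,
    ⟨L²⟩ = N·a².
    """
    return math.sqrt(model.n_links) * model.link_length


def link_count(l_max: float, a: float) -> int:
    """Number of links N = L_max/a, rounded to the nearest integer (ties away from zero)."""
    q = link_count_exact(l_max, a)
    return int(math.floor(q + 0.5))


def link_count_exact(l_max: float, a: float) -> float:
    """Unrounded link-count quotient L_max/a (diagnostic companion to :func:`link_count`)."""
    if l_max <= 0 or a <= 0:
        raise ValueError(f"l_max and a must be positive, got l_max={l_max}, a={a}")
    return l_max / a


def hidden_length(l_max: float, l_eq: float) -> float:
    """Hidden length L_hl = L_max − ⟨L⟩ in Å (contour not bearing load at equilibrium)."""
    if l_eq < 0:
        raise ValueError(f"l_eq must be >= 0, got {l_eq}")
    if l_eq > l_max:
        raise ValueError(f"l_eq={l_eq} exceeds l_max={l_max}")
    return l_max - l_eq


def hidden_length_ratio(l_hl: float, l_eq: float) -> float:
    """Hidden length relative to the equilibrium length, L_hl/⟨L⟩ (dimensionless)."""
    if l_eq <= 0:
        raise ValueError(f"l_eq must be positive, got {l_eq}")
    return l_hl / l_eq


def derived_quantities(model: ChainModel, l_eq: Optional[float] = None) -> DerivedQuantities:
    """Bundle L_max, ⟨L⟩, L_hl and L_hl/⟨L⟩ for a chain model.

    ``l_eq`` defaults to the theoretical √N·a; pass a measured equilibrium
    length to compute the hidden length against the simulation instead.
    """
    l_max = model.contour_length
    l_eq_theory = equilibrium_end_to_end(model)
    used = l_eq_theory if l_eq is None else float(l_eq)
    l_hl = hidden_length(l_max, used)
    return DerivedQuantities(
        l_max=l_max,
        l_eq_theory=l_eq_theory,
        l_hidden=l_hl,
        hidden_ratio=hidden_length_ratio(l_hl, used),
    )
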