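"""Chain-fragment descriptions and packaged reference fixtures.

The two packaged fragments are the polyglycine-rich repeats of the dragline
spidroins MaSp1a and MaSp2.2a: 36 and 50 residues whose fully extended
(β-pleated) Cα–Cα end-to-end lengths are 118.1 Å and 166.5 Å. The per-residue
rise is back-computed from those lengths (L_max/(n_residues − 1)) rather than
rebuilt from backbone dihedrals. The constant-force ladder explored in the
pulling simulations and the three published zero-force trajectory averages
are packaged alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = [
    "FragmentSpec",
    "FORCE_LADDER_PN",
    "MASP1A",
    "MASP2_2A",
    "PACKAGED_FRAGMENTS",
]

#: constant pulling forces (pN) explored for each fragment
FORCE_LADDER_PN: Tuple[float, ...] = (
    10, 20, 30, 40, 50, 100, 150, 200, 250, 300, 350, 400, 450, 500, 550, 600,
)


@dataclass(frozen=True)
class FragmentSpec:
    """A named peptide fragment modelled as a bead-per-residue chain.

    Parameters
    ----------
    name : str
        Fragment label.
    n_residues : int
        Number of residues (beads in the Cα trace).
    l_max : float
        Contour (fully extended Cα–Cα) length in Å.
    rise_per_residue : float, optional
        Cα–Cα rise along the pulling axis in Å; defaults to
        ``l_max / (n_residues − 1)``.
    force_ladder : tuple of float
        Strictly increasing constant pulling forces in pN.
    sequence : str, optional
        One-letter residue sequence; no derived quantity depends on it.
    zero_force_means : tuple of float, optional
        Published per-trajectory equilibrium ⟨L⟩ values (Å) at zero force.
    zero_force_sds : tuple of float, optional
        Published per-trajectory standard deviations (Å) at zero force.
    """

    name: str
    n_residues: int
    l_max: float
    rise_per_residue: Optional[float] = None
    force_ladder: Tuple[float, ...] = FORCE_LADDER_PN
    sequence: Optional[str] = None
    zero_force_means: Optional[Tuple[float, ...]] = None
    zero_force_sds: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError(f"n_residues must be >= 2, got {self.n_residues}")
        if self.l_max <= 0:
            raise ValueError(f"l_max must be positive, got {self.l_max}")
        rise = self.rise_per_residue
        if rise is None:
            rise = self.l_max / (self.n_residues - 1)
            object.__setattr__(self, "rise_per_residue", rise)
        if abs(self.l_max - (self.n_residues - 1) * rise) > 0.05:
            raise ValueError(
                f"l_max={self.l_max} inconsistent with "
                f"(n_residues-1)*rise={(self.n_residues - 1) * rise:.3f} beyond 0.05 Å"
            )
        ladder = tuple(float(f) for f in self.force_ladder)
        if any(f < 0 for f in ladder):
            raise ValueError("force ladder values must be >= 0")
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("force ladder must be strictly increasing")
        object.__setattr__(self, "force_ladder", ladder)


MASP1A = FragmentSpec(
    name="MaSp1a",
    n_residues=36,
    l_max=118.1,
    zero_force_means=(40.1, 33.4, 43.9),
    zero_force_sds=(14.6, 20.5, 15.1),
)

MASP2_2A = FragmentSpec(
    name="MaSp2.2a",
    n_residues=50,
    l_max=166.5,
    zero_force_means=(52.3, 60.1, 68.8),
    zero_force_sds=(27.6, 22.0, 24.8),
)

PACKAGED_FRAGMENTS = {f.name: f for f in (MASP1A, MASP2_2A)}
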