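"""Synthetic constant-force chain-pulling data.

Two generators stand in for atomistic pulling simulations, at the resolution
the downstream analysis actually consumes (per-frame Cα-trace conformations
and end-to-end distances):

* :func:`sample_fjc_end_to_end` — *exact* equilibrium Monte-Carlo samples of
  an ideal chain under a constant end-to-end force, drawn link by link from
  the tilted orientation distribution p(cosθ) ∝ exp(f̃·cosθ) with reduced
  force f̃ = F·a/(k_B·T). Its mean fractional extension is the Langevin
  closed form L(f̃) — the oracle every other generator is checked against.

* :func:`simulate_trajectory` — overdamped (Euler–Maruyama) Brownian dynamics
  of a bead–spring chain: beads joined by stiff harmonic bonds of rest
  length ``a``, thermal noise of per-coordinate variance 2·k_B·T·dt/γ, and a
  constant outward force ±F on the two end beads along z. Runs start from
  the fully extended conformation, mirroring relaxation from a β-pleated
  start, and save evenly strided frames.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np
from numba import njit

from .constants import thermal_energy
from .fjc import ChainModel
from .fragments import FragmentSpec

__all__ = [
    "Conformation",
    "Trajectory",
    "BdParams",
    "ConfigurationError",
    "build_extended_conformation",
    "sample_fjc_end_to_end",
    "simulate_trajectory",
    "run_force_ladder",
]


class ConfigurationError(ValueError):
    """Simulation parameters violate a stability or consistency requirement."""


@dataclass(frozen=True)
class Conformation:
    """An ordered Cα/bead trace: coordinates in Å, shape (n_beads, 3)."""

    coordinates: np.ndarray
    labels: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
            raise ValueError(f"coordinates must have shape (n>=2, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[0]

    @property
    def end_to_end(self) -> float:
        """Euclidean distance between first and last bead, Å."""
        return float(np.linalg.norm(self.coordinates[-1] - self.coordinates[0]))


@dataclass(frozen=True)
class Trajectory:
    """Saved frames of a pulling run: coordinates (n_frames, n_beads, 3), times in ps."""

    frames: np.ndarray
    frame_times: np.ndarray
    force_applied: float
    seed: int
    timestep: float
    friction: float
    bond_stiffness: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        times = np.asarray(self.frame_times, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError(f"frames must have shape (n_frames, n_beads, 3), got {frames.shape}")
        if len(times) != len(frames):
            raise ValueError("frame_times length must match frames")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_times", times)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def frame(self, i: int) -> Conformation:
        return Conformation(self.frames[i])


@dataclass(frozen=True)
class BdParams:
    """Brownian-dynamics settings (reduced friction units: γ in pN·ps/Å).

    ``bond_stiffness`` is in k_B·T/Å². ``timestep`` (ps), if None, is chosen
    automatically as the largest value satisfying both guards below.

    Guards: the per-step RMS thermal displacement √(6·k_B·T·dt/γ) must stay
    below 0.1 × link length, and dt ≤ 0.25·γ/k keeps the Euler–Maruyama
    scheme stable and accurate for the stiffest bond mode.
    """

    n_steps: int = 3_000_000
    save_stride: Optional[int] = None
    timestep: Optional[float] = None
    friction: float = 1.0
    bond_stiffness: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.friction <= 0 or self.bond_stiffness <= 0:
            raise ValueError("friction and bond_stiffness must be positive")

    def resolved_stride(self) -> int:
        """Save stride; defaults to n_steps//1000 (≈1000 saved frames)."""
        if self.save_stride is not None:
            if not 1 <= self.save_stride <= self.n_steps:
                raise ValueError("save_stride must be in [1, n_steps]")
            return self.save_stride
        return max(self.n_steps // 1000, 1)

    def resolved_timestep(self, link_length: float, temperature: float) -> float:
        kT = thermal_energy(temperature)
        k_phys = self.bond_stiffness * kT  # pN/Å
        dt_bond = 0.25 * self.friction / k_phys
        dt_noise = (0.1 * link_length) ** 2 * self.friction / (6.0 * kT)
        dt_max = min(dt_bond, dt_noise)
        if self.timestep is None:
            return dt_max
        if self.timestep > dt_max:
            raise ConfigurationError(
                f"timestep {self.timestep} ps violates the stability guard "
                f"(max {dt_max:.3e} ps for a={link_length} Å, k={self.bond_stiffness} kT/Å²)"
            )
        return self.timestep


def build_extended_conformation(n_residues: int, rise_per_residue: float) -> Conformation:
    """Straight Cα trace along +z at a fixed per-residue rise.

    The end-to-end distance is exactly ``(n_residues − 1) × rise_per_residue``,
    the geometric idealisation of a fully extended β-pleated backbone.
    """
    if n_residues < 2:
        raise ValueError(f"n_residues must be >= 2, got {n_residues}")
    if rise_per_residue <= 0:
        raise ValueError(f"rise_per_residue must be positive, got {rise_per_residue}")
    coords = np.zeros((n_residues, 3))
    coords[:, 2] = np.arange(n_residues) * rise_per_residue
    return Conformation(coords)


def sample_fjc_end_to_end(
    model: ChainModel, force: float, n_samples: int, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact equilibrium samples of the FJC end-to-end vector under constant force.

    Each sample sums N independent unit link vectors. For reduced force
    f̃ = F·a/(k_B·T) > 0 the polar cosine of each link is drawn by the
    inverse CDF of p(c) ∝ exp(f̃ c), evaluated in the overflow-safe form
    ``c = 1 + ln(u + (1−u)·exp(−2f̃))/f̃`` with u uniform on (0, 1]; the
    azimuth is uniform. At F = 0 the links are uniform on the sphere.

    Returns
    -------
    vectors : ndarray, shape (n_samples, 3)
        End-to-end vectors in Å (force along +z).
    magnitudes : ndarray, shape (n_samples,)
        Their Euclidean norms in Å.
    """
    if force < 0:
        raise ValueError(f"force must be >= 0, got {force}")
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    rng = np.random.default_rng(seed)
    n, a = model.n_links, model.link_length
    u = 1.0 - rng.random((n_samples, n))  # in (0, 1]
    f_red = force * a / model.kT
    if f_red == 0.0:
        cos_theta = 2.0 * u - 1.0
    else:
        cos_theta = 1.0 + np.log(u + (1.0 - u) * math.exp(-2.0 * f_red)) / f_red
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, None))
    phi = rng.random((n_samples, n)) * (2.0 * math.pi)
    vectors = a * np.stack(
        [
            (sin_theta * np.cos(phi)).sum(axis=1),
            (sin_theta * np.sin(phi)).sum(axis=1),
            cos_theta.sum(axis=1),
        ],
        axis=1,
    )
    return vectors, np.linalg.norm(vectors, axis=1)


@njit(cache=False)
def _bd_kernel(x0, n_steps, save_stride, dt, gamma, k, a, kT, force, seed):  # pragma: no cover
    np.random.seed(seed)
    n = x0.shape[0]
    x = x0.copy()
    n_saved = n_steps // save_stride
    out = np.empty((n_saved, n, 3))
    amp = np.sqrt(2.0 * kT * dt / gamma)
    mob = dt / gamma
    f = np.zeros((n, 3))
    nsav = 0
    for step in range(n_steps):
        z = np.random.standard_normal((n, 3))
        for i in range(n - 1):
            dx = x[i + 1, 0] - x[i, 0]
            dy = x[i + 1, 1] - x[i, 1]
            dz = x[i + 1, 2] - x[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            c = k * (r - a) / r
            f[i, 0] += c * dx
            f[i, 1] += c * dy
            f[i, 2] += c * dz
            f[i + 1, 0] -= c * dx
            f[i + 1, 1] -= c * dy
            f[i + 1, 2] -= c * dz
        f[0, 2] -= force
        f[n - 1, 2] += force
        for i in range(n):
            x[i, 0] += f[i, 0] * mob + amp * z[i, 0]
            x[i, 1] += f[i, 1] * mob + amp * z[i, 1]
            x[i, 2] += f[i, 2] * mob + amp * z[i, 2]
            f[i, 0] = 0.0
            f[i, 1] = 0.0
            f[i, 2] = 0.0
        if (step + 1) % save_stride == 0:
            out[nsav] = x
            nsav += 1
    return out


def simulate_trajectory(
    fragment: FragmentSpec,
    model: ChainModel,
    force: float,
    bd: BdParams,
) -> Trajectory:
    """Constant-force Brownian-dynamics pulling run of a bead–spring chain.

    The chain is rendered at the FJC resolution of ``model``: N+1 beads at
    spacing ``a`` joined by harmonic bonds of rest length ``a`` and stiffness
    ``bd.bond_stiffness`` (k_B·T/Å²). A constant force −F/+F is applied to
    the two end beads along z (pulling outward); the run starts from the
    fully extended conformation. Frames are saved every ``save_stride``
    steps; reproducible bit-for-bit given ``bd.seed``.

    ``fragment`` supplies provenance (name, ladder); geometry comes from
    ``model``.
    """
    if force < 0:
        raise ValueError(f"force must be >= 0, got {force}")
    a = model.link_length
    dt = bd.resolved_timestep(a, model.temperature)  # raises ConfigurationError
    stride = bd.resolved_stride()
    kT = model.kT
    k_phys = bd.bond_stiffness * kT
    start = build_extended_conformation(model.n_links + 1, a)
    frames = _bd_kernel(
        start.coordinates,
        bd.n_steps,
        stride,
        dt,
        bd.friction,
        k_phys,
        a,
        kT,
        float(force),
        bd.seed,
    )
    times = dt * stride * np.arange(1, frames.shape[0] + 1)
    return Trajectory(
        frames=frames,
        frame_times=times,
        force_applied=float(force),
        seed=bd.seed,
        timestep=dt,
        friction=bd.friction,
        bond_stiffness=bd.bond_stiffness,
    )


def run_force_ladder(
    fragment: FragmentSpec,
    model: ChainModel,
    bd: BdParams,
    seed: int,
    forces: Optional[Tuple[float, ...]] = None,
) -> Dict[float, Trajectory]:
    """One pulling trajectory per ladder force, with child seed = seed + force index.

    Returns a dict force → :class:`Trajectory`, in ascending force order.
    Per-force equilibrated summaries are computed downstream (see
    :func:`elastochain.trajectory.summarize_trajectory` and
    :func:`elastochain.curves.build_curve`).
    """
    ladder = fragment.force_ladder if forces is None else tuple(forces)
    out: Dict[float, Trajectory] = {}
    for idx, force in enumerate(ladder):
        child = replace(bd, seed=seed + idx)
        out[float(force)] = simulate_trajectory(fragment, model, force, child)
    return out
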