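"""Trajectory statistics: end-to-end distance, RMSD, equilibration, summaries.

Equilibration is detected from the stabilisation of a scalar series (in
practice the RMSD to the extended start): the first sliding window whose
standard deviation drops below a fraction of the whole-series standard
deviation marks the equilibrated regime. Per-trajectory means over the
equilibrated window and their cross-trajectory combination reproduce the
published three-replicate zero-force statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .simulate import Conformation, Trajectory

__all__ = [
    "ScalarSeries",
    "EquilibrationResult",
    "EquilibriumSummary",
    "end_to_end_series",
    "kabsch_superpose",
    "rmsd_series",
    "detect_equilibration",
    "summarize_trajectory",
    "combine_trajectories",
    "summarize_replicates",
]


@dataclass(frozen=True)
class ScalarSeries:
    """A per-frame scalar (Å) with frame indices and times (ps)."""

    values: np.ndarray
    frame_times: np.ndarray
    frames: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        times = np.asarray(self.frame_times, dtype=float)
        frames = (
            np.arange(len(values))
            if self.frames is None
            else np.asarray(self.frames, dtype=int)
        )
        if not (len(values) == len(times) == len(frames)):
            raise ValueError("values, frame_times and frames must have equal length")
        if not np.all(np.isfinite(values)):
            raise ValueError("series values must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "frame_times", times)
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.values)


class EquilibrationResult(NamedTuple):
    start: int
    converged: bool


@dataclass(frozen=True)
class EquilibriumSummary:
    """Cross-replicate zero-force equilibrium statistics.

    ``per_trajectory`` holds (mean L, SD of L, equilibration start frame) per
    replicate. ``grand_mean`` is the arithmetic mean of the per-trajectory
    means; ``grand_spread`` is their standard error (sample SD/√n, the spread
    the published table prints); ``grand_sd`` the sample SD itself.
    """

    per_trajectory: Tuple[Tuple[float, float, int], ...]
    grand_mean: float
    grand_spread: Optional[float]
    grand_sd: Optional[float]

    @property
    def n_trajectories(self) -> int:
        return len(self.per_trajectory)


def end_to_end_series(traj: Trajectory) -> ScalarSeries:
    """Per-frame Euclidean distance (Å) between the first and last bead."""
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    if traj.n_beads < 2:
        raise ValueError("trajectory frames need at least 2 beads")
    d = np.linalg.norm(traj.frames[:, -1] - traj.frames[:, 0], axis=1)
    return ScalarSeries(values=d, frame_times=traj.frame_times)


def kabsch_superpose(
    reference: Conformation, mobile: Conformation
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Least-squares (Kabsch/SVD) fit with a proper rotation (det +1).

    Returns
    -------
    rotation : ndarray (3, 3)
        Rotation matrix to apply to centred mobile coordinates.
    translation : ndarray (3,)
        Translation such that ``mobile @ R.T + t`` best matches reference.
    rmsd : float
        Minimised coordinate RMSD in Å.
    """
    ref = reference.coordinates
    mob = mobile.coordinates
    if ref.shape != mob.shape:
        raise ValueError(f"bead counts differ: {ref.shape[0]} vs {mob.shape[0]}")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    with warnings.catch_warnings():
        # collinear traces make the optimal rotation non-unique; RMSD is still defined
        warnings.simplefilter("ignore", UserWarning)
        rot, rssd = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    matrix = rot.as_matrix()
    translation = ref_c - matrix @ mob_c
    rmsd = float(rssd / np.sqrt(ref.shape[0]))
    return matrix, translation, rmsd


def rmsd_series(traj: Trajectory, reference: Conformation) -> ScalarSeries:
    """Per-frame Kabsch RMSD (Å) against a fixed reference conformation."""
    if reference.n_beads != traj.n_beads:
        raise ValueError(
            f"reference has {reference.n_beads} beads, trajectory {traj.n_beads}"
        )
    vals = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        vals[i] = kabsch_superpose(reference, traj.frame(i))[2]
    return ScalarSeries(values=vals, frame_times=traj.frame_times)


def detect_equilibration(
    series: ScalarSeries, window: int = 100, rel_tol: float = 0.25
) -> EquilibrationResult:
    """First frame from which the series has stabilised.

    Returns the first index ``i`` whose window ``[i, i+window)`` has standard
    deviation ≤ ``rel_tol`` × the whole-series standard deviation. If no
    window qualifies, the last admissible start is returned with
    ``converged=False`` (and a warning).
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    values = series.values
    if len(values) < window:
        raise ValueError(f"series length {len(values)} shorter than window {window}")
    full_sd = float(np.std(values))
    if full_sd == 0.0:
        return EquilibrationResult(0, True)
    # rolling SD via cumulative sums
    c1 = np.concatenate([[0.0], np.cumsum(values)])
    c2 = np.concatenate([[0.0], np.cumsum(values**2)])
    s1 = c1[window:] - c1[:-window]
    s2 = c2[window:] - c2[:-window]
    var = np.maximum(s2 / window - (s1 / window) ** 2, 0.0)
    ok = np.flatnonzero(np.sqrt(var) <= rel_tol * full_sd)
    if len(ok) == 0:
        warnings.warn(
            "no window met the stabilisation criterion; returning the last admissible start",
            stacklevel=2,
        )
        return EquilibrationResult(len(values) - window, False)
    return EquilibrationResult(int(ok[0]), True)


def summarize_trajectory(l_series: ScalarSeries, eq_start: int = 0) -> Tuple[float, float]:
    """Mean and sample SD (n−1) of the series over frames ≥ ``eq_start``."""
    if eq_start >= len(l_series):
        raise ValueError(f"eq_start {eq_start} beyond series length {len(l_series)}")
    tail = l_series.values[eq_start:]
    if len(tail) < 2:
        raise ValueError("need at least 2 equilibrated frames for a standard deviation")
    return float(np.mean(tail)), float(np.std(tail, ddof=1))


def combine_trajectories(per_traj_means: Sequence[float]) -> Tuple[float, float]:
    """Grand mean of per-trajectory means and its standard error (sample SD/√n)."""
    means = np.asarray(per_traj_means, dtype=float)
    if len(means) < 2:
        raise ValueError("need >= 2 per-trajectory means; the spread is undefined for 1")
    sem = float(np.std(means, ddof=1) / np.sqrt(len(means)))
    return float(np.mean(means)), sem


def summarize_replicates(
    series_list: Sequence[ScalarSeries],
    eq_starts: Optional[Sequence[int]] = None,
    window: int = 100,
    rel_tol: float = 0.25,
    rmsd_list: Optional[Sequence[ScalarSeries]] = None,
) -> EquilibriumSummary:
    """Full replicate pipeline: equilibration, per-trajectory stats, combination.

    Equilibration is detected per replicate on ``rmsd_list`` when given (the
    stabilisation criterion applies to RMSD), else on the L series itself;
    explicit ``eq_starts`` override detection.
    """
    if len(series_list) < 1:
        raise ValueError("need at least one series")
    per: List[Tuple[float, float, int]] = []
    for i, series in enumerate(series_list):
        if eq_starts is not None:
            start = int(eq_starts[i])
        else:
            basis = rmsd_list[i] if rmsd_list is not None else series
            start = detect_equilibration(basis, window=window, rel_tol=rel_tol).start
        mean, sd = summarize_trajectory(series, start)
        per.append((mean, sd, start))
    means = [m for m, _, _ in per]
    if len(means) >= 2:
        grand_mean, sem = combine_trajectories(means)
        grand_sd = float(np.std(means, ddof=1))
    else:
        grand_mean, sem, grand_sd = means[0], None, None
    return EquilibriumSummary(
        per_trajectory=tuple(per),
        grand_mean=grand_mean,
        grand_spread=sem,
        grand_sd=grand_sd,
    )
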