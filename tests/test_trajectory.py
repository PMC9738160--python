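"""Tests for trajectory statistics: distances, RMSD, equilibration, summaries."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import elastochain as ec
from elastochain.trajectory import EquilibriumSummary, summarize_replicates

from conftest import random_conformation


def make_traj(frames):
    frames = np.asarray(frames, dtype=float)
    return ec.Trajectory(
        frames=frames,
        frame_times=np.arange(1, len(frames) + 1, dtype=float),
        force_applied=0.0,
        seed=0,
        timestep=1.0,
        friction=1.0,
        bond_stiffness=200.0,
    )


def brute_force_min_rmsd(ref, mob, n_rotations=2000, seed=0):
    """Random-rotation-grid oracle for the optimal superposition RMSD."""
    ref_c = ref.coordinates - ref.coordinates.mean(axis=0)
    mob_c = mob.coordinates - mob.coordinates.mean(axis=0)
    rots = Rotation.random(n_rotations, rng=np.random.default_rng(seed)).as_matrix()
    rotated = np.einsum("rij,nj->rni", rots, mob_c)
    rmsds = np.sqrt(((rotated - ref_c) ** 2).sum(axis=2).mean(axis=1))
    return float(rmsds.min())


class TestEndToEndSeries:
    def test_constant_extended(self):
        conf = ec.build_extended_conformation(10, 2.0)
        traj = make_traj(np.repeat(conf.coordinates[None], 5, axis=0))
        assert np.all(ec.end_to_end_series(traj).values == pytest.approx(18.0))

    def test_hand_geometry(self):
        frames = [
            [[0, 0, 0], [0, 0, 10]],
            [[0, 0, 0], [0, 0, 5]],
        ]
        assert ec.end_to_end_series(make_traj(frames)).values == pytest.approx([10.0, 5.0])

    def test_zero_force_run_decreasing_trend(self, short_zero_force_run):
        series = ec.end_to_end_series(short_zero_force_run).values
        decile = len(series) // 10
        assert series[:decile].mean() > series[-decile:].mean()


class TestKabsch:
    def test_identical_gives_zero(self):
        rng = np.random.default_rng(0)
        conf = random_conformation(rng)
        assert ec.kabsch_superpose(conf, conf)[2] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_gives_zero(self):
        rng = np.random.default_rng(1)
        conf = random_conformation(rng)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = ec.Conformation(conf.coordinates @ rot.T + np.array([5.0, -3.0, 12.0]))
        matrix, translation, rmsd = ec.kabsch_superpose(conf, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        # returned transform actually maps mobile onto reference
        mapped = moved.coordinates @ matrix.T + translation
        assert np.allclose(mapped, conf.coordinates, atol=1e-6)

    def test_proper_rotation(self):
        rng = np.random.default_rng(2)
        ref, mob = random_conformation(rng), random_conformation(rng)
        matrix, _, _ = ec.kabsch_superpose(ref, mob)
        assert np.linalg.det(matrix) == pytest.approx(1.0, abs=1e-9)

    def test_beats_random_rotation_grid(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            ref, mob = random_conformation(rng), random_conformation(rng)
            rmsd = ec.kabsch_superpose(ref, mob)[2]
            assert rmsd <= brute_force_min_rmsd(ref, mob) + 1e-6

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        ref, mob = random_conformation(rng), random_conformation(rng)
        assert ec.kabsch_superpose(ref, mob)[2] == pytest.approx(
            ec.kabsch_superpose(mob, ref)[2], abs=1e-9
        )

    def test_mismatched_bead_counts(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            ec.kabsch_superpose(random_conformation(rng, 10), random_conformation(rng, 12))


class TestRmsdSeries:
    def test_identical_frames_all_zero(self):
        rng = np.random.default_rng(6)
        conf = random_conformation(rng)
        traj = make_traj(np.repeat(conf.coordinates[None], 4, axis=0))
        assert np.all(ec.rmsd_series(traj, conf).values == pytest.approx(0.0, abs=1e-9))

    def test_reference_frame_mid_trajectory(self):
        rng = np.random.default_rng(7)
        ref = random_conformation(rng)
        other = random_conformation(rng)
        traj = make_traj([other.coordinates, ref.coordinates, other.coordinates])
        vals = ec.rmsd_series(traj, ref).values
        assert vals[1] == pytest.approx(0.0, abs=1e-9)
        assert vals[0] > 1e-3 and vals[2] > 1e-3

    def test_higher_force_means_lower_rmsd(self, masp1a_chain):
        ref = ec.build_extended_conformation(16, 8.1)
        means = []
        for force, seed in ((20.0, 21), (600.0, 22)):
            traj = ec.simulate_trajectory(
                ec.MASP1A, masp1a_chain, force, ec.BdParams(n_steps=600_000, seed=seed)
            )
            vals = ec.rmsd_series(traj, ref).values
            means.append(vals[len(vals) // 2 :].mean())
        assert means[1] < means[0]


class TestEquilibrationDetection:
    def test_constant_series(self):
        series = ec.ScalarSeries(values=np.full(300, 7.0), frame_times=np.arange(300.0))
        assert ec.detect_equilibration(series).start == 0

    def test_ramp_then_constant_tail(self):
        values = np.concatenate([np.linspace(10, 1, 200), np.full(150, 1.0)])
        series = ec.ScalarSeries(values=values, frame_times=np.arange(350.0))
        result = ec.detect_equilibration(series, window=100, rel_tol=0.25)
        assert result.converged
        assert 100 <= result.start <= 250  # window fits inside/near the constant tail

    def test_no_stable_window_flags_warning(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=400)  # stationary noise: window SD ~ full SD
        series = ec.ScalarSeries(values=values, frame_times=np.arange(400.0))
        with pytest.warns(UserWarning):
            result = ec.detect_equilibration(series, window=100, rel_tol=0.25)
        assert result.start == 300 and not result.converged

    def test_seeded_relaxation_detected_in_first_half(self, masp1a_chain):
        # transient occupies roughly the first third of this 4e6-step run
        bd = ec.BdParams(n_steps=4_000_000, seed=2022)
        traj = ec.simulate_trajectory(ec.MASP1A, masp1a_chain, 0.0, bd)
        rmsd = ec.rmsd_series(traj, ec.build_extended_conformation(16, 8.1))
        result = ec.detect_equilibration(rmsd)
        assert result.converged
        assert result.start < traj.n_frames // 2

    def test_series_shorter_than_window(self):
        series = ec.ScalarSeries(values=np.ones(10), frame_times=np.arange(10.0))
        with pytest.raises(ValueError):
            ec.detect_equilibration(series, window=20)


class TestSummaries:
    def test_constant_series(self):
        series = ec.ScalarSeries(values=np.full(10, 4.2), frame_times=np.arange(10.0))
        assert ec.summarize_trajectory(series, 0) == (pytest.approx(4.2), pytest.approx(0.0))

    def test_hand_computation(self):
        series = ec.ScalarSeries(values=np.array([1.0, 2.0, 3.0]), frame_times=np.arange(3.0))
        mean, sd = ec.summarize_trajectory(series, 0)
        assert (mean, sd) == (pytest.approx(2.0), pytest.approx(1.0))

    def test_too_few_equilibrated_frames(self):
        series = ec.ScalarSeries(values=np.array([1.0, 2.0]), frame_times=np.arange(2.0))
        with pytest.raises(ValueError):
            ec.summarize_trajectory(series, 1)

    def test_combine_published_replicates(self):
        grand, spread = ec.combine_trajectories([40.1, 33.4, 43.9])
        assert round(grand) == 39 and round(spread) == 3
        assert grand == pytest.approx(39.133, abs=1e-3)
        grand, spread = ec.combine_trajectories([52.3, 60.1, 68.8])
        assert round(grand) == 60 and round(spread) == 5
        assert grand == pytest.approx(60.4, abs=1e-9)

    def test_combine_identical_values(self):
        assert ec.combine_trajectories([5.0, 5.0, 5.0]) == (5.0, 0.0)

    def test_combine_requires_two(self):
        with pytest.raises(ValueError):
            ec.combine_trajectories([39.0])

    def test_summarize_replicates_pipeline(self):
        rng = np.random.default_rng(9)
        series = [
            ec.ScalarSeries(
                values=np.concatenate([np.linspace(100, mu, 150), rng.normal(mu, 1.0, 250)]),
                frame_times=np.arange(400.0),
            )
            for mu in (30.0, 35.0, 40.0)
        ]
        summary = summarize_replicates(series)
        assert isinstance(summary, EquilibriumSummary)
        assert summary.n_trajectories == 3
        assert summary.grand_mean == pytest.approx(35.0, abs=2.0)
        assert summary.grand_spread is not None and summary.grand_spread > 0
        # grand mean is the arithmetic mean of per-trajectory means
        means = [m for m, _, _ in summary.per_trajectory]
        assert summary.grand_mean == pytest.approx(np.mean(means))
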