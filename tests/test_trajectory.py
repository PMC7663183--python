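"""Trajectory analytics: superposition, RMSD/RMSF, essential motions,
SASA time series and interval differences."""

import numpy as np
import pytest

from fabqsar.errors import DegenerateSelection, EmptyInterval
from fabqsar.imgt import RegionAnnotation
from fabqsar.struct_descriptors import region_sasa, residue_rsa
from fabqsar.structure import Trajectory
from fabqsar.synthetic import TrajectorySpec, make_toy_structure, make_trajectory
from fabqsar.trajectory_analysis import (SasaSeries, essential_motion_magnitude,
                                         kabsch_superpose, region_sasa_series,
                                         rmsd_series, rmsf, sasa_interval_diff)


@pytest.fixture(scope="module")
def base_structure():
    return make_toy_structure("GASTVLIKDERNQHYPMGSA", geometry="globule")


def static_trajectory(structure, n_frames=10):
    frames = np.repeat(structure.coords[None], n_frames, axis=0)
    times = np.arange(n_frames, dtype=float) * 40.0
    return Trajectory(frames=frames, times=times, template=structure)


def rot_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


class TestKabsch:
    def test_identical_sets_rmsd_zero(self, rng):
        pts = rng.normal(size=(6, 3))
        rot, trans, r = kabsch_superpose(pts, pts)
        assert r == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_rigid_motion_removed(self, rng):
        ref = rng.normal(size=(8, 3))
        mobile = ref @ rot_z(np.pi / 2).T + np.array([3.0, -1.0, 7.0])
        _, _, r = kabsch_superpose(mobile, ref)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_rotation_grid_oracle(self):
        """Planar 4-point problem: brute-force search over z-rotations."""
        ref = np.array([[1.0, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1.4, 0]])
        mobile = ref @ rot_z(0.65).T + 0.05 * np.array(
            [[1, -1, 0], [0, 1, 0], [-1, 0, 0], [1, 1, 0]])
        _, _, r_kabsch = kabsch_superpose(mobile, ref)
        best = np.inf
        for deg in np.arange(0.0, 360.0, 0.01):
            cand = mobile @ rot_z(np.deg2rad(deg)).T
            cand = cand - cand.mean(0) + ref.mean(0)
            best = min(best, np.sqrt(((cand - ref) ** 2).sum(1).mean()))
        assert r_kabsch == pytest.approx(best, abs=1e-3)

    def test_collinear_selection_raises(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateSelection):
            kabsch_superpose(line, line)

    def test_too_few_points_raises(self):
        with pytest.raises(DegenerateSelection):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_constant_trajectory_all_zero(self, base_structure):
        traj = static_trajectory(base_structure)
        assert np.allclose(rmsd_series(traj), 0.0, atol=1e-9)

    def test_linear_drift_monotone(self, base_structure):
        traj, _ = make_trajectory(base_structure, TrajectorySpec(
            n_frames=30, drift_magnitude=6.0, drift_start_frame=0,
            noise_sd=0.0), seed=0)
        series = rmsd_series(traj)
        assert np.all(np.diff(series) >= -1e-9)
        assert series[-1] > series[0]

    def test_noise_plateau_in_reported_band(self, base_structure):
        """Per-atom noise sd 1.2 Å puts the raw RMSD plateau in the 2–5 Å
        band typical of relaxed Fab simulations."""
        traj, _ = make_trajectory(base_structure, TrajectorySpec(
            n_frames=60, noise_sd=1.2), seed=1)
        series = rmsd_series(traj, superpose=False)
        plateau = series[10:].mean()
        assert 2.0 <= plateau <= 5.0

    def test_programmed_drift_magnitude_on_drifting_subset(self,
                                                           base_structure):
        traj, truth = make_trajectory(base_structure, TrajectorySpec(
            n_frames=40, drift_magnitude=3.0, drift_start_frame=0,
            noise_sd=0.0), seed=2)
        series = rmsd_series(traj, selection=truth["drift_atoms"],
                             superpose=False)
        assert series[-1] == pytest.approx(3.0, abs=1e-6)


class TestRmsf:
    def test_static_trajectory_zero(self, base_structure):
        traj = static_trajectory(base_structure)
        assert np.allclose(rmsf(traj), 0.0, atol=1e-9)

    def test_single_oscillating_atom(self):
        structure = make_toy_structure("GAVLIK", geometry="globule")
        frames = np.repeat(structure.coords[None], 8, axis=0)
        frames[::2, 3, 0] += 2.0   # atom 3 alternates +/-d about its mean
        frames[1::2, 3, 0] -= 2.0
        traj = Trajectory(frames=frames,
                          times=np.arange(8.0) * 40.0, template=structure)
        # superpose on the static atoms so the oscillation is not absorbed
        static = np.array([0, 1, 2, 4, 5])
        flucts = rmsf(traj, selection=np.arange(6), align_selection=static)
        assert flucts[3] == pytest.approx(2.0, rel=1e-6)
        assert np.all(flucts[static] < 1e-9)

    def test_invariant_under_global_rigid_motion(self, base_structure):
        traj, _ = make_trajectory(base_structure, TrajectorySpec(
            n_frames=12, noise_sd=0.3), seed=3)
        rot = rot_z(1.1)
        moved = Trajectory(frames=traj.frames @ rot.T + np.array([4, 5, 6.0]),
                           times=traj.times, template=base_structure)
        assert np.allclose(rmsf(traj), rmsf(moved), atol=1e-8)


class TestEssentialMotion:
    def test_single_coordinate_motion_one_mode(self):
        structure = make_toy_structure("GAVLIKDE", geometry="globule")
        frames = np.repeat(structure.coords[None], 20, axis=0)
        frames[:, 2, 2] += np.sin(np.arange(20))  # only atom 2, z moves
        traj = Trajectory(frames=frames, times=np.arange(20.0),
                          template=structure)
        eigvals, mag = essential_motion_magnitude(
            traj, selection=np.arange(structure.n_atoms))
        assert (eigvals > 1e-10 * eigvals[0]).sum() <= 3  # alignment residue
        assert mag == pytest.approx(np.sqrt(eigvals[0]))

    def test_trace_equals_total_variance(self, base_structure):
        traj, _ = make_trajectory(base_structure, TrajectorySpec(
            n_frames=15, noise_sd=0.4), seed=4)
        sel = np.arange(base_structure.n_atoms)
        eigvals, _ = essential_motion_magnitude(traj, selection=sel)
        from fabqsar.trajectory_analysis import _mean_aligned_frames
        aligned = _mean_aligned_frames(traj, sel)
        flat = aligned.reshape(traj.n_frames, -1)
        total_var = ((flat - flat.mean(0)) ** 2).sum() / traj.n_frames
        assert eigvals.sum() == pytest.approx(total_var, rel=1e-9)

    def test_two_mode_variances_recovered(self):
        structure = make_toy_structure("GAVLIKDERN" * 2, geometry="globule")
        n = structure.n_atoms
        rng = np.random.default_rng(7)
        frames = np.repeat(structure.coords[None], 400, axis=0)
        # two orthogonal collective modes with variances 4 and 1
        mode1 = np.zeros((n, 3)); mode1[5, 0] = 1.0
        mode2 = np.zeros((n, 3)); mode2[11, 1] = 1.0
        a = rng.normal(0, 2.0, 400)
        b = rng.normal(0, 1.0, 400)
        frames += a[:, None, None] * mode1 + b[:, None, None] * mode2
        traj = Trajectory(frames=frames, times=np.arange(400.0),
                          template=structure)
        eigvals, _ = essential_motion_magnitude(traj, selection=np.arange(n))
        assert eigvals[0] == pytest.approx(4.0, rel=0.25)
        assert eigvals[1] == pytest.approx(1.0, rel=0.25)


REGION = RegionAnnotation("CDR-H3", 0, 6, "heavy")


class TestSasaSeries:
    def test_constant_trajectory_constant_series(self, base_structure):
        traj = static_trajectory(base_structure, n_frames=5)
        series = region_sasa_series(traj, None, REGION)
        assert np.allclose(series.values, series.values[0])
        assert np.all(series.values >= 0)

    def test_matches_framewise_region_sasa(self, base_structure):
        traj, _ = make_trajectory(base_structure, TrajectorySpec(
            n_frames=4, noise_sd=0.2), seed=5)
        series = region_sasa_series(traj, None, REGION)
        for i in range(4):
            surfaces = residue_rsa(traj.frame_structure(i))
            assert series.values[i] == pytest.approx(
                region_sasa(surfaces, REGION, "all"))


class TestIntervalDiff:
    def test_constant_series_zero(self):
        series = SasaSeries("CDR-H3", np.arange(10) * 1000.0,
                            np.full(10, 120.0))
        assert sasa_interval_diff(series) == 0.0

    def test_step_series(self):
        times = np.arange(10) * 1000.0
        values = np.where(times < 5000, 100.0, 150.0)
        assert sasa_interval_diff(SasaSeries("x", times, values)) == 50.0

    def test_matches_two_pass_mean_oracle(self, rng):
        times = np.arange(50) * 200.0
        values = rng.uniform(50, 200, size=50)
        series = SasaSeries("x", times, values)
        early = [v for t, v in zip(times, values) if t < 5000]
        late = [v for t, v in zip(times, values) if t >= 5000]
        expected = abs(sum(early) / len(early) - sum(late) / len(late))
        assert sasa_interval_diff(series) == pytest.approx(expected)

    def test_sign_symmetric_and_scales_linearly(self, rng):
        times = np.arange(20) * 500.0
        values = rng.uniform(10, 30, size=20)
        series = SasaSeries("x", times, values)
        flipped = SasaSeries("x", times, values[::-1].copy())
        d = sasa_interval_diff(series)
        scaled = SasaSeries("x", times, values * 3.0)
        assert sasa_interval_diff(scaled) == pytest.approx(3.0 * d)
        assert d >= 0 and sasa_interval_diff(flipped) >= 0

    def test_series_must_span_split(self):
        series = SasaSeries("x", np.arange(5) * 100.0, np.ones(5))
        with pytest.raises(EmptyInterval):
            sasa_interval_diff(series, split_time=5000.0)
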