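import numpy as np
import pytest

from adapt2state.preprocessing import (LateralProfile, NoMovementError,
                                       adaptation_angle, baseline_correct,
                                       detect_end, detect_onset, epochize,
                                       mean_profile, normalize_trajectory,
                                       process_trajectories,
                                       project_to_perturbed_dimension)
from adapt2state.surrogate import (CUBE_TARGETS, TrajectoryRecord,
                                   synth_trajectories)


def make_traj(points, dt=0.1, **kwargs):
    points = np.asarray(points, dtype=float)
    defaults = dict(trial=0, target_id=1, phase="baseline", plane="coronal")
    defaults.update(kwargs)
    return TrajectoryRecord(t=np.arange(len(points)) * dt, pos=points, **defaults)


def speed_ramp_traj(speeds_cm_s, dt=1.0):
    """Trajectory whose finite-difference speed sequence is as given."""
    steps = np.concatenate([[0.0], np.asarray(speeds_cm_s, float)[1:] * dt])
    x = np.cumsum(steps)
    return make_traj(np.column_stack([x, np.zeros_like(x), np.zeros_like(x)]),
                     dt=dt)


class TestDetectOnset:
    def test_stationary_raises_no_movement(self):
        traj = make_traj(np.zeros((20, 3)))
        with pytest.raises(NoMovementError):
            detect_onset(traj)

    def test_first_crossing_on_ramp(self):
        traj = speed_ramp_traj([0, 1, 2, 4, 6, 8, 10])
        assert detect_onset(traj, v_thresh=3.0, dwell=1) == 3  # the "4" sample

    def test_dwell_rejects_transient_spike(self):
        traj = speed_ramp_traj([0, 10, 0, 0, 4, 5, 6, 7])
        assert detect_onset(traj, v_thresh=3.0, dwell=3) == 4

    def test_noise_robust_against_generator_ground_truth(self):
        # ground truth = the 3 cm/s crossing of the noise-free trajectory;
        # smooth position noise must not shift the detected onset by > 2
        clean = synth_trajectories(8, aim_angle=15.0, plane="coronal",
                                   noise_sd=0.0, seed=3, hold_time=0.4, dt=0.01)
        noisy = synth_trajectories(8, aim_angle=15.0, plane="coronal",
                                   noise_sd=0.05, seed=3, hold_time=0.4, dt=0.01)
        for ref, rec in zip(clean, noisy):
            assert abs(detect_onset(rec) - detect_onset(ref)) <= 2


class TestNormalizeTrajectory:
    def test_constant_velocity_segment_is_uniform(self):
        pos = np.linspace([0, 0, 0], [10, 0, 0], 101)
        traj = make_traj(pos, dt=0.01)
        path = normalize_trajectory(traj, 0, 100)
        assert path.shape == (50, 3)
        np.testing.assert_allclose(np.diff(path[:, 0]),
                                   np.full(49, 10 / 49), atol=1e-9)
        np.testing.assert_allclose(path[:, 1:], 0, atol=1e-12)

    def test_fifty_uniform_samples_identity(self):
        rng = np.random.default_rng(0)
        pos = np.cumsum(rng.normal(size=(50, 3)), axis=0)
        traj = make_traj(pos, dt=0.02)
        np.testing.assert_allclose(normalize_trajectory(traj, 0, 49), pos,
                                   atol=1e-12)

    def test_reversed_window_rejected(self):
        traj = make_traj(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            normalize_trajectory(traj, 8, 3)


def rotate_about(axis, deg, vec):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    rad = np.deg2rad(deg)
    return (vec * np.cos(rad) + np.cross(axis, vec) * np.sin(rad)
            + axis * (axis @ vec) * (1 - np.cos(rad)))


class TestProjection:
    def test_straight_path_zero_lateral(self):
        target = CUBE_TARGETS[1]
        path = np.linspace([0, 0, 0], target, 50)
        prof = project_to_perturbed_dimension(path, target, "coronal")
        np.testing.assert_allclose(prof.d, 0, atol=1e-12)
        assert prof.target_dist == pytest.approx(np.linalg.norm(target))

    def test_in_plane_rotation_gives_tangent_ratio(self):
        # in-plane target: rotating the whole path by -10 deg about the
        # horizontal-plane normal (a clockwise re-aim) is compensatory
        target = np.array([10.0, 0.0, 0.0])
        straight = np.linspace([0, 0, 0], target, 50)
        rotated = np.array([rotate_about([0, 0, 1], -10.0, p) for p in straight])
        prof = project_to_perturbed_dimension(rotated, target, "horizontal")
        ratio = prof.d[1:] / prof.s[1:]
        np.testing.assert_allclose(ratio, np.tan(np.deg2rad(10.0)), atol=1e-10)

    def test_out_of_plane_deviation_invisible(self):
        target = np.array([10.0, 0.0, 0.0])
        path = np.linspace([0, 0, 0], target, 50)
        path[:, 2] += np.sin(np.linspace(0, np.pi, 50))  # within-sagittal bump
        prof = project_to_perturbed_dimension(path, target, "horizontal")
        np.testing.assert_allclose(prof.d, 0, atol=1e-12)

    def test_degenerate_target_rejected(self):
        path = np.zeros((50, 3))
        with pytest.raises(ValueError):
            project_to_perturbed_dimension(path, [0, 0, 5.0], "horizontal")


class TestBaselineCorrection:
    def make_profile(self, d, tid=1):
        return LateralProfile(s=np.linspace(0, 10, 50), d=d, target_dist=10.0,
                              target_id=tid)

    def test_profile_minus_itself_is_zero(self):
        prof = self.make_profile(np.sin(np.linspace(0, 1, 50)))
        corrected = baseline_correct(prof, prof)
        np.testing.assert_allclose(corrected.d, 0, atol=1e-15)

    def test_centering_identity(self):
        rng = np.random.default_rng(1)
        profs = [self.make_profile(rng.normal(size=50)) for _ in range(6)]
        mean = mean_profile(profs)
        corrected = [baseline_correct(p, mean) for p in profs]
        np.testing.assert_allclose(np.mean([c.d for c in corrected], axis=0),
                                   0, atol=1e-12)

    def test_target_mismatch_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(self.make_profile(np.zeros(50), tid=1),
                             self.make_profile(np.zeros(50), tid=2))

    def test_curved_baseline_plus_rotation_recovers_rotation(self):
        # curvature shared by baseline and perturbed trials cancels out
        base = synth_trajectories(16, 0.0, "coronal", seed=11, curvature=0.8,
                                  phase="baseline")
        pert = synth_trajectories(16, 30.0, "coronal", seed=12, curvature=0.8,
                                  phase="perturbation", start_trial=16)
        run = process_trajectories(base + pert, "coronal")
        pert_vals = [y for y, lab in zip(run.y, run.schedule.phase)
                     if lab == "perturbation"]
        assert np.mean(pert_vals) == pytest.approx(30.0, abs=0.5)


class TestAdaptationAngle:
    def test_zero_deviation_zero_angle(self):
        prof = LateralProfile(s=np.linspace(0, 10, 50), d=np.zeros(50),
                              target_dist=10.0)
        assert adaptation_angle(prof) == 0.0

    def test_half_distance_deviation_gives_45_degrees(self):
        prof = LateralProfile(s=np.linspace(0, 10, 50), d=np.full(50, 5.0),
                              target_dist=10.0)
        assert adaptation_angle(prof) == pytest.approx(45.0)

    def test_rigid_rotation_of_straight_path(self):
        target = np.array([10.0, 0.0, 0.0])
        straight = np.linspace([0, 0, 0], target, 50)
        rotated = np.array([rotate_about([0, 0, 1], -30.0, p) for p in straight])
        prof = project_to_perturbed_dimension(rotated, target, "horizontal")
        assert adaptation_angle(prof) == pytest.approx(30.0, abs=1e-6)

    def test_never_reaching_half_distance_rejected(self):
        prof = LateralProfile(s=np.linspace(0, 2, 50), d=np.zeros(50),
                              target_dist=10.0)
        with pytest.raises(ValueError):
            adaptation_angle(prof)


class TestEpochize:
    def test_uniform_epoch(self):
        run = epochize([12.0] * 8, list(range(1, 9)), ["baseline"] * 8)
        assert run.y == pytest.approx([12.0])

    def test_arithmetic_mean(self):
        run = epochize(np.arange(1.0, 9.0), list(range(1, 9)),
                       ["perturbation"] * 8)
        assert run.y == pytest.approx([4.5])
        assert run.schedule.p == pytest.approx([30.0])

    def test_incomplete_epoch_rejected(self):
        with pytest.raises(ValueError):
            epochize([1.0] * 9, list(range(1, 9)) + [1], ["baseline"] * 9)

    def test_duplicated_target_rejected(self):
        tids = [1, 1, 3, 4, 5, 6, 7, 8]
        with pytest.raises(ValueError, match="duplicated target"):
            epochize([0.0] * 8, tids, ["baseline"] * 8)

    def test_phase_straddle_rejected(self):
        phases = ["baseline"] * 4 + ["perturbation"] * 4
        with pytest.raises(ValueError, match="straddles"):
            epochize([0.0] * 8, list(range(1, 9)), phases)


class TestPipelineRoundTrip:
    @pytest.mark.parametrize("theta", [-30.0, -10.0, 0.0, 10.0, 30.0])
    def test_injected_angle_recovered_with_noise(self, theta):
        # 5 baseline epochs keep the baseline-mean noise small, as in the
        # real block design (the experiment has 15 baseline epochs)
        base = synth_trajectories(40, 0.0, "coronal", noise_sd=0.2, seed=21,
                                  phase="baseline")
        pert = synth_trajectories(24, theta, "coronal", noise_sd=0.2, seed=22,
                                  phase="perturbation", start_trial=40)
        run = process_trajectories(base + pert, "coronal")
        pert_vals = [y for y, lab in zip(run.y, run.schedule.phase)
                     if lab == "perturbation"]
        assert abs(np.mean(pert_vals) - theta) < 1.0

    @pytest.mark.parametrize("other", ["sagittal", "horizontal"])
    def test_plane_separation_on_epoch_average(self, other):
        # a coronal-plane rotation leaves no epoch-average footprint in the
        # other planes (per-target leakage cancels over the 8 cube corners)
        pert = synth_trajectories(24, 30.0, "coronal", noise_sd=0.0, seed=23)
        run = process_trajectories(pert, other)
        assert np.all(np.abs(run.y) < 1.0)
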