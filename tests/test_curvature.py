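"""Rotation, monotonic resampling, normalization, sign convention and the
median-angular-deviation curvature statistic."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from saccurve.core import GazeTrace, Saccade
from saccurve.curvature import (MonotonicProfile, NormalizedTrajectory,
                                RotatedTrajectory, apply_sign_convention,
                                average_profile, curvature_angle,
                                curvature_from_points, monotonic_resample,
                                normalize_trajectory, rotate_to_upward)
from saccurve.synth import bump_height, curved_saccade_path

FIXTURE = np.array([[0, 0], [0.5, 2.5], [1, 5], [0.5, 7.5], [0, 10]], float)


class TestCurvatureStatistic:
    def test_brute_force_fixture(self):
        """Median of per-point arctangents: 11.31, 11.31, 3.81 -> 11.31."""
        assert curvature_from_points(FIXTURE) == pytest.approx(11.31, abs=0.005)

    def test_points_on_chord_give_zero(self):
        pts = np.column_stack([np.zeros(20), np.linspace(0, 10, 20)])
        assert curvature_from_points(pts) == 0.0

    def test_odd_symmetry_of_fixture(self):
        mirrored = FIXTURE * np.array([-1, 1])
        assert curvature_from_points(mirrored) == pytest.approx(-11.31, abs=0.005)

    def test_degenerate_chord_rejected(self):
        pts = np.tile([1.0, 1.0], (6, 1))
        with pytest.raises(ValueError):
            curvature_from_points(pts)

    @given(angle=st.floats(-np.pi, np.pi), tx=st.floats(-20, 20), ty=st.floats(-20, 20))
    def test_rigid_invariance(self, angle, tx, ty):
        """Translating and rotating the scene leaves the statistic unchanged."""
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s], [s, c]])
        moved = FIXTURE @ R.T + [tx, ty]
        assert curvature_from_points(moved) == pytest.approx(
            curvature_from_points(FIXTURE), abs=1e-9)

    @given(curv=st.floats(-10, 10))
    def test_generator_statistic_consistency(self, curv):
        xy = curved_saccade_path((0, 0), (0, 15), curv, 54)
        assert curvature_from_points(xy) == pytest.approx(curv, abs=0.05)


def _upward_trace(curv=3.0, amplitude=15.0, duration=54):
    xy = curved_saccade_path((0, 0), (0, amplitude), curv, duration)
    t = np.arange(len(xy), dtype=float)
    return GazeTrace(0, t, xy), Saccade(0.0, t[-1], xy[0], xy[-1])


class TestRotateToUpward:
    def test_upward_saccade_maps_to_identity(self):
        trace, sac = _upward_trace()
        rot = rotate_to_upward(sac, trace)
        assert np.allclose(rot.along, trace.xy[:, 1], atol=1e-12)
        assert np.allclose(rot.ortho, trace.xy[:, 0], atol=1e-12)

    def test_downward_saccade_along_increases(self):
        xy = curved_saccade_path((0, 0), (0, -15), 2.0, 54)
        t = np.arange(len(xy), dtype=float)
        sac = Saccade(0.0, t[-1], xy[0], xy[-1])
        rot = rotate_to_upward(sac, GazeTrace(0, t, xy))
        assert rot.along[0] < rot.along[-1]
        assert rot.along[-1] == pytest.approx(15.0)

    def test_straight_saccade_any_direction_has_zero_ortho(self):
        xy = curved_saccade_path((2, -3), (-7, 6), 0.0, 47)
        t = np.arange(len(xy), dtype=float)
        sac = Saccade(0.0, t[-1], xy[0], xy[-1])
        rot = rotate_to_upward(sac, GazeTrace(0, t, xy))
        assert np.allclose(rot.ortho, 0, atol=1e-12)

    def test_too_few_samples_rejected(self):
        xy = np.array([[0, 0], [0, 5], [0, 10]], float)
        trace = GazeTrace(0, np.arange(3.0), xy)
        with pytest.raises(ValueError):
            rotate_to_upward(Saccade(0.0, 2.0, xy[0], xy[-1]), trace)


class TestMonotonicResample:
    def test_straight_path_gives_zero_profile(self):
        trace, sac = _upward_trace(curv=0.0)
        prof = monotonic_resample(rotate_to_upward(sac, trace), 50)
        assert np.allclose(prof.ortho_mean, 0, atol=1e-12)
        assert (np.diff(prof.grid) > 0).all()

    def test_overshoot_still_yields_monotonic_grid(self):
        """Along-axis progress that doubles back (dynamic overshoot) must
        still produce a strictly increasing grid."""
        along = np.concatenate([np.linspace(0, 16, 40), np.linspace(16, 15, 10)])
        ortho = np.sin(np.pi * along / 15) * 0.5
        rot = RotatedTrajectory(along, ortho, 15.0)
        prof = monotonic_resample(rot, 30)
        assert (np.diff(prof.grid) > 0).all()

    def test_sine_bump_reproduced(self):
        h = bump_height(4.0, 15.0)
        trace, sac = _upward_trace(curv=4.0)
        prof = monotonic_resample(rotate_to_upward(sac, trace), 50)
        expected = h * np.sin(np.pi * prof.grid / 15.0)
        assert np.allclose(prof.ortho_mean, expected, atol=h * 0.02)

    def test_zero_amplitude_rejected(self):
        rot = RotatedTrajectory(np.linspace(0, 1, 20), np.zeros(20), 0.0)
        with pytest.raises(ValueError):
            monotonic_resample(rot, 10)


class TestNormalization:
    def _profile(self, values, amplitude=15.0):
        n = len(values)
        grid = (np.arange(n) + 0.5) * amplitude / n
        return MonotonicProfile(grid, np.asarray(values, float), amplitude)

    def test_trial_equal_to_baseline_is_flat(self):
        p = self._profile(np.sin(np.linspace(0, np.pi, 50)))
        norm = normalize_trajectory(p, p)
        assert np.allclose(norm.ortho_norm, 0)

    def test_additivity_removes_constant_bias(self):
        bump = np.sin(np.linspace(0, np.pi, 50))
        trial = self._profile(bump + 0.3)
        base = self._profile(np.full(50, 0.3))
        norm = normalize_trajectory(trial, base)
        assert np.allclose(norm.ortho_norm, bump, atol=1e-12)

    def test_mismatched_grids_are_regridded(self):
        trial = self._profile(np.linspace(0, 1, 50))
        base = self._profile(np.linspace(0, 1, 25))
        norm = normalize_trajectory(trial, base)
        assert np.allclose(norm.ortho_norm, 0, atol=0.03)

    def test_average_profile_rejects_empty(self):
        with pytest.raises(ValueError):
            average_profile([])


class TestSignConvention:
    def _norm(self, values):
        n = len(values)
        grid = (np.arange(n) + 0.5) * 15.0 / n
        return NormalizedTrajectory(grid, np.asarray(values, float), 15.0)

    def test_clockwise_unchanged(self):
        traj = self._norm(np.ones(20))
        out = apply_sign_convention(traj, "clockwise")
        assert np.allclose(out.ortho_norm, 1.0)

    def test_counterclockwise_negated(self):
        traj = self._norm(np.ones(20))
        out = apply_sign_convention(traj, "counterclockwise")
        assert np.allclose(out.ortho_norm, -1.0)

    def test_unknown_rotation_rejected(self):
        with pytest.raises(ValueError):
            apply_sign_convention(self._norm(np.ones(20)), "widdershins")

    def test_mirrored_physics_identical_after_convention(self):
        """A clockwise trial and its mirror-image counterclockwise twin
        carry the same signed curvature."""
        cw_path = curved_saccade_path((0, 0), (0, 15), -2.0, 54)
        ccw_path = cw_path * np.array([-1, 1])   # mirror across the midline
        for path, rotation in ((cw_path, "clockwise"), (ccw_path, "counterclockwise")):
            t = np.arange(len(path), dtype=float)
            sac = Saccade(0.0, t[-1], path[0], path[-1])
            prof = monotonic_resample(rotate_to_upward(sac, GazeTrace(0, t, path)), 50)
            norm = NormalizedTrajectory(prof.grid, prof.ortho_mean, prof.amplitude)
            signed = curvature_angle(apply_sign_convention(norm, rotation))
            assert signed == pytest.approx(-2.0, abs=0.05)


def test_curvature_angle_needs_interior_points():
    traj = NormalizedTrajectory(np.array([0.1, 7.5, 14.9]), np.zeros(3), 15.0)
    with pytest.raises(ValueError):
        curvature_angle(traj, margin=0.4)
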