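"""Synthetic-experiment generator: path calibration, trial structure,
determinism, and artifact plumbing."""
import numpy as np
import pytest

from saccurve.config import ArtifactRates, SimulationConfig
from saccurve.core import SEQUENCES
from saccurve.curvature import curvature_from_points
from saccurve.detection import compute_velocity, detect_saccades
from saccurve.io import events_to_frame, traces_to_frame, truth_to_frame
from saccurve.synth import curved_saccade_path, simulate_experiment

from conftest import make_events, make_trial


class TestCurvedPath:
    def test_straight_path_is_collinear(self):
        xy = curved_saccade_path((0, 0), (0, 15), 0.0, 60)
        assert np.allclose(xy[:, 0], 0)
        assert abs(curvature_from_points(xy)) < 1e-12

    @pytest.mark.parametrize("curv", [-10, -5, -1, 0.5, 5, 10])
    def test_requested_curvature_recovered_by_reference_statistic(self, curv):
        xy = curved_saccade_path((0, 0), (0, 15), curv, 60)
        assert curvature_from_points(xy) == pytest.approx(curv, abs=0.05)

    def test_mirror_gives_opposite_sign(self):
        plus = curved_saccade_path((0, 0), (0, 15), 5.0, 60)
        minus = curved_saccade_path((0, 0), (0, 15), -5.0, 60)
        assert curvature_from_points(minus) == pytest.approx(
            -curvature_from_points(plus), abs=1e-9)

    def test_endpoints_and_monotonic_progress(self):
        start, end = np.array([3.0, -2.0]), np.array([-5.0, 9.0])
        xy = curved_saccade_path(start, end, 4.0, 45)
        assert np.allclose(xy[0], start) and np.allclose(xy[-1], end)
        d = (end - start) / np.linalg.norm(end - start)
        along = (xy - start) @ d
        assert (np.diff(along) > 0).all()

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError, match="zero-amplitude"):
            curved_saccade_path((1, 1), (1, 1), 3.0, 60)


class TestSimulateTrial:
    def test_no_effects_gives_straight_second_saccade(self, quiet_sim, rng):
        ev = make_events(modality="none")
        trace, gt = make_trial(ev, quiet_sim, rng)
        seg = trace.window(gt.onset2_ms, gt.offset2_ms)
        assert abs(curvature_from_points(seg.xy)) < 1e-9

    def test_injected_effect_recovered_over_trials(self, quiet_sim, rng):
        """Ground-truth oracle: mean measured curvature of inter-saccadic
        trials matches the injected effect within 2 SEM."""
        quiet_sim.effect_map = {("visual", "inter_saccadic"): -3.0}
        vals = []
        for i in range(200):
            rot = "clockwise" if i % 2 == 0 else "counterclockwise"
            dx = 7.5 if rot == "clockwise" else -7.5
            ev = make_events(trial_id=i, dx=dx, onset=290.0)
            trace, gt = make_trial(ev, quiet_sim, rng)
            if gt.interval_truth != "inter_saccadic":
                continue
            seg = trace.window(gt.onset2_ms, gt.offset2_ms)
            sign = 1.0 if rot == "clockwise" else -1.0
            vals.append(sign * curvature_from_points(seg.xy))
        vals = np.asarray(vals)
        assert len(vals) > 100
        sem = max(vals.std(ddof=1) / np.sqrt(len(vals)), 1e-6)
        assert abs(vals.mean() + 3.0) <= max(2 * sem, 0.01)

    def test_forced_blink_leaves_gap(self, quiet_sim, rng):
        for i in range(10):
            ev = make_events(trial_id=i)
            trace, gt = make_trial(ev, quiet_sim, rng, blink=True)
            assert np.isnan(trace.xy).any()
            assert gt.blink

    def test_noise_neutrality_of_straight_saccades(self, quiet_sim, rng):
        """Isotropic position noise does not bias the curvature of straight
        saccades (within 3 standard errors over >= 500 trials)."""
        quiet_sim.noise_sd_deg = 0.05
        vals = []
        for i in range(500):
            ev = make_events(trial_id=i, modality="none")
            trace, gt = make_trial(ev, quiet_sim, rng)
            seg = trace.window(gt.onset2_ms, gt.offset2_ms)
            vals.append(curvature_from_points(seg.xy))
        vals = np.asarray(vals)
        assert abs(vals.mean()) <= 3 * vals.std(ddof=1) / np.sqrt(vals.size)


class TestSimulateExperiment:
    def test_same_seed_reproduces_tables_exactly(self):
        sim = SimulationConfig(n_participants=2, trials_per_cell=3, seed=42)
        a = simulate_experiment(sim)
        b = simulate_experiment(sim)
        assert traces_to_frame(a[0]).equals(traces_to_frame(b[0]))
        assert events_to_frame(a[1]).equals(events_to_frame(b[1]))
        assert truth_to_frame(a[2]).equals(truth_to_frame(b[2]))

    def test_row_counts_match_design_product(self):
        sim = SimulationConfig(n_participants=3, trials_per_cell=4,
                               artifact_rates=ArtifactRates(blink=0.5))
        traces, events, truths = simulate_experiment(sim)
        n_none = round(len(sim.modalities) * 2 * 4 / 3)
        expected = 3 * (len(sim.modalities) * 2 * len(SEQUENCES) * 4
                        + len(SEQUENCES) * n_none)
        # artifacts flag trials, they never drop rows
        assert len(traces) == len(events) == len(truths) == expected

    def test_distractor_onsets_within_configured_range(self):
        sim = SimulationConfig(n_participants=1, trials_per_cell=5,
                               distractor_onset_range_ms=(-100, 300))
        _, events, _ = simulate_experiment(sim)
        onsets = [ev.distractor_onset_ms for ev in events if ev.has_distractor]
        assert min(onsets) >= -100 and max(onsets) <= 300

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_participants=0)
        with pytest.raises(ValueError):
            SimulationConfig(trials_per_cell=-1)

    def test_both_timing_cells_populated(self):
        """Under the default latency model the distractors reliably fall
        both before the first and between the two saccades."""
        sim = SimulationConfig(n_participants=2, trials_per_cell=6, seed=7)
        _, _, truths = simulate_experiment(sim)
        labels = {t.interval_truth for t in truths}
        assert {"pre_saccadic", "inter_saccadic"} <= labels

    def test_blinks_survive_velocity_and_detection(self, quiet_sim, rng):
        ev = make_events()
        trace, _ = make_trial(ev, quiet_sim, rng, blink=True)
        vel = compute_velocity(trace)
        assert np.isnan(vel.v).sum() > 50  # gap propagates as undefined speed
        detect_saccades(vel)  # runs never cross the gap
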