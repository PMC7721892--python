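"""Synthetic double-step saccade experiments with known ground truth.

The generator emulates the recording conditions the analysis assumes: 1 kHz
gaze traces of a horizontal saccade to the screen center followed by a
vertical saccade to the second target, with per-participant idiosyncratic
trajectory curvature, distractor-evoked curvature of configurable magnitude
per modality and timing interval, truncated-Gaussian latencies, isotropic
Gaussian position noise, and injectable artifacts (blinks, fixation breaks,
inaccurate landings) to exercise the selection filters.

Curvature is injected as a single orthogonal sine bump whose height is
calibrated against the curvature-angle statistic; independent curvature
components (idiosyncrasy, distractor effect) superpose in deviation space.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .config import ApparatusConfig, SelectionCriteria, SimulationConfig
from .core import SEQUENCES, GazeTrace, GroundTruthRecord, TrialEvents
from .curvature import curvature_from_points
from .selection import classify_interval_times, distractor_rotation

PRE_TRACE_MS = 300.0    # recorded fixation time before targets onset
POST_TRACE_MS = 100.0   # recorded time after the second saccade offset


def bump_height(curvature_deg: float, length: float) -> float:
    """Orthogonal sine-bump height yielding the requested curvature angle.

    The per-point deviation angle of the bump ``h*sin(pi*s)`` is monotone in
    the normalized progress ``s``, and saccade sample points are symmetric
    about ``s = 0.5``, so the median angle is the one at mid-chord:
    ``atan(2h / length)``.  Inverting gives ``h = length * tan(angle) / 2``.
    """
    return length * np.tan(np.radians(curvature_deg)) / 2.0


def _progress(n: int) -> np.ndarray:
    """Raised-cosine speed profile: normalized along-path progress at each
    of ``n + 1`` uniformly spaced sample times."""
    tau = np.arange(n + 1) / n
    return tau - np.sin(2 * np.pi * tau) / (2 * np.pi)


def saccade_path(start, end, height: float, duration_ms: float,
                 rate_hz: float) -> Tuple[np.ndarray, np.ndarray]:
    """Sample a saccade from ``start`` to ``end`` with an orthogonal sine
    bump of the given height (positive = clockwise side of the chord).

    Returns (t_ms relative to onset, xy samples).  Along-chord progress is
    monotonic by construction (raised-cosine speed profile).
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    chord = end - start
    length = np.hypot(*chord)
    if length <= 0:
        raise ValueError("zero-amplitude saccade (start == end)")
    if duration_ms < 10:
        raise ValueError("saccade duration must be >= 10 ms")
    n = max(int(round(duration_ms * rate_hz / 1000.0)), 5)
    s = _progress(n)
    d = chord / length
    u = np.array([d[1], -d[0]])        # maps to +ortho after rotation upward
    xy = start + np.outer(s * length, d) + np.outer(height * np.sin(np.pi * s), u)
    t = np.arange(n + 1) * (1000.0 / rate_hz)
    return t, xy


def curved_saccade_path(start, end, curvature_deg: float, duration_ms: float,
                        rate_hz: float = 1000.0) -> np.ndarray:
    """Path whose curvature-angle statistic equals ``curvature_deg``.

    The noiseless path, fed back through :func:`curvature_from_points`,
    returns the requested angle within 0.05 deg.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    length = np.hypot(*(end - start))
    if length <= 0:
        raise ValueError("zero-amplitude saccade (start == end)")
    _, xy = saccade_path(start, end, bump_height(curvature_deg, length),
                         duration_ms, rate_hz)
    return xy


@dataclass
class ParticipantParams:
    """Idiosyncratic baseline curvature (deg) per saccade sequence.

    The baseline sign convention is the rotated-upward frame: positive
    curvature bulges toward the side a clockwise distractor would occupy.
    """

    participant: str
    baseline_deg: Dict[str, float]


def _trunc_normal(rng, mean, sd, lo, hi) -> float:
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _distractor_position(target2_dir: str, rotation: str, offset: float) -> Tuple[float, float]:
    sy = 1.0 if target2_dir == "up" else -1.0
    # clockwise of 'up' is the right quadrant; mirrored for 'down'
    sx = sy if rotation == "clockwise" else -sy
    return (sx * offset, sy * offset)


def simulate_trial(events: TrialEvents, params: ParticipantParams,
                   rng: np.random.Generator,
                   sim: SimulationConfig,
                   apparatus: ApparatusConfig | None = None,
                   criteria: SelectionCriteria | None = None,
                   blink: bool = False, fixation_break: bool = False,
                   landing_error: bool = False,
                   ) -> Tuple[GazeTrace, GroundTruthRecord]:
    """Generate one trial's gaze trace and its ground-truth record."""
    apparatus = apparatus or ApparatusConfig()
    criteria = criteria or SelectionCriteria()
    ecc = apparatus.target_eccentricity_deg
    rate = apparatus.sampling_rate_hz
    dt = apparatus.dt_ms
    lat = sim.latency
    kin = sim.kinematics

    mean1, mean2 = lat.means.get(events.distractor_modality, lat.means["none"])
    onset1 = _trunc_normal(rng, mean1, lat.sd_first_ms, lat.min_first_ms, lat.cap_first_ms)
    onset1 = round(onset1)

    fix = events.fixation_pos(ecc)
    center = np.zeros(2)
    if landing_error:
        ang = rng.uniform(0, 2 * np.pi)
        landing1 = center + rng.uniform(4.0, 6.0) * np.array([np.cos(ang), np.sin(ang)])
    else:
        landing1 = center + rng.normal(0, sim.landing_sd_deg, 2)
    amp1 = float(np.hypot(*(landing1 - fix)))
    dur1 = max(round(kin.duration_ms(amp1)), 10)
    offset1 = onset1 + dur1

    lo2 = max(offset1 + lat.min_second_gap_ms, 0.0)
    onset2 = round(_trunc_normal(rng, mean2, lat.sd_second_ms, lo2, lat.cap_second_ms))
    target2 = events.target2_pos(ecc)
    landing2 = target2 + rng.normal(0, sim.landing_sd_deg, 2)
    amp2 = float(np.hypot(*(landing2 - landing1)))
    dur2 = max(round(kin.duration_ms(amp2)), 10)
    offset2 = onset2 + dur2

    # distractor-evoked curvature, decided by where the true timing falls
    effect = 0.0
    interval = "no_distractor"
    rotation = "none"
    if events.has_distractor:
        rotation = distractor_rotation(events)
        interval = classify_interval_times(
            events.distractor_onset_ms, events.distractor_offset_ms,
            onset1, offset1, onset2,
            pre_window=criteria.pre_window_ms, inter_gap=criteria.inter_gap_ms)
        if interval == "inter_saccadic":
            effect = sim.effect_map.get((events.distractor_modality, "inter_saccadic"), 0.0)
        elif interval == "pre_saccadic":
            same_side = events.distractor_x_deg * fix[0] > 0
            key = "pre_saccadic_inter" if same_side else "pre_saccadic_intra"
            effect = sim.effect_map.get((events.distractor_modality, key), 0.0)

    baseline = params.baseline_deg.get(events.sequence, 0.0)
    trial_curv = float(rng.normal(0, sim.trial_curvature_sd_deg)) \
        if sim.trial_curvature_sd_deg > 0 else 0.0
    sign_cw = 1.0 if rotation != "counterclockwise" else -1.0
    height = bump_height(baseline + trial_curv, amp2) \
        + sign_cw * bump_height(effect, amp2)

    t = np.arange(-PRE_TRACE_MS, offset2 + POST_TRACE_MS + dt / 2, dt)
    xy = np.empty((t.size, 2))
    xy[:] = fix
    i1 = np.searchsorted(t, onset1)
    t1, path1 = saccade_path(fix, landing1, 0.0, dur1, rate)
    xy[i1:i1 + path1.shape[0]] = path1
    xy[i1 + path1.shape[0]:] = landing1
    i2 = np.searchsorted(t, onset2)
    t2, path2 = saccade_path(landing1, landing2, height, dur2, rate)
    xy[i2:i2 + path2.shape[0]] = path2
    xy[i2 + path2.shape[0]:] = landing2

    if fixation_break:
        m = (t >= -220) & (t <= -120)
        xy[m] += np.array([apparatus.fixation_radius_deg + 2.0, 0.0])
    if sim.noise_sd_deg > 0:
        xy = xy + rng.normal(0, sim.noise_sd_deg, xy.shape)
    if blink:
        gap = rng.integers(80, 151)
        g0 = rng.integers(int(onset1) - 50, int(offset2) - gap)
        xy[(t >= g0) & (t < g0 + gap)] = np.nan

    trace = GazeTrace(events.trial_id, t, xy)
    truth = GroundTruthRecord(
        trial_id=events.trial_id, participant=events.participant,
        sequence=events.sequence, rotation=rotation,
        onset1_ms=float(onset1), offset1_ms=float(offset1),
        onset2_ms=float(onset2), offset2_ms=float(offset2),
        baseline_curvature_deg=baseline, effect_curvature_deg=effect,
        trial_curvature_deg=trial_curv,
        interval_truth=interval, blink=blink,
        fixation_break=fixation_break, landing_error=landing_error)
    return trace, truth


def _onset_subranges(sim: SimulationConfig, apparatus: ApparatusConfig,
                     modality: str) -> Dict[str, Tuple[int, int]]:
    """Integer-ms distractor-onset subranges aimed at the two timing cells.

    Both lie inside the experiment's global onset interval; the intended
    class is only a stratification device — the true class is always read
    off the realized saccade times.
    """
    lo, hi = sim.distractor_onset_range_ms
    mean1, mean2 = sim.latency.means[modality]
    dur1 = sim.kinematics.duration_ms(apparatus.target_eccentricity_deg)
    d = sim.distractor_duration_ms
    pre = (max(lo, mean1 - 150 - d + 10), min(hi, mean1 - d - 10))
    inter = (max(lo, mean1 + 2 * sim.latency.sd_first_ms + dur1), min(hi, mean2 - 150))
    return {"pre": (round(pre[0]), round(pre[1])),
            "inter": (round(inter[0]), round(inter[1]))}


def simulate_experiment(sim: SimulationConfig,
                        apparatus: ApparatusConfig | None = None,
                        criteria: SelectionCriteria | None = None,
                        ) -> Tuple[List[GazeTrace], List[TrialEvents], List[GroundTruthRecord]]:
    """Generate a full experiment: per participant, ``trials_per_cell``
    trials for every (modality x intended timing x sequence) cell plus
    ``trials_per_cell`` distractor-absent trials per sequence.

    Clockwise/counterclockwise distractors alternate within each cell.
    Artifacts only flag trials (via the ground-truth record); no rows are
    dropped.  Identical configs and seeds give identical output.
    """
    apparatus = apparatus or ApparatusConfig()
    criteria = criteria or SelectionCriteria()
    rng = np.random.default_rng(sim.seed)
    d_off = apparatus.distractor_offset_deg

    traces: List[GazeTrace] = []
    events_all: List[TrialEvents] = []
    truths: List[GroundTruthRecord] = []
    trial_id = 0
    for p in range(sim.n_participants):
        name = f"p{p + 1:02d}"
        params = ParticipantParams(
            participant=name,
            baseline_deg={seq: float(rng.normal(0, sim.idiosyncrasy_sd_deg))
                          for seq in SEQUENCES})
        plan: List[TrialEvents] = []
        for modality in sim.modalities:
            ranges = _onset_subranges(sim, apparatus, modality)
            for intent in ("pre", "inter"):
                o_lo, o_hi = ranges[intent]
                for seq in SEQUENCES:
                    side, t2dir = seq.split("-")
                    for i in range(sim.trials_per_cell):
                        rot = "clockwise" if i % 2 == 0 else "counterclockwise"
                        dx, dy = _distractor_position(t2dir, rot, d_off)
                        onset = int(rng.integers(o_lo, o_hi + 1))
                        plan.append(TrialEvents(
                            trial_id=-1, participant=name, fixation_side=side,
                            target2_dir=t2dir, distractor_modality=modality,
                            distractor_x_deg=dx, distractor_y_deg=dy,
                            distractor_onset_ms=float(onset),
                            distractor_duration_ms=sim.distractor_duration_ms))
        # distractor-absent trials make up 1/4 of the experiment (they are
        # the normalization baseline): one third of the distractor total
        n_none = max(sim.trials_per_cell,
                     round(len(sim.modalities) * 2 * sim.trials_per_cell / 3))
        for seq in SEQUENCES:
            side, t2dir = seq.split("-")
            for _ in range(n_none):
                plan.append(TrialEvents(
                    trial_id=-1, participant=name, fixation_side=side,
                    target2_dir=t2dir, distractor_modality="none"))
        for ev in plan:
            ev.trial_id = trial_id
            trial_id += 1
            rates = sim.artifact_rates
            trace, truth = simulate_trial(
                ev, params, rng, sim, apparatus, criteria,
                blink=rng.random() < rates.blink,
                fixation_break=rng.random() < rates.fixation_break,
                landing_error=rng.random() < rates.landing_error)
            traces.append(trace)
            events_all.append(ev)
            truths.append(truth)
    return traces, events_all, truths
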