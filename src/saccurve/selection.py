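"""Trial inclusion filters and distractor classification.

A valid trial requires: fixation held near the fixation target before the
targets appeared, a first saccade from the fixation target landing near the
screen center, a second saccade from the center landing near the second
target, latencies under the online caps, and no blink.  Distractor-present
valid trials are then partitioned by timing into pre-saccadic,
inter-saccadic, or excluded, and pre-saccadic trials by whether the first
saccade carries the distractor's eye-centered representation across the
vertical meridian (inter-hemifield) or not (intra-hemifield).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import ApparatusConfig, SelectionCriteria
from .core import GazeTrace, Saccade, TrialEvents

REJECTION_REASONS = (
    "blink", "fixation_break", "first_start_error", "landing_error",
    "late_first_saccade", "second_start_error", "second_landing_error",
    "late_second_saccade", "too_few_saccades", "missing_center_saccade",
    "missing_second_saccade",
)


@dataclass
class TrialClassification:
    trial_id: int
    valid: bool
    reason: Optional[str] = None           # exactly one primary cause when invalid
    interval: str = "not_applicable"       # pre_saccadic | inter_saccadic | excluded | no_distractor
    hemifield: str = "not_applicable"      # inter | intra (pre-saccadic trials only)
    rotation: str = "none"                 # clockwise | counterclockwise


def validate_trial(events: TrialEvents, first: Saccade, second: Saccade,
                   criteria: SelectionCriteria,
                   trace: Optional[GazeTrace] = None,
                   apparatus: Optional[ApparatusConfig] = None,
                   ) -> TrialClassification:
    """Apply the inclusion filters; every failure becomes a reason, checked
    in a fixed order so an invalid trial carries one primary cause."""
    apparatus = apparatus or ApparatusConfig()
    ecc = apparatus.target_eccentricity_deg
    fix = events.fixation_pos(ecc)
    center = np.zeros(2)
    target2 = events.target2_pos(ecc)

    def fail(reason: str) -> TrialClassification:
        return TrialClassification(events.trial_id, valid=False, reason=reason)

    if trace is not None:
        if np.isnan(trace.xy).any():
            return fail("blink")
        hold = (trace.t >= -criteria.fixation_hold_ms) & (trace.t < 0)
        if hold.any():
            dist = np.hypot(*(trace.xy[hold] - fix).T)
            if (dist > criteria.fixation_radius_deg).any():
                return fail("fixation_break")
    if np.hypot(*(first.start - fix)) > criteria.fixation_radius_deg:
        return fail("first_start_error")
    if np.hypot(*(first.end - center)) > criteria.landing_radius_deg:
        return fail("landing_error")
    if first.latency > criteria.max_latency_first_ms:
        return fail("late_first_saccade")
    if np.hypot(*(second.start - center)) > criteria.fixation_radius_deg:
        return fail("second_start_error")
    if np.hypot(*(second.end - target2)) > criteria.landing_radius_deg:
        return fail("second_landing_error")
    if second.latency > criteria.max_latency_second_ms:
        return fail("late_second_saccade")
    return TrialClassification(events.trial_id, valid=True)


def classify_interval_times(d_onset: float, d_offset: float,
                            onset1: float, offset1: float, onset2: float,
                            pre_window: float = 150.0,
                            inter_gap: float = 100.0) -> str:
    """Timing partition on one clock (ms from targets onset).

    pre-saccadic:   distractor offset in [onset1 - pre_window, onset1)
    inter-saccadic: distractor onset after offset1 AND offset at most
                    (onset2 - inter_gap)
    excluded otherwise (e.g. late distractors, or ones still on at the first
    saccade onset).
    """
    if d_offset < d_onset:
        raise ValueError("distractor offset precedes its onset")
    if onset1 - pre_window <= d_offset < onset1:
        return "pre_saccadic"
    if d_onset > offset1 and d_offset <= onset2 - inter_gap:
        return "inter_saccadic"
    return "excluded"


def classify_distractor_interval(events: TrialEvents, first: Saccade,
                                 second: Saccade,
                                 criteria: SelectionCriteria) -> str:
    if not events.has_distractor:
        return "no_distractor"
    return classify_interval_times(
        events.distractor_onset_ms, events.distractor_offset_ms,
        first.onset_t, first.offset_t, second.onset_t,
        pre_window=criteria.pre_window_ms, inter_gap=criteria.inter_gap_ms)


def classify_hemifield(events: TrialEvents,
                       apparatus: Optional[ApparatusConfig] = None) -> str:
    """inter: distractor horizontally between fixation and screen center
    (same side as fixation, so the first saccade moves its eye-centered
    trace into the opposite hemifield); intra: on the far side."""
    apparatus = apparatus or ApparatusConfig()
    fx = events.fixation_pos(apparatus.target_eccentricity_deg)[0]
    dx = events.distractor_x_deg
    if dx == 0 or not np.isfinite(dx):
        raise ValueError("distractor on the vertical midline has no hemifield")
    return "inter" if dx * fx > 0 else "intra"


def eye_distractor_eccentricity(fixation, distractor) -> float:
    """Planar distance in screen-degree coordinates (the bookkeeping the
    analysis uses; an approximation to the true angular separation)."""
    fixation = np.asarray(fixation, dtype=float)
    distractor = np.asarray(distractor, dtype=float)
    return float(np.hypot(*(distractor - fixation)))


def angular_separation(p, q, viewing_distance_cm: float = 76.5) -> float:
    """True visual angle (deg) between two screen positions given in degree
    coordinates (each axis value is the visual angle along that axis)."""
    def ray(pt):
        x, y = np.radians(np.asarray(pt, dtype=float))
        v = np.array([np.tan(x), np.tan(y), 1.0])
        return v / np.linalg.norm(v)
    cosang = np.clip(ray(p) @ ray(q), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def distractor_rotation(events: TrialEvents) -> str:
    """Side of the distractor relative to the second-saccade target, from
    the signed angle about the screen center: negative (clockwise) or
    positive (counterclockwise)."""
    if not events.has_distractor:
        raise ValueError("no distractor in this trial")
    t2 = events.target2_pos(1.0)
    d = events.distractor_pos
    cross = t2[0] * d[1] - t2[1] * d[0]
    if cross == 0 or not np.isfinite(cross):
        raise ValueError("distractor collinear with the second-saccade target")
    return "clockwise" if cross < 0 else "counterclockwise"
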