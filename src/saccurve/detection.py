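"""Velocity-threshold saccade detection.

Gaze speed is the norm of boxcar-smoothed centered finite differences
(moving average over ``window`` samples).  A saccade is a maximal run of
samples whose smoothed speed exceeds

    threshold = median(speed) + k * spread(speed)

for at least ``min_duration_ms``, where the spread is by default the robust
(median-absolute-deviation) estimate over the trial.  The threshold is
floored so that recordings with vanishing velocity spread do not trigger on
arbitrarily slow drift.  Blink gaps propagate as undefined speed and can
never be part of a detected event.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .config import ApparatusConfig, DetectionParams
from .core import GazeTrace, Saccade, TrialEvents

MAD_TO_SD = 1.4826  # normal-consistency factor


@dataclass
class VelocityTrace:
    t: np.ndarray
    v: np.ndarray             # smoothed speed, deg/s; NaN where undefined
    source: GazeTrace


class AssignmentError(ValueError):
    """Trial cannot be mapped onto the two task saccades."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def compute_velocity(trace: GazeTrace, params: DetectionParams | None = None) -> VelocityTrace:
    """Smoothed gaze speed: centered differences of position, boxcar-averaged
    componentwise over the window, then the Euclidean norm."""
    params = params or DetectionParams()
    dt_s = trace.dt / 1000.0
    n = trace.t.size
    if n < params.window + 2:
        raise ValueError("trace shorter than the smoothing window")
    diff = np.full_like(trace.xy, np.nan)
    diff[1:-1] = (trace.xy[2:] - trace.xy[:-2]) / (2.0 * dt_s)
    kernel = np.ones(params.window) / params.window
    sm = np.column_stack([np.convolve(diff[:, c], kernel, mode="same")
                          for c in (0, 1)])
    v = np.hypot(sm[:, 0], sm[:, 1])
    return VelocityTrace(t=trace.t, v=v, source=trace)


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2] - 1))


def detect_saccades(vel: VelocityTrace, params: DetectionParams | None = None) -> List[Saccade]:
    params = params or DetectionParams()
    v = vel.v
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("velocity undefined over the whole trial")
    med = float(np.median(v[finite]))
    if params.robust:
        spread = MAD_TO_SD * float(np.median(np.abs(v[finite] - med)))
    else:
        spread = float(np.std(v[finite]))
    threshold = max(med + params.k * spread, params.floor_deg_s)

    dt = vel.source.dt
    above = np.zeros(v.size, dtype=bool)
    above[finite] = v[finite] > threshold
    runs = _runs(above)
    merged: List[Tuple[int, int]] = []
    for run in runs:
        if merged and (run[0] - merged[-1][1] - 1) * dt < params.merge_gap_ms \
                and finite[merged[-1][1]:run[0] + 1].all():
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    out: List[Saccade] = []
    xy = vel.source.xy
    for i0, i1 in merged:
        if (i1 - i0 + 1) * dt < params.min_duration_ms:
            continue
        j = min(i1 + 1, v.size - 1)  # first sample back below threshold
        out.append(Saccade(onset_t=float(vel.t[i0]), offset_t=float(vel.t[j]),
                           start=xy[i0], end=xy[j]))
    return out


def assign_sequence(saccades: List[Saccade], events: TrialEvents,
                    apparatus: ApparatusConfig | None = None) -> Tuple[Saccade, Saccade]:
    """Pick the two task saccades of the double-step sequence.

    The first is the earliest saccade leaving the fixation target and
    landing near the screen center; the second the earliest later saccade
    leaving the center with at least half the target eccentricity.  Small
    corrective movements are ignored; trials without a geometrically
    consistent pair raise :class:`AssignmentError` with a reason.
    """
    apparatus = apparatus or ApparatusConfig()
    ecc = apparatus.target_eccentricity_deg
    r = apparatus.fixation_radius_deg
    loose = ecc / 2   # geometric gate only; the strict radii live in validation
    if len(saccades) < 1:
        raise AssignmentError("too_few_saccades")
    fix = events.fixation_pos(ecc)
    center = np.zeros(2)
    ordered = sorted(saccades, key=lambda s: s.onset_t)
    first = next(
        (s for s in ordered
         if np.hypot(*(s.start - fix)) <= r
         and np.hypot(*(s.end - center)) <= loose
         and s.amplitude >= loose), None)
    if first is None:
        raise AssignmentError("missing_center_saccade")
    second = next(
        (s for s in ordered
         if s.onset_t >= first.offset_t
         and np.hypot(*(s.start - center)) <= loose
         and s.amplitude >= loose), None)
    if second is None:
        raise AssignmentError("missing_second_saccade")
    return first, second
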