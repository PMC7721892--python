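"""Core containers for gaze data and experimental events.

Coordinate convention: screen-centered degrees of visual angle, x positive
rightward, y positive upward.  Time is in milliseconds relative to the onset
of the saccade targets (t = 0), sampled on a uniform grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SEQUENCES = ("left-up", "left-down", "right-up", "right-down")
MODALITIES = ("visual", "auditory", "audiovisual")


@dataclass
class GazeTrace:
    """One trial's time-stamped 2-D gaze samples.

    ``xy`` has shape (n, 2); blink dropouts are runs of NaN samples.
    """

    trial_id: int
    t: np.ndarray          # ms, uniform grid, int-valued
    xy: np.ndarray         # (n, 2) degrees, screen centered

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n, 2)")
        if self.t.shape[0] != self.xy.shape[0]:
            raise ValueError("t and xy lengths differ")

    @property
    def dt(self) -> float:
        steps = np.diff(self.t)
        if steps.size == 0:
            raise ValueError("trace too short")
        if not np.allclose(steps, steps[0]):
            raise ValueError("non-uniform sample times")
        return float(steps[0])

    def window(self, t0: float, t1: float) -> "GazeTrace":
        m = (self.t >= t0) & (self.t <= t1)
        return GazeTrace(self.trial_id, self.t[m], self.xy[m])


@dataclass
class TrialEvents:
    """Experimental facts of one trial (what was shown, not what the eye did)."""

    trial_id: int
    participant: str
    fixation_side: str                 # 'left' | 'right'
    target2_dir: str                   # 'up' | 'down'
    distractor_modality: str           # 'visual' | 'auditory' | 'audiovisual' | 'none'
    distractor_x_deg: float = np.nan
    distractor_y_deg: float = np.nan
    distractor_onset_ms: float = np.nan
    distractor_duration_ms: float = np.nan

    @property
    def has_distractor(self) -> bool:
        return self.distractor_modality != "none"

    @property
    def sequence(self) -> str:
        return f"{self.fixation_side}-{self.target2_dir}"

    @property
    def distractor_offset_ms(self) -> float:
        return self.distractor_onset_ms + self.distractor_duration_ms

    def fixation_pos(self, eccentricity: float) -> np.ndarray:
        sx = -1.0 if self.fixation_side == "left" else 1.0
        return np.array([sx * eccentricity, 0.0])

    def target2_pos(self, eccentricity: float) -> np.ndarray:
        sy = 1.0 if self.target2_dir == "up" else -1.0
        return np.array([0.0, sy * eccentricity])

    @property
    def distractor_pos(self) -> np.ndarray:
        return np.array([self.distractor_x_deg, self.distractor_y_deg])


@dataclass
class Saccade:
    """A detected rapid eye movement."""

    onset_t: float         # ms
    offset_t: float        # ms
    start: np.ndarray      # (2,) deg
    end: np.ndarray        # (2,) deg

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        if not self.onset_t < self.offset_t:
            raise ValueError("saccade onset must precede offset")

    @property
    def amplitude(self) -> float:
        return float(np.hypot(*(self.end - self.start)))

    @property
    def latency(self) -> float:
        """Latency relative to targets onset (t = 0)."""
        return float(self.onset_t)

    @property
    def duration(self) -> float:
        return float(self.offset_t - self.onset_t)


@dataclass
class GroundTruthRecord:
    """Per-trial generator bookkeeping: true event times and injected curvature."""

    trial_id: int
    participant: str
    sequence: str
    rotation: str                      # 'clockwise' | 'counterclockwise' | 'none'
    onset1_ms: float
    offset1_ms: float
    onset2_ms: float
    offset2_ms: float
    baseline_curvature_deg: float      # idiosyncratic component, rotated-frame sign
    effect_curvature_deg: float        # distractor-evoked, toward(+)/away(-) convention
    interval_truth: str                # 'pre_saccadic' | 'inter_saccadic' | 'excluded' | 'no_distractor'
    trial_curvature_deg: float = 0.0   # trial-level scatter, rotated-frame sign
    blink: bool = False
    fixation_break: bool = False
    landing_error: bool = False

    def __post_init__(self) -> None:
        if not (self.onset1_ms < self.offset1_ms < self.onset2_ms < self.offset2_ms):
            raise ValueError("ground-truth saccade times out of order")
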