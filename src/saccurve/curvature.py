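"""Trajectory normalization and the curvature-angle statistic.

The statistic is the median, over interior sample points, of each point's
angular deviation from the straight chord connecting the saccade's start and
end points.  Negative values are, after the clockwise/counterclockwise sign
convention, deviations away from the distractor's screen position.

Processing chain for one second saccade:

    rotate_to_upward -> monotonic_resample -> normalize_trajectory
        -> apply_sign_convention -> curvature_angle
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import GazeTrace, Saccade, TrialEvents


@dataclass
class RotatedTrajectory:
    """Second-saccade samples in the chord frame.

    ``along`` grows from 0 (saccade start) toward the amplitude; ``ortho`` is
    the signed orthogonal deviation from the chord, positive on the side a
    clockwise distractor occupies.
    """

    along: np.ndarray
    ortho: np.ndarray
    amplitude: float
    trial_id: int = -1


@dataclass
class MonotonicProfile:
    grid: np.ndarray        # strictly increasing bin centers over [0, amplitude]
    ortho_mean: np.ndarray  # mean orthogonal deviation per bin
    amplitude: float
    trial_id: int = -1


@dataclass
class NormalizedTrajectory:
    grid: np.ndarray
    ortho_norm: np.ndarray
    amplitude: float
    trial_id: int = -1
    low_baseline: bool = False   # baseline built from fewer trials than requested


def rotate_to_upward(second: Saccade, trace: GazeTrace,
                     events: Optional[TrialEvents] = None) -> RotatedTrajectory:
    """Rigidly rotate the second saccade so its chord points upward.

    The start maps to the origin and the chord to the positive along-axis.
    Being a proper rotation (no reflection), a distractor presented clockwise
    of the second-saccade direction always lands on the positive ortho side.
    """
    seg = trace.window(second.onset_t, second.offset_t)
    if seg.t.size < 5:
        raise ValueError("second saccade has fewer than 5 samples")
    chord = second.end - second.start
    length = np.hypot(*chord)
    if length <= 0:
        raise ValueError("degenerate saccade chord")
    d = chord / length
    rel = seg.xy - second.start
    along = rel @ d
    ortho = rel @ np.array([d[1], -d[0]])
    return RotatedTrajectory(along=along, ortho=ortho, amplitude=float(length),
                             trial_id=trace.trial_id)


def monotonic_resample(rot: RotatedTrajectory, n_bins: int = 50) -> MonotonicProfile:
    """Average orthogonal deviation in equal-width along-axis bins.

    Along-axis progress of the raw samples need not be monotonic (dynamic
    overshoot); binning enforces a strictly increasing grid.  Empty interior
    bins are linearly interpolated from their neighbours.
    """
    if rot.amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if rot.along.size < max(4, n_bins // 4):
        raise ValueError("too few samples for resampling")
    finite = np.isfinite(rot.along) & np.isfinite(rot.ortho)
    along, ortho = rot.along[finite], rot.ortho[finite]
    idx = np.clip((along / rot.amplitude * n_bins).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    centers = (np.arange(n_bins) + 0.5) * rot.amplitude / n_bins
    filled = counts > 0
    # mean position per bin on both axes: the grid is the mean along-axis
    # progress of the samples in the bin, not the bin center
    means = np.full(n_bins, np.nan)
    grid = centers.copy()
    means[filled] = np.bincount(idx, weights=ortho, minlength=n_bins)[filled] / counts[filled]
    grid[filled] = np.bincount(idx, weights=along, minlength=n_bins)[filled] / counts[filled]
    if not filled.all():
        means[~filled] = np.interp(centers[~filled], grid[filled], means[filled])
    return MonotonicProfile(grid=grid, ortho_mean=means,
                            amplitude=rot.amplitude, trial_id=rot.trial_id)


def average_profile(profiles: list[MonotonicProfile]) -> MonotonicProfile:
    """Bin-wise mean of same-binning profiles (relative-position alignment)."""
    if not profiles:
        raise ValueError("no profiles to average")
    n = {p.grid.size for p in profiles}
    if len(n) != 1:
        raise ValueError("profiles have mismatched bin counts")
    amp = float(np.mean([p.amplitude for p in profiles]))
    ortho = np.mean([p.ortho_mean for p in profiles], axis=0)
    grid = np.mean([p.grid for p in profiles], axis=0)
    return MonotonicProfile(grid=grid, ortho_mean=ortho, amplitude=amp)


def normalize_trajectory(profile: MonotonicProfile, baseline: MonotonicProfile,
                         low_baseline: bool = False) -> NormalizedTrajectory:
    """Subtract the distractor-absent mean profile of the same participant
    and saccade sequence, removing idiosyncratic curvature.

    Profiles with equal bin counts are aligned bin-by-bin (same relative
    position along the movement); otherwise the baseline is regridded by
    linear interpolation on relative position.
    """
    if profile.grid.size == baseline.grid.size:
        base = baseline.ortho_mean
    else:
        rel = profile.grid / profile.amplitude
        base = np.interp(rel, baseline.grid / baseline.amplitude, baseline.ortho_mean)
    return NormalizedTrajectory(grid=profile.grid,
                                ortho_norm=profile.ortho_mean - base,
                                amplitude=profile.amplitude,
                                trial_id=profile.trial_id,
                                low_baseline=low_baseline)


def apply_sign_convention(traj: NormalizedTrajectory, rotation: str) -> NormalizedTrajectory:
    """Flip the orthogonal axis for counterclockwise distractors.

    After the flip, positive deviations point toward and negative away from
    the distractor's screen position in every trial.
    """
    if rotation == "counterclockwise":
        return NormalizedTrajectory(traj.grid, -traj.ortho_norm, traj.amplitude,
                                    traj.trial_id, traj.low_baseline)
    if rotation in ("clockwise", "none"):
        return traj
    raise ValueError(f"unknown rotation {rotation!r}")


def _median_angle(along: np.ndarray, ortho: np.ndarray, length: float,
                  margin: float) -> float:
    lo, hi = margin * length, (1.0 - margin) * length
    keep = (along >= lo) & (along <= hi) & np.isfinite(ortho) & (along > 0)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 interior points for the curvature median")
    return float(np.degrees(np.median(np.arctan2(ortho[keep], along[keep]))))


def curvature_angle(traj: NormalizedTrajectory, margin: float = 0.05) -> float:
    """Median angular deviation (deg) of interior points from the chord.

    The chord is the start->end line of the saccade, which the rotation step
    placed on the along-axis; points within ``margin`` of either endpoint are
    excluded because the deviation angle is numerically unstable near the
    start.  |angle| < 90 by construction.
    """
    if traj.amplitude <= 0:
        raise ValueError("degenerate chord")
    return _median_angle(traj.grid, traj.ortho_norm, traj.amplitude, margin)


def curvature_from_points(xy: np.ndarray, margin: float = 0.05) -> float:
    """Brute-force curvature angle of a raw 2-D path.

    The first and last points define the chord; every other point contributes
    arctan(orthogonal deviation / along-chord distance from the start), and
    the statistic is the median over points inside the margins.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 5:
        raise ValueError("need an (n>=5, 2) array of points")
    chord = xy[-1] - xy[0]
    length = np.hypot(*chord)
    if length <= 0:
        raise ValueError("degenerate chord")
    d = chord / length
    rel = xy - xy[0]
    along = rel @ d
    ortho = rel @ np.array([d[1], -d[0]])
    return _median_angle(along, ortho, length, margin)
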