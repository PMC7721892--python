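"""Participant-structured aggregation and bootstrap inference.

Per-trial curvature angles are first averaged within participants, then
across participants (the group SEM is the SD of participant means over the
square root of the participant count).  Inference draws bootstrap samples
that keep the participant and condition structure: each replicate resamples
trials with replacement within every participant, preserving the
per-participant trial counts, and the replicate statistic is the group mean
of participant means.  Two conditions are compared through the distribution
of differences of their replicate means.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd


@dataclass
class ConditionSummary:
    condition: str
    participant_means: Dict[str, float]
    group_mean: float
    group_sem: float        # NaN for a single participant
    n_participants: int
    n_trials: int


@dataclass
class BootstrapResult:
    condition: str
    n_boot: int
    seed: int
    boot: np.ndarray        # replicate group means


def _by_participant(df: pd.DataFrame, value_col: str = "curvature_deg") -> Dict[str, np.ndarray]:
    return {p: g[value_col].to_numpy(dtype=float)
            for p, g in df.groupby("participant", sort=True)}


def summarize_condition(df: pd.DataFrame, condition: str = "",
                        value_col: str = "curvature_deg") -> ConditionSummary:
    """Participant means over trials, then group mean and SEM over
    participants.  ``df`` holds one condition's trials."""
    if len(df) == 0:
        raise ValueError(f"empty condition {condition!r}")
    values = _by_participant(df, value_col)
    means = {p: float(np.mean(v)) for p, v in values.items()}
    m = np.array(list(means.values()))
    sem = float(np.std(m, ddof=1) / np.sqrt(m.size)) if m.size > 1 else float("nan")
    return ConditionSummary(condition=condition, participant_means=means,
                            group_mean=float(m.mean()), group_sem=sem,
                            n_participants=m.size, n_trials=len(df))


def bootstrap_distribution(df: pd.DataFrame, condition: str = "",
                           n_boot: int = 10000, seed: int = 0,
                           value_col: str = "curvature_deg") -> BootstrapResult:
    """Hierarchical bootstrap of the group mean.

    Every replicate draws, within each participant, that participant's
    original number of trials with replacement, and averages the resulting
    participant means.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    values = _by_participant(df, value_col)
    if not values:
        raise ValueError(f"empty condition {condition!r}")
    rng = np.random.default_rng(seed)
    acc = np.zeros(n_boot)
    for v in values.values():
        idx = rng.integers(0, v.size, size=(n_boot, v.size))
        acc += v[idx].mean(axis=1)
    return BootstrapResult(condition=condition, n_boot=n_boot, seed=seed,
                           boot=acc / len(values))


def two_tailed_p(a: BootstrapResult, b: BootstrapResult) -> float:
    """Two-tailed p for the difference of two bootstrapped condition means,
    floored at 2/(n_boot + 1) to avoid zero from finite resampling."""
    if a.n_boot != b.n_boot:
        raise ValueError("bootstrap results have mismatched n_boot")
    d = b.boot - a.boot
    p = 2.0 * min(np.mean(d >= 0), np.mean(d <= 0))
    return float(min(max(p, 2.0 / (a.n_boot + 1)), 1.0))


def median_split_latency(latencies: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
    """Per participant: trials strictly below the median latency are
    'early', strictly above 'late'; ties at the median alternate assignment
    so the two groups stay within one trial of each other."""
    out: Dict[str, np.ndarray] = {}
    for p, lat in latencies.items():
        lat = np.asarray(lat, dtype=float)
        if lat.size < 2:
            raise ValueError(f"participant {p!r} has fewer than 2 trials")
        med = np.median(lat)
        labels = np.empty(lat.size, dtype=object)
        labels[lat < med] = "early"
        labels[lat > med] = "late"
        n_early = int(np.sum(lat < med))
        n_late = int(np.sum(lat > med))
        for t in np.flatnonzero(lat == med):
            if n_early <= n_late:
                labels[t] = "early"
                n_early += 1
            else:
                labels[t] = "late"
                n_late += 1
        out[p] = labels
    return out
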