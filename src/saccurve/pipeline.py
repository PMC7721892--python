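"""End-to-end pipeline: gaze samples -> per-trial normalized curvature ->
condition summaries and bootstrap comparisons, with a reconciling manifest.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import PipelineConfig, config_to_dict
from .core import GazeTrace, TrialEvents
from .curvature import (MonotonicProfile, apply_sign_convention, average_profile,
                        curvature_angle, monotonic_resample, normalize_trajectory,
                        rotate_to_upward)
from .detection import AssignmentError, assign_sequence, compute_velocity, detect_saccades
from .selection import (classify_distractor_interval, classify_hemifield,
                        distractor_rotation, validate_trial)
from .stats import bootstrap_distribution, median_split_latency, summarize_condition, two_tailed_p
from .synth import simulate_experiment


@dataclass
class PipelineResult:
    trials: pd.DataFrame           # analyzed trials with normalized curvature
    classifications: pd.DataFrame  # every input trial with validity and labels
    saccades: pd.DataFrame         # detected-saccade table
    summary: pd.DataFrame          # condition-level means and SEMs
    summary_split: pd.DataFrame    # pre-saccadic conditions by latency split
    comparisons: pd.DataFrame      # bootstrap condition contrasts
    manifest: dict
    truth: Optional[pd.DataFrame] = None


def condition_label(modality: str, interval: str, hemifield: str) -> str:
    if interval == "no_distractor":
        return "no_distractor"
    if interval == "pre_saccadic":
        return f"{modality}:pre_saccadic:{hemifield}"
    return f"{modality}:{interval}"


def process_trials(traces: List[GazeTrace], events: List[TrialEvents],
                   config: PipelineConfig,
                   ) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[int, MonotonicProfile], pd.DataFrame]:
    """Detect, assign, validate and classify every trial; build monotonic
    second-saccade profiles for the analyzable ones."""
    det, sel, app = config.detection, config.selection, config.apparatus
    class_rows, sacc_rows, info_rows = [], [], []
    profiles: Dict[int, MonotonicProfile] = {}
    by_id = {ev.trial_id: ev for ev in events}
    for trace in traces:
        ev = by_id[trace.trial_id]
        row = {"trial_id": ev.trial_id, "participant": ev.participant,
               "valid": False, "reason": None, "interval": "not_applicable",
               "hemifield": "not_applicable", "rotation": "none"}
        if np.isnan(trace.xy).any():
            row["reason"] = "blink"
            class_rows.append(row)
            continue
        try:
            vel = compute_velocity(trace, det)
            saccades = detect_saccades(vel, det)
        except ValueError:
            row["reason"] = "blink"
            class_rows.append(row)
            continue
        for i, s in enumerate(saccades):
            sacc_rows.append({"trial_id": ev.trial_id, "index": i,
                              "onset_ms": s.onset_t, "offset_ms": s.offset_t,
                              "x0": s.start[0], "y0": s.start[1],
                              "x1": s.end[0], "y1": s.end[1],
                              "latency_ms": s.latency})
        try:
            first, second = assign_sequence(saccades, ev, app)
        except AssignmentError as err:
            row["reason"] = err.reason
            class_rows.append(row)
            continue
        cls = validate_trial(ev, first, second, sel, trace=trace, apparatus=app)
        row["valid"] = cls.valid
        row["reason"] = cls.reason
        if not cls.valid:
            class_rows.append(row)
            continue
        interval = classify_distractor_interval(ev, first, second, sel)
        row["interval"] = interval
        if ev.has_distractor:
            row["rotation"] = distractor_rotation(ev)
            if interval == "pre_saccadic":
                row["hemifield"] = classify_hemifield(ev, app)
        class_rows.append(row)
        if interval == "excluded":
            continue
        rot = rotate_to_upward(second, trace, ev)
        profiles[ev.trial_id] = monotonic_resample(rot, config.analysis.n_bins)
        info_rows.append({"trial_id": ev.trial_id, "participant": ev.participant,
                          "sequence": ev.sequence, "modality": ev.distractor_modality,
                          "interval": interval, "hemifield": row["hemifield"],
                          "rotation": row["rotation"],
                          "latency1_ms": first.latency, "latency2_ms": second.latency})
    return (pd.DataFrame(class_rows), pd.DataFrame(sacc_rows), profiles,
            pd.DataFrame(info_rows))


def curvature_table(info: pd.DataFrame, profiles: Dict[int, MonotonicProfile],
                    config: PipelineConfig) -> pd.DataFrame:
    """Normalize each analyzable trial against its participant/sequence
    distractor-absent baseline and compute the signed curvature angle."""
    empty = pd.DataFrame(columns=[
        "trial_id", "participant", "sequence", "modality", "interval",
        "hemifield", "rotation", "latency1_ms", "latency2_ms",
        "curvature_deg", "low_baseline", "condition", "latency_group"])
    if len(info) == 0:
        return empty
    baselines: Dict[Tuple[str, str], Tuple[MonotonicProfile, bool]] = {}
    base_trials = info[info.modality == "none"]
    for (p, seq), g in base_trials.groupby(["participant", "sequence"]):
        profs = [profiles[tid] for tid in g.trial_id]
        baselines[(p, seq)] = (average_profile(profs),
                               len(profs) < config.analysis.min_baseline_trials)
    rows = []
    for r in info.itertuples():
        key = (r.participant, r.sequence)
        if key not in baselines:
            continue
        base, low = baselines[key]
        norm = normalize_trajectory(profiles[r.trial_id], base, low_baseline=low)
        norm = apply_sign_convention(norm, r.rotation)
        angle = curvature_angle(norm, margin=config.analysis.margin)
        rows.append({**r._asdict(), "curvature_deg": angle, "low_baseline": low})
    if not rows:
        return empty
    df = pd.DataFrame(rows).drop(columns=["Index"])
    df["condition"] = [condition_label(m, i, h) for m, i, h in
                       zip(df.modality, df.interval, df.hemifield)]
    # per-participant median split of first-saccade latency, pre-saccadic trials
    df["latency_group"] = "not_applicable"
    pre = df[df.interval == "pre_saccadic"]
    if len(pre):
        lat = {p: g.latency1_ms.to_numpy() for p, g in pre.groupby("participant")}
        labels = median_split_latency(lat)
        for p, g in pre.groupby("participant"):
            df.loc[g.index, "latency_group"] = labels[p]
    return df


def summarize(trials: pd.DataFrame, split: bool = False) -> pd.DataFrame:
    rows = []
    if len(trials) == 0:
        return pd.DataFrame(columns=["condition", "group_mean_deg", "group_sem_deg",
                                     "n_participants", "n_trials"])
    if split:
        pre = trials[trials.interval == "pre_saccadic"]
        groups = pre.groupby(["condition", "latency_group"])
        keys = [f"{c}:{g}" for c, g in groups.groups]
        frames = [grp for _, grp in groups]
    else:
        groups = trials.groupby("condition")
        keys = list(groups.groups)
        frames = [grp for _, grp in groups]
    for key, grp in zip(keys, frames):
        s = summarize_condition(grp, key)
        rows.append({"condition": key, "group_mean_deg": s.group_mean,
                     "group_sem_deg": s.group_sem,
                     "n_participants": s.n_participants, "n_trials": s.n_trials})
    return pd.DataFrame(rows)


def compare_conditions(trials: pd.DataFrame, n_boot: int, seed: int) -> pd.DataFrame:
    """Each distractor condition against no-distractor, plus pre- vs
    inter-saccadic within modality (and hemifield for the pre side)."""
    conditions = sorted(trials.condition.unique())
    boots = {}
    for i, c in enumerate(conditions):
        boots[c] = bootstrap_distribution(trials[trials.condition == c], c,
                                          n_boot=n_boot, seed=seed + i)
    pairs = []
    for c in conditions:
        if c != "no_distractor" and "no_distractor" in boots:
            pairs.append((c, "no_distractor"))
        if ":pre_saccadic:" in c:
            inter = c.split(":")[0] + ":inter_saccadic"
            if inter in boots:
                pairs.append((c, inter))
    rows = []
    for a, b in pairs:
        rows.append({"condition_a": a, "condition_b": b,
                     "mean_diff_deg": float(np.mean(boots[a].boot) - np.mean(boots[b].boot)),
                     "p_two_tailed": two_tailed_p(boots[a], boots[b]),
                     "n_boot": n_boot, "seed": seed})
    return pd.DataFrame(rows)


def config_hash(config: PipelineConfig) -> str:
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig,
                 traces: Optional[List[GazeTrace]] = None,
                 events: Optional[List[TrialEvents]] = None) -> PipelineResult:
    """Run the full chain; simulates the experiment when no input is given.

    Deterministic given the config (simulation and analysis seeds); when
    ``config.out_dir`` is set, all tables and the manifest are persisted.
    """
    truth_df = None
    if traces is None or events is None:
        traces, events, truths = simulate_experiment(
            config.simulation, config.apparatus, config.selection)
        from .io import truth_to_frame
        truth_df = truth_to_frame(truths)
    classifications, saccades, profiles, info = process_trials(traces, events, config)
    trials = curvature_table(info, profiles, config)
    summary = summarize(trials)
    summary_split = summarize(trials, split=True)
    comparisons = compare_conditions(trials, config.analysis.n_boot,
                                     config.analysis.seed)
    n_total = len(classifications)
    n_valid = int(classifications.valid.sum())
    reasons = (classifications[~classifications.valid]
               .reason.value_counts().to_dict())
    manifest = {
        "version": __version__,
        "config_hash": config_hash(config),
        "seeds": {"simulation": config.simulation.seed,
                  "analysis": config.analysis.seed},
        "counts": {
            "trials_in": n_total,
            "trials_valid": n_valid,
            "trials_rejected": {str(k): int(v) for k, v in reasons.items()},
            "trials_interval_excluded": int((classifications.interval == "excluded").sum()),
            "trials_analyzed": len(trials),
            "per_condition": trials.condition.value_counts().to_dict() if len(trials) else {},
        },
    }
    rej = sum(manifest["counts"]["trials_rejected"].values())
    assert n_total == n_valid + rej, "manifest counts do not reconcile"
    result = PipelineResult(trials=trials, classifications=classifications,
                            saccades=saccades, summary=summary,
                            summary_split=summary_split, comparisons=comparisons,
                            manifest=manifest, truth=truth_df)
    if config.out_dir:
        _persist(result, config)
    return result


def _persist(result: PipelineResult, config: PipelineConfig) -> None:
    from pathlib import Path
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.trials.to_csv(out / "trials.csv", index=False)
    result.classifications.to_csv(out / "classifications.csv", index=False)
    result.saccades.to_csv(out / "saccades.csv", index=False)
    result.summary.to_csv(out / "summary.csv", index=False)
    result.summary_split.to_csv(out / "summary_split.csv", index=False)
    result.comparisons.to_csv(out / "comparisons.csv", index=False)
    if result.truth is not None:
        result.truth.to_csv(out / "ground_truth.csv", index=False)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=True)
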