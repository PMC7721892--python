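"""Readers and writers for the pipeline's delimited-text tables.

All tables are header-keyed CSV; column order does not matter.  Gaze samples
use empty fields for blink dropouts.  Malformed rows are rejected with their
row numbers.
"""
from __future__ import annotations

from typing import Dict, List

import numpy as np
import pandas as pd

from .core import GazeTrace, GroundTruthRecord, TrialEvents

GAZE_COLUMNS = ["trial_id", "t_ms", "x_deg", "y_deg"]
EVENTS_COLUMNS = ["trial_id", "participant", "fixation_side", "target2_dir",
                  "distractor_modality", "distractor_x_deg", "distractor_y_deg",
                  "distractor_onset_ms", "distractor_duration_ms"]


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, required: List[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def _coerce_numeric(df: pd.DataFrame, cols: List[str], what: str,
                    allow_missing: List[str] = ()) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        raw = df[c]
        out = pd.to_numeric(raw, errors="coerce")
        was_blank = raw.isna() | (raw.astype(str).str.strip() == "")
        bad = out.isna() & ~was_blank
        if bad.any():
            rows = ", ".join(str(i) for i in df.index[bad][:5])
            raise SchemaError(f"{what} table: non-numeric values in column "
                              f"'{c}' at row(s) {rows}")
        if out.isna().any() and c not in allow_missing:
            rows = ", ".join(str(i) for i in df.index[out.isna()][:5])
            raise SchemaError(f"{what} table: missing values in column "
                              f"'{c}' at row(s) {rows}")
        df[c] = out
    return df


def traces_to_frame(traces: List[GazeTrace]) -> pd.DataFrame:
    parts = [pd.DataFrame({"trial_id": np.full(tr.t.size, tr.trial_id, dtype=int),
                           "t_ms": tr.t, "x_deg": tr.xy[:, 0], "y_deg": tr.xy[:, 1]})
             for tr in traces]
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> List[GazeTrace]:
    out = []
    for tid, g in df.groupby("trial_id", sort=True):
        out.append(GazeTrace(int(tid), g["t_ms"].to_numpy(),
                             g[["x_deg", "y_deg"]].to_numpy()))
    return out


def read_gaze_table(path) -> List[GazeTrace]:
    df = pd.read_csv(path)
    _require_columns(df, GAZE_COLUMNS, "gaze")
    df = _coerce_numeric(df, GAZE_COLUMNS, "gaze", allow_missing=["x_deg", "y_deg"])
    return frame_to_traces(df)


def write_gaze_table(traces: List[GazeTrace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False, float_format="%.4f")


def events_to_frame(events: List[TrialEvents]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trial_id": ev.trial_id, "participant": ev.participant,
        "fixation_side": ev.fixation_side, "target2_dir": ev.target2_dir,
        "distractor_modality": ev.distractor_modality,
        "distractor_x_deg": ev.distractor_x_deg,
        "distractor_y_deg": ev.distractor_y_deg,
        "distractor_onset_ms": ev.distractor_onset_ms,
        "distractor_duration_ms": ev.distractor_duration_ms,
    } for ev in events])


def frame_to_events(df: pd.DataFrame) -> List[TrialEvents]:
    return [TrialEvents(
        trial_id=int(r.trial_id), participant=str(r.participant),
        fixation_side=str(r.fixation_side), target2_dir=str(r.target2_dir),
        distractor_modality=str(r.distractor_modality),
        distractor_x_deg=float(r.distractor_x_deg),
        distractor_y_deg=float(r.distractor_y_deg),
        distractor_onset_ms=float(r.distractor_onset_ms),
        distractor_duration_ms=float(r.distractor_duration_ms),
    ) for r in df.itertuples()]


def read_events_table(path) -> List[TrialEvents]:
    df = pd.read_csv(path)
    _require_columns(df, EVENTS_COLUMNS, "events")
    numeric = ["trial_id", "distractor_x_deg", "distractor_y_deg",
               "distractor_onset_ms", "distractor_duration_ms"]
    df = _coerce_numeric(df, numeric, "events",
                         allow_missing=numeric[1:])
    return frame_to_events(df)


def write_events_table(events: List[TrialEvents], path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def truth_to_frame(truths: List[GroundTruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in truths])


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
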