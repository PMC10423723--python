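"""CSV/JSON readers and writers for every pipeline artifact.

Dialect, fixed: comma separator, '.' decimal, numeric seconds
timestamps, UTF-8, mandatory one-line header.  The sample log, events
and responses files use exactly the schema the simulator emits and the
preprocessing stage consumes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .features import FeatureVector, ResponseRecord, feature_group
from .geometry import TrialSchedule
from .preprocess import EyeSampleLog

SAMPLE_COLUMNS = (
    ["t", "pupil_l", "pupil_r", "open_l", "open_r"]
    + [f"origin_l_{c}" for c in "xyz"]
    + [f"origin_r_{c}" for c in "xyz"]
    + [f"dir_l_{c}" for c in "xyz"]
    + [f"dir_r_{c}" for c in "xyz"]
    + ["fixated_l", "fixated_r"]
)
EVENT_COLUMNS = ["onset_t", "offset_t", "stimulus_index"]
RESPONSE_COLUMNS = [
    "stimulus_index",
    "disparity_arcsec",
    "position_label",
    "reaction_time_s",
    "correct",
]
SCHEDULE_COLUMNS = [
    "index",
    "disparity_arcsec",
    "position_label",
    "azimuth_deg",
    "inclination_deg",
    "target_ball",
    "D_cm",
    "scale_s",
    "jitter_up_cm",
    "jitter_down_cm",
    "jitter_left_cm",
    "jitter_right_cm",
]


def _check_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def write_sample_log(log: EyeSampleLog, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "t": log.t,
            "pupil_l": log.pupil_l,
            "pupil_r": log.pupil_r,
            "open_l": log.open_l,
            "open_r": log.open_r,
        }
    )
    for name, arr in (
        ("origin_l", log.origin_l),
        ("origin_r", log.origin_r),
        ("dir_l", log.dir_l),
        ("dir_r", log.dir_r),
    ):
        for k, c in enumerate("xyz"):
            df[f"{name}_{c}"] = arr[:, k]
    df["fixated_l"] = log.fixated_l
    df["fixated_r"] = log.fixated_r
    df.to_csv(path, index=False)


def write_events(events: list[tuple[float, float, int]], path: str | Path, idle_start_t: float = 0.0) -> None:
    df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    df.to_csv(path, index=False)
    # idle start rides along in a sidecar-free convention: first onset
    # minus the idle duration is recoverable from the samples file.


def read_sample_log(sample_path: str | Path, events_path: str | Path) -> EyeSampleLog:
    df = pd.read_csv(sample_path)
    _check_columns(df, SAMPLE_COLUMNS, "sample log")
    ev = pd.read_csv(events_path)
    _check_columns(ev, EVENT_COLUMNS, "events")
    events = [
        (float(r.onset_t), float(r.offset_t), int(r.stimulus_index)) for r in ev.itertuples()
    ]
    return EyeSampleLog(
        t=df["t"].to_numpy(float),
        pupil_l=df["pupil_l"].to_numpy(float),
        pupil_r=df["pupil_r"].to_numpy(float),
        open_l=df["open_l"].to_numpy(float),
        open_r=df["open_r"].to_numpy(float),
        origin_l=df[[f"origin_l_{c}" for c in "xyz"]].to_numpy(float),
        origin_r=df[[f"origin_r_{c}" for c in "xyz"]].to_numpy(float),
        dir_l=df[[f"dir_l_{c}" for c in "xyz"]].to_numpy(float),
        dir_r=df[[f"dir_r_{c}" for c in "xyz"]].to_numpy(float),
        fixated_l=df["fixated_l"].astype(str).to_numpy(object),
        fixated_r=df["fixated_r"].astype(str).to_numpy(object),
        events=events,
        idle_start_t=0.0,
    )


def write_responses(responses: list[ResponseRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "stimulus_index": r.stimulus_index,
                "disparity_arcsec": r.disparity_arcsec,
                "position_label": r.position_label,
                "reaction_time_s": r.reaction_time_s,
                "correct": int(r.correct),
            }
            for r in responses
        ]
    )
    df.to_csv(path, index=False)


def read_responses(path: str | Path) -> list[ResponseRecord]:
    df = pd.read_csv(path)
    _check_columns(df, RESPONSE_COLUMNS, "responses")
    return [
        ResponseRecord(
            stimulus_index=int(r.stimulus_index),
            disparity_arcsec=float(r.disparity_arcsec),
            position_label=str(r.position_label),
            reaction_time_s=float(r.reaction_time_s),
            correct=bool(r.correct),
        )
        for r in df.itertuples()
    ]


def write_schedule(schedule: TrialSchedule, path: str | Path) -> None:
    rows = []
    for s in schedule.stimuli:
        rows.append(
            {
                "index": s.index,
                "disparity_arcsec": s.disparity_arcsec,
                "position_label": s.position_label,
                "azimuth_deg": s.azimuth_deg,
                "inclination_deg": s.inclination_deg,
                "target_ball": s.target_ball,
                "D_cm": s.geometry.D_cm,
                "scale_s": s.geometry.scale_s,
                "jitter_up_cm": s.jitter_cm.get("Up", 0.0),
                "jitter_down_cm": s.jitter_cm.get("Down", 0.0),
                "jitter_left_cm": s.jitter_cm.get("Left", 0.0),
                "jitter_right_cm": s.jitter_cm.get("Right", 0.0),
            }
        )
    pd.DataFrame(rows, columns=SCHEDULE_COLUMNS).to_csv(path, index=False)


def write_feature_matrix(
    vectors: dict[str, FeatureVector], labels: dict[str, str], path: str | Path
) -> pd.DataFrame:
    """One row per participant: id, label, then the 73 feature columns."""
    if not vectors:
        raise SchemaError("no feature vectors to write")
    names = list(next(iter(vectors.values())).values)
    rows = []
    for pid, vec in vectors.items():
        row = {"participant_id": pid, "label": labels[pid]}
        row.update(vec.values)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["participant_id", "label"] + names)
    df.to_csv(path, index=False)
    return df


def read_feature_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, str]]:
    """Returns (X, y, feature_names, group_tags)."""
    df = pd.read_csv(path)
    _check_columns(df, ["participant_id", "label"], "feature matrix")
    names = [c for c in df.columns if c not in ("participant_id", "label")]
    X = df[names].to_numpy(float)
    y = df["label"].to_numpy(object)
    tags = {n: feature_group(n) for n in names}
    return X, y, names, tags


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
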