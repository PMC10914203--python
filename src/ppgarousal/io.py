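"""Reading and writing waveforms and annotations.

CSV schemas
-----------
PPG waveform   : columns ``time_s, ppg`` (uniform grid; rate inferred).
Annotations    : columns ``track, start_s, duration_s, label`` where track is one
                 of ``arousal`` (label = scored cause), ``resp_event`` (label =
                 event type), ``desaturation`` (label empty) and ``stage``
                 (label = stage, duration 30 s).
EDF input is read through :mod:`mne` when available (signal label configurable).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    AnnotationSet,
    Arousal,
    Desaturation,
    PPGRecord,
    RespEvent,
    StageEpoch,
)

ANNOTATION_COLUMNS = ["track", "start_s", "duration_s", "label"]


def read_ppg_csv(path: str | Path, subject_id: str = "") -> PPGRecord:
    df = pd.read_csv(path)
    for col in ("time_s", "ppg"):
        if col not in df.columns:
            raise ValueError(f"{path}: PPG CSV must have a {col!r} column")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"{path}: PPG CSV must contain at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
        raise ValueError(f"{path}: PPG samples are not uniformly spaced")
    return PPGRecord(
        samples=df["ppg"].to_numpy(float),
        sampling_rate=1.0 / dt[0],
        subject_id=subject_id or Path(path).stem,
        start_time_s=float(t[0]),
    )


def write_ppg_csv(record: PPGRecord, path: str | Path) -> None:
    pd.DataFrame({"time_s": record.times(), "ppg": record.samples}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_ppg_edf(path: str | Path, channel: str = "Pleth", subject_id: str = "") -> PPGRecord:
    """Read one PPG channel from an EDF file (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("EDF input requires the 'mne' package (pip install ppgarousal[edf])") from exc
    raw = mne.io.read_raw_edf(path, include=[channel], preload=True, verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(f"{path}: channel {channel!r} not found")
    data = raw.get_data(picks=[channel])[0]
    return PPGRecord(
        samples=data,
        sampling_rate=float(raw.info["sfreq"]),
        subject_id=subject_id or Path(path).stem,
    )


def annotations_to_frame(ann: AnnotationSet) -> pd.DataFrame:
    rows: list[tuple[str, float, float, str]] = []
    for a in ann.arousals:
        rows.append(("arousal", a.start_s, a.duration_s, a.scored_cause))
    for e in ann.resp_events:
        rows.append(("resp_event", e.start_s, e.duration_s, e.type))
    for d in ann.desaturations:
        rows.append(("desaturation", d.start_s, d.duration_s, ""))
    for ep in ann.stage_epochs:
        rows.append(("stage", ep.epoch_start_s, 30.0, ep.stage))
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return df.sort_values(["track", "start_s"], kind="stable").reset_index(drop=True)


def frame_to_annotations(df: pd.DataFrame) -> AnnotationSet:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    ann = AnnotationSet()
    for i, row in df.iterrows():
        track = row["track"]
        try:
            start = float(row["start_s"])
            dur = float(row["duration_s"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"annotation row {i}: bad start/duration") from exc
        label = "" if pd.isna(row["label"]) else str(row["label"])
        if track == "arousal":
            ann.arousals.append(Arousal(start, dur, scored_cause=label or "spontaneous"))
        elif track == "resp_event":
            ann.resp_events.append(RespEvent(start, dur, type=label))
        elif track == "desaturation":
            ann.desaturations.append(Desaturation(start, dur))
        elif track == "stage":
            ann.stage_epochs.append(StageEpoch(start, stage=label))
        else:
            raise ValueError(f"annotation row {i}: unknown track {track!r}")
    ann.arousals.sort(key=lambda a: a.start_s)
    ann.resp_events.sort(key=lambda e: e.start_s)
    ann.desaturations.sort(key=lambda d: d.start_s)
    ann.stage_epochs.sort(key=lambda e: e.epoch_start_s)
    return ann


def write_annotations_csv(ann: AnnotationSet, path: str | Path) -> None:
    annotations_to_frame(ann).to_csv(path, index=False)


def read_annotations_csv(path: str | Path) -> AnnotationSet:
    return frame_to_annotations(pd.read_csv(path))


def write_series_csv(series, path: str | Path) -> None:
    """Export a characteristic trace as a two-column (time_s, value) CSV."""
    pd.DataFrame({"time_s": series.times, "value": series.values}).to_csv(
        path, index=False, float_format="%.6f"
    )
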