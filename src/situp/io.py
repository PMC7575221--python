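"""Plain-text interchange formats (CSV + JSON sidecars).

A signal lives in two files: ``<stem>.csv`` with columns time_s, ecg_mv,
bp_mmhg, and ``<stem>.json`` carrying the sampling rate, protocol
annotations, cuff readings and (for synthetic records) the embedded ground
truth.  Beat tables, window summaries, feature tables and cohort tables are
single CSVs; linkages are JSON.  Every reader validates its schema and
names the missing column on failure.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .beats import BeatSeries
from .cluster import Linkage
from .waveforms import Annotations, CuffReading, SignalRecord

__all__ = [
    "write_signal", "read_signal",
    "write_beats", "read_beats",
    "write_features", "read_features",
    "write_linkage", "read_linkage",
]

FEATURE_COLUMNS = ["subject_id", "d_sbp", "d_dbp", "d_hr", "source_window"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_signal(record: SignalRecord, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({
        "time_s": record.time,
        "ecg_mv": record.ecg,
        "bp_mmhg": record.bp,
    })
    df.to_csv(path, index=False)
    ann = record.annotations
    meta = {
        "fs_hz": record.fs,
        "annotations": {
            "supine_start_s": ann.supine_start_s,
            "sit_onset_s": ann.sit_onset_s,
            "seated_end_s": ann.seated_end_s,
            "transition_s": ann.transition_s,
        },
        "cuff_readings": [
            {"time_s": c.time_s, "sbp_mmhg": c.sbp, "dbp_mmhg": c.dbp}
            for c in record.cuff_readings
        ],
        "metadata": record.metadata,
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_signal(path: str | Path) -> SignalRecord:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "ecg_mv", "bp_mmhg"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    meta = json.loads(_sidecar(path).read_text())
    ann = meta["annotations"]
    return SignalRecord(
        fs=float(meta["fs_hz"]),
        ecg=df["ecg_mv"].to_numpy(float),
        bp=df["bp_mmhg"].to_numpy(float),
        annotations=Annotations(
            supine_start_s=float(ann["supine_start_s"]),
            sit_onset_s=float(ann["sit_onset_s"]),
            seated_end_s=float(ann["seated_end_s"]),
            transition_s=float(ann.get("transition_s", 10.0)),
        ),
        cuff_readings=[
            CuffReading(float(c["time_s"]), float(c["sbp_mmhg"]), float(c["dbp_mmhg"]))
            for c in meta.get("cuff_readings", [])
        ],
        metadata=meta.get("metadata", {}),
    )


def write_beats(beats: BeatSeries, path: str | Path) -> None:
    beats.to_frame().to_csv(Path(path), index=False)


def read_beats(path: str | Path) -> BeatSeries:
    return BeatSeries.from_frame(pd.read_csv(Path(path)))


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {', '.join(missing)}")
    features.to_csv(Path(path), index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    return df


def write_linkage(linkage: Linkage, path: str | Path) -> None:
    Path(path).write_text(linkage.to_json())


def read_linkage(path: str | Path) -> Linkage:
    return Linkage.from_json(Path(path).read_text())
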