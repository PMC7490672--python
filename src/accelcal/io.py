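"""Plain-text I/O: the epoch CSV dialect, manifests and ground truth.

Epoch CSV dialect (UTF-8, comma, "." decimal), one header line:

    participant_id,day,placement,epoch_start,epoch_length_s,axis1,axis2,axis3,vm

Axis columns and ``vm`` are each optional but at least one group must
be present; when both are present the ``vm`` column wins and the axis
columns are ignored with a logged notice.  ``epoch_start`` is ISO-8601
local time.  One file per participant-day-placement, indexed by a
manifest CSV (participant_id, day, placement, path).  The simulator
additionally writes a ground-truth file (true state and wear mask per
epoch) for detector/agreement oracles.

An ActiLife-style reader skips metadata preamble lines by detecting the
first line whose first field parses as a timestamp.
"""

from __future__ import annotations

import logging
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSeries

logger = logging.getLogger(__name__)

__all__ = [
    "write_epoch_csv",
    "read_epoch_csv",
    "read_actilife_csv",
    "write_study",
    "read_manifest",
]

_COLUMNS = [
    "participant_id",
    "day",
    "placement",
    "epoch_start",
    "epoch_length_s",
    "axis1",
    "axis2",
    "axis3",
    "vm",
]


def _epoch_starts(start_time: str, n: int, epoch_length: int) -> list[str]:
    t0 = datetime.fromisoformat(f"2000-01-01T{start_time}")
    return [
        (t0 + timedelta(seconds=i * epoch_length)).time().isoformat()
        for i in range(n)
    ]


def write_epoch_csv(series: EpochSeries, path) -> Path:
    """Write one participant-day-placement series in the epoch dialect."""
    path = Path(path)
    n = series.n_epochs
    df = pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "day": series.day_index,
            "placement": series.placement,
            "epoch_start": _epoch_starts(series.start_time, n, series.epoch_length),
            "epoch_length_s": series.epoch_length,
        }
    )
    if series.axes is not None:
        df["axis1"], df["axis2"], df["axis3"] = series.axes.T
    else:
        df["axis1"] = df["axis2"] = df["axis3"] = ""
    df["vm"] = series.values if series.values is not None else ""
    df.to_csv(path, index=False)
    return path


def read_epoch_csv(path) -> EpochSeries:
    """Read a series written in the epoch dialect."""
    df = pd.read_csv(path)
    missing = [c for c in ("participant_id", "day", "placement", "epoch_length_s") if c not in df.columns]
    if missing:
        raise ValueError(f"epoch CSV missing required columns: {missing}")
    has_vm = "vm" in df.columns and df["vm"].notna().all() and (df["vm"].astype(str) != "").all()
    axis_cols = ["axis1", "axis2", "axis3"]
    has_axes = all(c in df.columns for c in axis_cols) and df[axis_cols].notna().all().all()
    if not has_vm and not has_axes:
        for c in axis_cols:
            if c not in df.columns or df[c].isna().any():
                raise ValueError(f"missing axis column {c} and no vm column")
    if has_vm and has_axes:
        logger.info("%s: both vm and axis columns present; vm wins", path)
    values = df["vm"].astype(np.int64).to_numpy() if has_vm else None
    axes = df[axis_cols].astype(np.int64).to_numpy() if (has_axes and not has_vm) else None
    return EpochSeries(
        participant_id=str(df["participant_id"].iloc[0]),
        day_index=int(df["day"].iloc[0]),
        placement=str(df["placement"].iloc[0]),
        epoch_length=int(df["epoch_length_s"].iloc[0]),
        values=values,
        axes=axes,
        start_time=str(df["epoch_start"].iloc[0]) if "epoch_start" in df.columns else "09:00:00",
    )


def _parses_as_timestamp(field: str) -> bool:
    field = field.strip().strip('"')
    for fmt in ("%H:%M:%S", "%m/%d/%Y %H:%M:%S", "%Y-%m-%d %H:%M:%S"):
        try:
            datetime.strptime(field, fmt)
            return True
        except ValueError:
            continue
    return False


def read_actilife_csv(
    path, participant_id: str, day_index: int, placement: str, epoch_length: int
) -> EpochSeries:
    """Read an ActiLife-style per-epoch export with a metadata preamble.

    The preamble is skipped by finding the first line whose first
    comma-separated field parses as a timestamp; subsequent fields are
    axis1, axis2, axis3 (and optionally vm, which wins when present).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    start = next(
        (i for i, ln in enumerate(lines) if ln and _parses_as_timestamp(ln.split(",")[0])),
        None,
    )
    if start is None:
        raise ValueError(f"{path}: no line starting with a timestamp found")
    rows = [ln.split(",") for ln in lines[start:] if ln.strip()]
    ncol = min(len(r) for r in rows)
    data = np.array([[c.strip().strip('"') for c in r[:ncol]] for r in rows])
    t0 = data[0, 0]
    if ncol >= 5:
        values, axes = data[:, 4].astype(np.int64), None
    elif ncol == 4:
        values, axes = None, data[:, 1:4].astype(np.int64)
    else:
        raise ValueError(f"{path}: expected timestamp + 3 axis columns")
    return EpochSeries(
        participant_id=participant_id,
        day_index=day_index,
        placement=placement,
        epoch_length=epoch_length,
        values=values,
        axes=axes,
        start_time=t0.split(" ")[-1],
    )


def write_study(study, out_dir) -> Path:
    """Write a simulated study: epoch files, manifest and ground truth.

    Returns the manifest path.  Layout: ``epochs/<pid>_d<day>_<placement>.csv``
    per series, ``manifest.csv`` and ``ground_truth.csv`` at the root.
    """
    out = Path(out_dir)
    (out / "epochs").mkdir(parents=True, exist_ok=True)
    manifest_rows, truth_frames = [], []
    for pd_ in study.days:
        for series in (pd_.hip, pd_.wrist):
            rel = f"epochs/{series.participant_id}_d{series.day_index}_{series.placement}.csv"
            write_epoch_csv(series, out / rel)
            manifest_rows.append(
                {
                    "participant_id": series.participant_id,
                    "day": series.day_index,
                    "placement": series.placement,
                    "path": rel,
                }
            )
        t = pd_.truth.copy()
        t.insert(0, "participant_id", pd_.participant_id)
        t.insert(1, "day", pd_.day)
        t.insert(2, "epoch", np.arange(len(t)))
        truth_frames.append(t)
    manifest = out / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    pd.concat(truth_frames, ignore_index=True).to_csv(out / "ground_truth.csv", index=False)
    return manifest


def read_manifest(manifest_path) -> list[EpochSeries]:
    """Load every series referenced by a manifest CSV."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    root = manifest_path.parent
    return [read_epoch_csv(root / row["path"]) for _, row in df.iterrows()]
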