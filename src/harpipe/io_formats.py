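"""Reading/writing delimited sensor formats and window segmentation.

Supported layouts: a plain CSV of records (``source_id, timestamp,
ch_0..ch_{k-1}, label``; empty channel fields = missing), and the
UCI-HAR-style layout of whitespace-delimited per-channel window files plus a
label file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import MISSING_LABEL, RawRecordSet, WindowSet

__all__ = [
    "CsvSchema",
    "read_raw_csv",
    "write_raw_csv",
    "write_defect_flags_csv",
    "read_ucihar_layout",
    "downsample",
    "segment_stream",
]


@dataclass
class CsvSchema:
    """Column layout of a record CSV."""

    channel_columns: list[str] = field(default_factory=lambda: ["ch_0", "ch_1", "ch_2"])
    label_column: str = "label"
    timestamp_column: str = "timestamp"
    source_column: str = "source_id"

    def __post_init__(self) -> None:
        if not self.channel_columns:
            raise ValueError("schema must name at least one channel column")


def write_raw_csv(records: RawRecordSet, path: str | os.PathLike) -> None:
    """Write records as CSV; missing entries become empty fields."""
    df = pd.DataFrame(records.values, columns=records.channel_names)
    df.insert(0, "timestamp", records.timestamps)
    df.insert(0, "source_id", records.source_ids)
    df["label"] = records.labels
    df.to_csv(path, index=False, float_format="%.12g")


def write_defect_flags_csv(ground_truth, path: str | os.PathLike) -> None:
    """Sidecar CSV of per-record defect flags from generator ground truth."""
    n, c = ground_truth.missing_mask.shape
    df = pd.DataFrame(
        {
            "duplicate": ground_truth.duplicate_flags.astype(int),
            **{f"missing_ch_{j}": ground_truth.missing_mask[:, j].astype(int) for j in range(c)},
            **{f"corrupt_ch_{j}": ground_truth.corrupt_mask[:, j].astype(int) for j in range(c)},
        }
    )
    df.to_csv(path, index=False)


def read_raw_csv(path: str | os.PathLike, schema: CsvSchema | None = None) -> RawRecordSet:
    """Read a record CSV, preserving order and flagging empty fields as missing.

    Raises a ``ValueError`` naming the offending line for unparseable rows and
    listing the value for unknown (non-integer) label symbols.
    """
    schema = schema or CsvSchema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [
        c
        for c in [schema.source_column, schema.timestamp_column, schema.label_column]
        + schema.channel_columns
        if c not in df.columns
    ]
    if missing_cols:
        raise ValueError(f"CSV at {path} is missing columns: {missing_cols}")

    n = len(df)
    values = np.empty((n, len(schema.channel_columns)))
    for j, col in enumerate(schema.channel_columns):
        raw = df[col].to_numpy()
        out = np.empty(n)
        for i, cell in enumerate(raw):
            cell = cell.strip()
            if cell == "":
                out[i] = np.nan
                continue
            try:
                out[i] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"unparseable value {cell!r} in column {col} at line {i + 2}"
                ) from exc
        values[:, j] = out

    labels = np.empty(n, dtype=np.int64)
    for i, cell in enumerate(df[schema.label_column].to_numpy()):
        cell = cell.strip()
        if cell == "":
            labels[i] = MISSING_LABEL
            continue
        try:
            labels[i] = int(cell)
        except ValueError as exc:
            raise ValueError(f"unknown label symbol {cell!r} at line {i + 2}") from exc

    try:
        timestamps = df[schema.timestamp_column].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise ValueError(f"unparseable timestamp in {path}: {exc}") from exc

    return RawRecordSet(
        timestamps=timestamps,
        values=values,
        labels=labels,
        source_ids=df[schema.source_column].to_numpy(),
        channel_names=list(schema.channel_columns),
    )


def read_ucihar_layout(directory: str | os.PathLike) -> WindowSet:
    """Read a UCI-HAR-style directory of fixed-width window files.

    Expects one whitespace-delimited file per channel (each row one window)
    plus ``y*.txt`` with one integer label per row.  Channel files are every
    other ``*.txt`` file, stacked in sorted-name order.
    """
    directory = os.fspath(directory)
    files = sorted(f for f in os.listdir(directory) if f.endswith(".txt"))
    label_files = [f for f in files if f.startswith("y")]
    channel_files = [f for f in files if not f.startswith("y")]
    if not label_files or not channel_files:
        raise ValueError(
            f"{directory} must contain channel files and a y*.txt label file"
        )
    channels = [
        np.loadtxt(os.path.join(directory, f), ndmin=2) for f in channel_files
    ]
    labels = np.loadtxt(os.path.join(directory, label_files[0]), dtype=np.int64, ndmin=1)
    n_rows = {f: ch.shape[0] for f, ch in zip(channel_files, channels)}
    if len(set(n_rows.values())) > 1:
        raise ValueError(f"row-count mismatch between channel files: {n_rows}")
    n = channels[0].shape[0]
    if len(labels) != n:
        raise ValueError(f"label file has {len(labels)} rows but windows have {n}")
    windows = np.stack(channels, axis=1)  # (n, c, window_len)
    return WindowSet(
        windows=windows,
        labels=labels,
        channel_names=[os.path.splitext(f)[0] for f in channel_files],
        provenance=[(directory, i) for i in range(n)],
    )


def downsample(records: RawRecordSet, factor: int) -> RawRecordSet:
    """Decimate by averaging non-overlapping blocks of ``factor`` samples.

    The nominal rate drops by ``factor``; a trailing partial block is dropped.
    Block label = majority label, ties toward the smaller class id.  NaNs
    propagate (a block containing a missing entry is missing).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return records
    parts = []
    for sid in np.unique(records.source_ids):
        sub = records.take(np.flatnonzero(records.source_ids == sid))
        n_blocks = sub.n_records // factor
        if n_blocks == 0:
            continue
        v = sub.values[: n_blocks * factor].reshape(n_blocks, factor, -1).mean(axis=1)
        ts = sub.timestamps[::factor][:n_blocks]
        labels = np.array(
            [
                _majority_label(sub.labels[i * factor : (i + 1) * factor])
                for i in range(n_blocks)
            ]
        )
        parts.append((ts, v, labels, np.full(n_blocks, sid)))
    if not parts:
        raise ValueError("no source has enough samples for the decimation factor")
    return RawRecordSet(
        timestamps=np.concatenate([p[0] for p in parts]),
        values=np.concatenate([p[1] for p in parts]),
        labels=np.concatenate([p[2] for p in parts]),
        source_ids=np.concatenate([p[3] for p in parts]),
        sample_rate=records.sample_rate / factor,
        stage=records.stage,
        channel_names=list(records.channel_names),
    )


def _majority_label(labels: np.ndarray) -> int:
    """Majority label; ties broken toward the smaller class id."""
    ids, counts = np.unique(labels, return_counts=True)
    return int(ids[np.argmax(counts)])  # np.unique sorts ids -> smaller wins ties


def segment_stream(
    records: RawRecordSet,
    window_len: int,
    hop: int | None = None,
    allow_missing: bool = False,
) -> WindowSet:
    """Cut each source's stream into sliding windows of ``window_len`` samples.

    Windows are half-open ``[start, start + window_len)``; segments shorter
    than a window at the stream end are discarded, never padded.  Window label
    is the majority of member labels (ties toward the smaller class id).
    Requires a cleaned stream unless ``allow_missing`` is set.
    """
    if hop is None:
        hop = window_len
    if hop < 1:
        raise ValueError("hop must be >= 1")
    if not allow_missing and np.isnan(records.values).any():
        raise ValueError(
            "records contain missing values; run cleaning before segmentation"
        )
    windows, labels, prov = [], [], []
    for sid in np.unique(records.source_ids):
        sub = records.take(np.flatnonzero(records.source_ids == sid))
        for start in range(0, sub.n_records - window_len + 1, hop):
            stop = start + window_len
            windows.append(sub.values[start:stop].T)
            labels.append(_majority_label(sub.labels[start:stop]))
            prov.append((str(sid), start))
    if not windows:
        windows_arr = np.empty((0, records.n_channels, window_len))
    else:
        windows_arr = np.stack(windows)
    return WindowSet(
        windows=windows_arr,
        labels=np.asarray(labels, dtype=np.int64),
        channel_names=list(records.channel_names),
        provenance=prov,
        stage="segmented",
    )
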