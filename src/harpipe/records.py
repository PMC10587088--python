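"""Core data containers shared across pipeline stages.

A :class:`RawRecordSet` holds a timestamped multi-channel sensor stream with
possible defects (missing entries are NaN, duplicates and corruption are
ordinary rows until cleaning removes/fixes them).  A :class:`WindowSet` holds
fixed-length labelled windows cut from one or more cleaned streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RawRecordSet", "WindowSet", "MISSING_LABEL"]

#: Sentinel for a record without an activity label.
MISSING_LABEL = -1


@dataclass
class RawRecordSet:
    """Ordered multi-channel sensor records from one or more sources.

    Parameters
    ----------
    timestamps : (n,) int array
        Sample indices, non-decreasing within each source.
    values : (n, n_channels) float array
        Sensor readings; missing entries are ``NaN``.
    labels : (n,) int array
        Integer activity labels, ``MISSING_LABEL`` where absent.
    source_ids : (n,) array of str
        Identifier of the peer/device each record came from.
    sample_rate : float
        Nominal sampling rate in Hz (1.0 after downsampling).
    stage : str
        Provenance tag: ``raw``, ``cleaned``, ``integrated`` or ``digital``.
    """

    timestamps: np.ndarray
    values: np.ndarray
    labels: np.ndarray
    source_ids: np.ndarray
    sample_rate: float = 1.0
    stage: str = "raw"
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.source_ids = np.asarray(self.source_ids)
        if not self.channel_names:
            self.channel_names = [f"ch_{i}" for i in range(self.n_channels)]
        n = len(self.timestamps)
        if not (len(self.values) == len(self.labels) == len(self.source_ids) == n):
            raise ValueError("timestamps, values, labels and source_ids must align")
        for sid in np.unique(self.source_ids):
            ts = self.timestamps[self.source_ids == sid]
            if np.any(np.diff(ts) < 0):
                raise ValueError(f"timestamps not non-decreasing for source {sid!r}")

    @property
    def n_records(self) -> int:
        return len(self.timestamps)

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """(n, n_channels) boolean mask of missing entries."""
        return np.isnan(self.values)

    def with_stage(self, stage: str) -> "RawRecordSet":
        return replace(self, stage=stage)

    def take(self, index: np.ndarray) -> "RawRecordSet":
        """Subset of records (order preserved)."""
        return replace(
            self,
            timestamps=self.timestamps[index],
            values=self.values[index],
            labels=self.labels[index],
            source_ids=self.source_ids[index],
        )


@dataclass
class WindowSet:
    """Labelled fixed-length windows: ``windows[i]`` is (n_channels, window_len)."""

    windows: np.ndarray
    labels: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    provenance: list[tuple[str, int]] = field(default_factory=list)
    stage: str = "windows"

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        if self.windows.ndim != 3:
            raise ValueError("windows must have shape (n, n_channels, window_len)")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.windows):
            raise ValueError("labels must align with windows")
        if not self.channel_names:
            self.channel_names = [f"ch_{i}" for i in range(self.n_channels)]

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]

    @property
    def window_len(self) -> int:
        return self.windows.shape[2]

    def take(self, index: np.ndarray) -> "WindowSet":
        index = np.asarray(index)
        return WindowSet(
            windows=self.windows[index],
            labels=self.labels[index],
            channel_names=list(self.channel_names),
            provenance=[self.provenance[i] for i in index] if self.provenance else [],
            stage=self.stage,
        )
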