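"""Synthetic wearable-sensor data with controlled defects.

The generator emulates the statistical structure the recognition pipeline
assumes: each activity class is a mixture of per-channel sinusoids (inertial
signals are quasi-periodic) plus Gaussian sensor noise and a per-window
constant drift.  Data defects — missing entries, exact duplicate records and
corrupted (spiked) values — are injected at configurable rates with their
positions recorded, so cleaning can be scored against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import MISSING_LABEL, RawRecordSet

__all__ = [
    "ActivityModel",
    "DefectSpec",
    "GroundTruth",
    "default_activity_models",
    "generate_dataset",
    "generate_informative_feature_table",
]


@dataclass(frozen=True)
class ActivityModel:
    """Signal model for one activity class.

    ``base_freqs[c]`` is a list of oscillation frequencies (cycles/sample,
    below the 0.5 Nyquist limit) for channel ``c``; ``amplitudes[c]`` scales
    that channel.  ``drift`` is the half-width of the uniform per-window
    constant offset.
    """

    class_id: int
    name: str
    base_freqs: tuple[tuple[float, ...], ...]
    amplitudes: tuple[float, ...]
    noise_sd: float = 0.3
    drift: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for ch in self.base_freqs:
            for f in ch:
                if not 0.0 < f < 0.5:
                    raise ValueError(f"frequency {f} outside (0, 0.5) cycles/sample")


@dataclass(frozen=True)
class DefectSpec:
    """Rates of the three injected defect kinds, as fractions of records."""

    missing_rate: float = 0.0
    duplicate_rate: float = 0.0
    corrupt_rate: float = 0.0
    corrupt_magnitude: float = 50.0

    def __post_init__(self) -> None:
        rates = (self.missing_rate, self.duplicate_rate, self.corrupt_rate)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("defect rates must lie in [0, 1]")
        if sum(rates) > 1.0:
            raise ValueError("defect rates must sum to at most 1")


@dataclass
class GroundTruth:
    """Bookkeeping of what the generator actually did.

    ``clean_values`` is the defect-free stream; the defect masks/flags index
    into the *emitted* record order (after duplicate insertion).
    """

    clean_values: np.ndarray
    missing_mask: np.ndarray          # (n, c) True where an entry was blanked
    corrupt_mask: np.ndarray          # (n, c) True where an entry was spiked
    duplicate_flags: np.ndarray       # (n,) True for inserted duplicate rows
    window_labels: np.ndarray         # (n_windows,) class of each window

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    @property
    def n_corrupt(self) -> int:
        return int(self.corrupt_mask.sum())

    @property
    def n_duplicates(self) -> int:
        return int(self.duplicate_flags.sum())


def default_activity_models(n_channels: int = 3) -> list[ActivityModel]:
    """Five default activities: walking, blinking, standing, sitting, emergency.

    Frequencies span the sub-Nyquist octaves a dyadic wavelet bank resolves;
    near-static postures get low amplitude, the emergency class a large one.
    """
    base = [
        ("walking", [0.06, 0.10, 0.08], 1.0),
        ("blinking", [0.22, 0.18, 0.25], 0.8),
        ("standing", [0.03, 0.025, 0.035], 0.3),
        ("sitting", [0.012, 0.015, 0.02], 0.15),
        ("emergency", [0.30, 0.35, 0.28], 2.0),
    ]
    models = []
    for cid, (name, freqs, amp) in enumerate(base):
        ch_freqs = tuple((freqs[c % len(freqs)],) for c in range(n_channels))
        models.append(
            ActivityModel(
                class_id=cid,
                name=name,
                base_freqs=ch_freqs,
                amplitudes=tuple(amp for _ in range(n_channels)),
            )
        )
    return models


def _clean_windows(
    models: list[ActivityModel],
    n_windows_per_class: int,
    window_len: int,
    n_channels: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Defect-free (n_windows, c, L) stack and per-window labels."""
    t = np.arange(window_len)
    windows, labels = [], []
    for model in models:
        for _ in range(n_windows_per_class):
            w = np.empty((n_channels, window_len))
            for c in range(n_channels):
                freqs = model.base_freqs[c % len(model.base_freqs)]
                amp = model.amplitudes[c % len(model.amplitudes)]
                phase = rng.uniform(0, 2 * np.pi, size=len(freqs))
                sig = sum(
                    amp * np.sin(2 * np.pi * f * t + p) for f, p in zip(freqs, phase)
                )
                sig = sig + rng.normal(0.0, model.noise_sd, size=window_len)
                sig = sig + rng.uniform(-model.drift, model.drift)
                w[c] = sig
            windows.append(w)
            labels.append(model.class_id)
    return np.stack(windows), np.asarray(labels, dtype=np.int64)


def generate_dataset(
    models: list[ActivityModel],
    n_windows_per_class: int = 200,
    window_len: int = 128,
    n_channels: int = 3,
    defects: DefectSpec | None = None,
    seed: int = 0,
    source_id: str = "sim0",
) -> tuple[RawRecordSet, GroundTruth]:
    """Generate a raw record stream of labelled activity windows plus defects.

    Windows are laid back-to-back in the stream (one activity per window,
    classes interleaved in order), then defects are injected: ``missing``
    blanks one channel entry to NaN, ``corrupt`` multiplies one entry by
    ``corrupt_magnitude`` and ``duplicate`` inserts an exact copy of a record
    directly after it.  Defect sites are disjoint across kinds.  Identical
    ``seed`` gives bit-identical output.
    """
    if not models:
        raise ValueError("at least one ActivityModel is required")
    if window_len < 8:
        raise ValueError("window_len must be at least 8")
    if n_windows_per_class < 1:
        raise ValueError("n_windows_per_class must be at least 1")
    defects = defects or DefectSpec()
    rng = np.random.default_rng(seed)

    windows, win_labels = _clean_windows(
        models, n_windows_per_class, window_len, n_channels, rng
    )
    # interleave classes so the stream alternates activities
    order = np.argsort(np.tile(np.arange(n_windows_per_class), len(models)), kind="stable")
    windows, win_labels = windows[order], win_labels[order]

    n = windows.shape[0] * window_len
    clean = windows.transpose(0, 2, 1).reshape(n, n_channels)
    rec_labels = np.repeat(win_labels, window_len)

    # choose disjoint record slots for each defect kind
    n_missing = int(round(defects.missing_rate * n))
    n_corrupt = int(round(defects.corrupt_rate * n))
    n_dup = int(round(defects.duplicate_rate * n))
    slots = rng.permutation(n)
    miss_rows = slots[:n_missing]
    corr_rows = slots[n_missing : n_missing + n_corrupt]
    dup_rows = slots[n_missing + n_corrupt : n_missing + n_corrupt + n_dup]

    values = clean.copy()
    missing_mask = np.zeros_like(values, dtype=bool)
    corrupt_mask = np.zeros_like(values, dtype=bool)
    if n_missing:
        cols = rng.integers(0, n_channels, size=n_missing)
        values[miss_rows, cols] = np.nan
        missing_mask[miss_rows, cols] = True
    if n_corrupt:
        cols = rng.integers(0, n_channels, size=n_corrupt)
        values[corr_rows, cols] *= defects.corrupt_magnitude
        corrupt_mask[corr_rows, cols] = True

    # duplicate = insert exact copy right after the chosen record
    insert_after = np.sort(dup_rows)
    out_index = np.insert(np.arange(n), insert_after + 1, insert_after)
    dup_flags = np.zeros(len(out_index), dtype=bool)
    # positions of the inserted copies in the emitted order
    inserted_at = insert_after + 1 + np.arange(len(insert_after))
    dup_flags[inserted_at] = True

    gt = GroundTruth(
        clean_values=clean,
        missing_mask=missing_mask[out_index],
        corrupt_mask=corrupt_mask[out_index],
        duplicate_flags=dup_flags,
        window_labels=win_labels,
    )
    records = RawRecordSet(
        timestamps=np.arange(n)[out_index],
        values=values[out_index],
        labels=rec_labels[out_index],
        source_ids=np.full(len(out_index), source_id),
        sample_rate=1.0,
        stage="raw",
    )
    return records, gt


def generate_informative_feature_table(
    n_samples: int,
    n_features: int,
    n_informative: int,
    effect_size: float,
    n_classes: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian feature table with planted class-informative columns.

    Informative columns get a class-conditional mean shift of ``effect_size``
    standard deviations (class k shifted by ``k * effect_size``); the rest are
    exchangeable N(0, 1) noise.  Returns ``(X, y, informative_indices)``.
    """
    if n_informative > n_features:
        raise ValueError("n_informative cannot exceed n_features")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_classes, size=n_samples)
    X = rng.normal(size=(n_samples, n_features))
    informative = rng.choice(n_features, size=n_informative, replace=False)
    informative.sort()
    for j in informative:
        X[:, j] += effect_size * y
    return X, y, informative
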