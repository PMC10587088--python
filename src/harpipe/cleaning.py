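"""Mode-Integrated Binning Algorithm (MIBA) for sensor-stream cleaning.

Each channel's values are partitioned into bins; values are smoothed by a
per-bin representative (mean, median or nearest boundary), and missing values
are imputed with the channel's *grouped mode*

    M = l + t * (F_m - F_p) / ((F_m - F_p) + (F_m - F_s)),

the classical mode estimate for binned data from the modal bin's lower limit
``l``, width ``t`` and the modal/preceding/succeeding bin frequencies.  Exact
consecutive duplicate records are removed before smoothing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .records import RawRecordSet

__all__ = [
    "grouped_mode",
    "BinningModel",
    "CleaningModel",
    "fit_bins",
    "fit_cleaning_model",
    "drop_consecutive_duplicates",
    "clean",
    "apply_to_array",
    "DegenerateModeError",
]

logger = logging.getLogger(__name__)


class DegenerateModeError(ValueError):
    """Raised when the grouped-mode formula degenerates to 0/0 (flat histogram)."""


def grouped_mode(l: float, t: float, F_m: float, F_p: float, F_s: float) -> float:
    """Mode of grouped data from the modal class and its neighbours.

    Parameters are the modal class lower limit ``l``, class width ``t``, and
    the modal, preceding and succeeding class frequencies.  The result always
    lies in ``[l, l + t]``.
    """
    if t <= 0:
        raise ValueError("class width t must be positive")
    if F_m < F_p or F_m < F_s:
        raise ValueError("modal frequency must be the maximum")
    denom = (F_m - F_p) + (F_m - F_s)
    if denom == 0:
        raise DegenerateModeError(
            "flat histogram around the modal class: grouped mode is 0/0"
        )
    return l + t * (F_m - F_p) / denom


@dataclass
class BinningModel:
    """Fitted binning of one channel."""

    edges: np.ndarray                 # len n_bins + 1, strictly increasing
    frequencies: np.ndarray           # len n_bins, counts of non-missing values
    representatives: np.ndarray       # len n_bins, smoothing value per bin
    modal_class_index: int
    mode_value: float
    smoothing: str = "means"

    @property
    def n_bins(self) -> int:
        return len(self.frequencies)

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value; out-of-range values clamp into terminal bins."""
        idx = np.searchsorted(self.edges, values, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)

    def smooth(self, values: np.ndarray) -> np.ndarray:
        """Replace non-missing values by their bin representative; impute NaN
        with the grouped mode."""
        out = np.where(
            np.isnan(values), self.mode_value, self.representatives[self.assign(values)]
        )
        return out


def fit_bins(
    values: np.ndarray,
    n_bins: int = 16,
    strategy: str = "equal-frequency",
    smoothing: str = "means",
) -> BinningModel:
    """Fit a :class:`BinningModel` on the non-missing values of one channel.

    ``strategy`` is ``equal-width`` or ``equal-frequency`` (quantile edges).
    Frequencies are counted over half-open bins with the last bin closed.
    If there are fewer distinct values than bins, the binning collapses to
    distinct-value bins with a warning.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise ValueError("cannot fit bins on an all-missing channel")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    distinct = np.unique(values)

    if len(distinct) == 1:
        c = float(distinct[0])
        eps = max(abs(c), 1.0) * 1e-9
        return BinningModel(
            edges=np.array([c - eps, c + eps]),
            frequencies=np.array([len(values)]),
            representatives=np.array([c]),
            modal_class_index=0,
            mode_value=c,
            smoothing=smoothing,
        )

    if len(distinct) < n_bins:
        warnings.warn(
            f"only {len(distinct)} distinct values for {n_bins} bins; "
            "collapsing to distinct-value bins",
            stacklevel=2,
        )
        mids = (distinct[:-1] + distinct[1:]) / 2
        edges = np.concatenate([[distinct[0]], mids, [distinct[-1]]])
        # widen terminal edges a hair so both extremes fall inside
        edges[0] -= max(abs(edges[0]), 1.0) * 1e-9
    elif strategy == "equal-width":
        edges = np.linspace(values.min(), values.max(), n_bins + 1)
    elif strategy == "equal-frequency":
        qs = np.linspace(0, 1, n_bins + 1)
        edges = np.quantile(values, qs)
        edges = np.unique(edges)
        if len(edges) < 3:
            edges = np.linspace(values.min(), values.max(), n_bins + 1)
    else:
        raise ValueError(f"unknown binning strategy {strategy!r}")

    freqs, _ = np.histogram(values, bins=edges)  # last bin closed, as needed
    idx = np.searchsorted(edges, values, side="right") - 1
    idx = np.clip(idx, 0, len(freqs) - 1)

    reps = np.empty(len(freqs))
    for b in range(len(freqs)):
        members = values[idx == b]
        lo, hi = edges[b], edges[b + 1]
        if smoothing == "means":
            reps[b] = members.mean() if len(members) else (lo + hi) / 2
        elif smoothing == "medians":
            reps[b] = np.median(members) if len(members) else (lo + hi) / 2
        elif smoothing == "boundaries":
            mid = (lo + hi) / 2
            reps[b] = lo  # placeholder; boundary smoothing acts per value
        else:
            raise ValueError(f"unknown smoothing {smoothing!r}")

    modal = int(np.argmax(freqs))
    l, t = float(edges[modal]), float(edges[modal + 1] - edges[modal])
    F_m = float(freqs[modal])
    F_p = float(freqs[modal - 1]) if modal > 0 else 0.0
    F_s = float(freqs[modal + 1]) if modal < len(freqs) - 1 else 0.0
    try:
        mode_value = grouped_mode(l, t, F_m, F_p, F_s)
    except DegenerateModeError:
        logger.info("flat histogram: grouped mode fell back to modal-bin midpoint")
        mode_value = l + t / 2

    model = BinningModel(
        edges=edges,
        frequencies=freqs,
        representatives=reps,
        modal_class_index=modal,
        mode_value=mode_value,
        smoothing=smoothing,
    )
    if smoothing == "boundaries":
        # nearest-edge smoothing: representative depends on the value's side
        # of the bin midpoint, handled in smooth() via representatives of
        # both edges; encode as midpoint rule
        model.representatives = edges[:-1]  # lower edges; smooth() special-cases
        model = _BoundaryBinningModel(**model.__dict__)
    return model


class _BoundaryBinningModel(BinningModel):
    """Bin-boundary smoothing: each value snaps to the nearest bin edge."""

    def smooth(self, values: np.ndarray) -> np.ndarray:
        idx = self.assign(values)
        lo, hi = self.edges[idx], self.edges[idx + 1]
        snapped = np.where(np.abs(values - lo) <= np.abs(hi - values), lo, hi)
        return np.where(np.isnan(values), self.mode_value, snapped)


@dataclass
class CleaningModel:
    """Per-channel binning models for a whole record set."""

    channels: list[BinningModel] = field(default_factory=list)

    def smooth(self, values: np.ndarray) -> np.ndarray:
        """Apply per-channel smoothing + imputation to an (n, c) array."""
        if values.shape[1] != len(self.channels):
            raise ValueError("channel count mismatch with fitted model")
        out = np.empty_like(values, dtype=float)
        for j, model in enumerate(self.channels):
            out[:, j] = model.smooth(values[:, j])
        return out


def fit_cleaning_model(
    values: np.ndarray,
    n_bins: int = 16,
    strategy: str = "equal-frequency",
    smoothing: str = "means",
    channel_names: list[str] | None = None,
) -> CleaningModel:
    """Fit per-channel bins on an (n, c) value array (NaNs ignored)."""
    models = []
    for j in range(values.shape[1]):
        col = values[:, j]
        if np.all(np.isnan(col)):
            name = channel_names[j] if channel_names else f"ch_{j}"
            raise ValueError(f"channel {name} is entirely missing; cannot clean")
        models.append(fit_bins(col, n_bins=n_bins, strategy=strategy, smoothing=smoothing))
    return CleaningModel(channels=models)


def drop_consecutive_duplicates(records: RawRecordSet) -> tuple[RawRecordSet, int]:
    """Remove records identical to their predecessor in source, timestamp,
    all channel values (NaN-aware) and label.  Returns (deduped, n_removed)."""
    n = records.n_records
    if n == 0:
        return records, 0
    same_vals = np.all(
        (records.values[1:] == records.values[:-1])
        | (np.isnan(records.values[1:]) & np.isnan(records.values[:-1])),
        axis=1,
    )
    dup = (
        same_vals
        & (records.timestamps[1:] == records.timestamps[:-1])
        & (records.labels[1:] == records.labels[:-1])
        & (records.source_ids[1:] == records.source_ids[:-1])
    )
    keep = np.concatenate([[True], ~dup])
    return records.take(np.flatnonzero(keep)), int((~keep).sum())


def clean(
    records: RawRecordSet,
    n_bins: int = 16,
    strategy: str = "equal-frequency",
    smoothing: str = "means",
    model: CleaningModel | None = None,
) -> tuple[RawRecordSet, CleaningModel]:
    """Full MIBA cleaning: dedupe, bin-smooth, impute missing with the mode.

    A prefitted ``model`` can be supplied (e.g. fitted on a training split);
    otherwise bins are fitted on this record set's non-missing values.
    The output carries ``stage='cleaned'`` and no missing entries.
    """
    deduped, _ = drop_consecutive_duplicates(records)
    if model is None:
        model = fit_cleaning_model(
            deduped.values,
            n_bins=n_bins,
            strategy=strategy,
            smoothing=smoothing,
            channel_names=deduped.channel_names,
        )
    smoothed = model.smooth(deduped.values)
    out = RawRecordSet(
        timestamps=deduped.timestamps,
        values=smoothed,
        labels=deduped.labels,
        source_ids=deduped.source_ids,
        sample_rate=deduped.sample_rate,
        stage="cleaned",
        channel_names=list(deduped.channel_names),
    )
    return out, model


def apply_to_array(model: CleaningModel, values: np.ndarray) -> np.ndarray:
    """Smooth + impute an arbitrary (n, c) array with a fitted model."""
    return model.smooth(values)
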