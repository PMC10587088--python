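"""Peer-to-peer integration and E-C-D discretization.

Integration merges cleaned streams from several sources (peers) into one
stream ordered by ``(source_id, timestamp)``, optionally harmonizing units
with per-source affine maps.

E-C-D (Entropy / Candidate-k partition / Discretization) turns each
continuous channel into a small set of levels: per-channel Shannon histogram
entropy (scaled by a Boltzmann-style constant ``C_boltz``) weights the
channels, 1-D k-means is run for each candidate cluster count, the k with the
best mean silhouette wins, and values are then quantized to their nearest
centroid.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .records import RawRecordSet

__all__ = [
    "integrate",
    "channel_entropy",
    "DiscretizationModel",
    "fit_discretizer",
    "discretize",
]

logger = logging.getLogger(__name__)


def integrate(
    sources: list[RawRecordSet],
    affine_maps: dict[str, tuple[float, float]] | None = None,
) -> RawRecordSet:
    """Merge cleaned sources into one stream ordered by (source_id, timestamp).

    ``affine_maps`` optionally maps a source_id to ``(scale, offset)`` applied
    to all its channels (unit harmonization).  Record count is conserved.
    """
    if not sources:
        raise ValueError("need at least one source")
    schema = sources[0].channel_names
    for s in sources[1:]:
        if s.channel_names != schema:
            diff = set(s.channel_names) ^ set(schema)
            raise ValueError(f"channel schema mismatch between sources: {sorted(diff)}")
    parts = []
    for s in sources:
        v = s.values
        if affine_maps:
            sid_arr = s.source_ids
            v = v.copy()
            for sid, (a, b) in affine_maps.items():
                m = sid_arr == sid
                v[m] = a * v[m] + b
        parts.append((s, v))
    ts = np.concatenate([s.timestamps for s, _ in parts])
    vals = np.concatenate([v for _, v in parts])
    labels = np.concatenate([s.labels for s, _ in parts])
    sids = np.concatenate([s.source_ids for s, _ in parts])
    order = np.lexsort((np.arange(len(ts)), ts, sids))
    return RawRecordSet(
        timestamps=ts[order],
        values=vals[order],
        labels=labels[order],
        source_ids=sids[order],
        sample_rate=sources[0].sample_rate,
        stage="integrated",
        channel_names=list(schema),
    )


def channel_entropy(values: np.ndarray, n_hist_bins: int = 32, C_boltz: float = 1.0) -> float:
    """Boltzmann-scaled Shannon entropy (nats) of a channel's value histogram.

    Empty histogram bins are skipped; a channel concentrated in one bin has
    zero entropy.  ``C_boltz = 1`` gives pure Shannon entropy.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    if n_hist_bins < 1:
        raise ValueError("n_hist_bins must be >= 1")
    counts, _ = np.histogram(values, bins=n_hist_bins)
    p = counts[counts > 0] / counts.sum()
    return float(C_boltz * -(p * np.log(p)).sum())


@dataclass
class DiscretizationModel:
    """Fitted E-C-D model: per-channel sorted centroids at the chosen k."""

    k: int
    centroids: list[np.ndarray]            # per channel, sorted ascending
    entropies: np.ndarray                  # per channel, nats
    weights: np.ndarray                    # entropy weights E / sum(E)
    candidate_ks: list[int] = field(default_factory=list)
    inertia: dict[int, float] = field(default_factory=dict)     # per candidate k
    silhouette: dict[int, float] = field(default_factory=dict)  # per candidate k
    C_boltz: float = 1.0

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "centroids": [c.tolist() for c in self.centroids],
            "entropies": self.entropies.tolist(),
            "weights": self.weights.tolist(),
            "candidate_ks": list(self.candidate_ks),
            "inertia": {str(k): v for k, v in self.inertia.items()},
            "silhouette": {str(k): v for k, v in self.silhouette.items()},
            "C_boltz": self.C_boltz,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DiscretizationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            k=d["k"],
            centroids=[np.asarray(c) for c in d["centroids"]],
            entropies=np.asarray(d["entropies"]),
            weights=np.asarray(d["weights"]),
            candidate_ks=d["candidate_ks"],
            inertia={int(k): v for k, v in d["inertia"].items()},
            silhouette={int(k): v for k, v in d["silhouette"].items()},
            C_boltz=d["C_boltz"],
        )


def _kmeans_1d(x: np.ndarray, k: int, n_init: int, seed: int) -> tuple[np.ndarray, float, np.ndarray]:
    """Best-of-restarts 1-D k-means; returns (sorted centroids, inertia, labels)."""
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, max_iter=300, tol=1e-6)
    lab = km.fit_predict(x.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    centroids = km.cluster_centers_.ravel()[order]
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return centroids, float(km.inertia_), relabel[lab]


def fit_discretizer(
    stream: RawRecordSet,
    candidate_ks: list[int] = (3, 4, 6, 8, 12),
    n_init: int = 10,
    seed: int = 0,
    n_hist_bins: int = 32,
    C_boltz: float = 1.0,
    max_silhouette_samples: int = 2000,
) -> DiscretizationModel:
    """Fit E-C-D: entropy-weight channels, k-means per candidate k, pick the
    k with the highest mean silhouette over channels.

    Candidates exceeding a channel's distinct-value count are skipped with a
    warning; if every candidate is skipped an error is raised.
    """
    if len(candidate_ks) == 0:
        raise ValueError("candidate_ks must be non-empty")
    X = stream.values
    if np.isnan(X).any():
        raise ValueError("stream contains missing values; clean before discretizing")
    n, c = X.shape
    entropies = np.array([channel_entropy(X[:, j], n_hist_bins, C_boltz) for j in range(c)])
    total = entropies.sum()
    weights = entropies / total if total > 0 else np.full(c, 1.0 / c)
    # positive per-channel scaling leaves the 1-D partition unchanged; the
    # weights are applied for fidelity and the centroids mapped back
    scale = np.where(weights > 0, weights, 1.0)

    rng = np.random.default_rng(seed)
    n_distinct = [len(np.unique(X[:, j])) for j in range(c)]
    results: dict[int, tuple[list[np.ndarray], float, float]] = {}
    for k in candidate_ks:
        if any(k > d for d in n_distinct):
            warnings.warn(f"candidate k={k} exceeds distinct values; skipped", stacklevel=2)
            continue
        cents, inert, sils = [], 0.0, []
        for j in range(c):
            xs = X[:, j] * scale[j]
            cj, ij, labj = _kmeans_1d(xs, k, n_init, seed + 31 * j + k)
            cents.append(cj / scale[j])
            inert += ij / scale[j] ** 2
            if k >= 2:
                if n > max_silhouette_samples:
                    idx = rng.choice(n, max_silhouette_samples, replace=False)
                else:
                    idx = np.arange(n)
                if len(np.unique(labj[idx])) >= 2:
                    sils.append(
                        silhouette_score(xs[idx].reshape(-1, 1), labj[idx])
                    )
        sil = float(np.mean(sils)) if sils else -np.inf
        results[k] = (cents, inert, sil)
    if not results:
        raise ValueError("all candidate cluster counts were skipped (too few distinct values)")
    best_k = max(results, key=lambda k: results[k][2])
    cents, _, _ = results[best_k]
    return DiscretizationModel(
        k=best_k,
        centroids=cents,
        entropies=entropies,
        weights=weights,
        candidate_ks=[k for k in candidate_ks],
        inertia={k: v[1] for k, v in results.items()},
        silhouette={k: v[2] for k, v in results.items()},
        C_boltz=C_boltz,
    )


def quantize_channel(values: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Map each value to its nearest centroid; ties go to the smaller centroid."""
    if len(centroids) == 1:
        return np.full_like(values, centroids[0])
    mids = (centroids[:-1] + centroids[1:]) / 2
    idx = np.searchsorted(mids, values, side="left")
    return centroids[idx]


def discretize(stream: RawRecordSet, model: DiscretizationModel) -> RawRecordSet:
    """Quantize every value to its channel's nearest centroid (stage ``digital``)."""
    X = stream.values
    if X.shape[1] != len(model.centroids):
        raise ValueError("channel count mismatch with fitted discretizer")
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = quantize_channel(X[:, j], model.centroids[j])
    return RawRecordSet(
        timestamps=stream.timestamps,
        values=out,
        labels=stream.labels,
        source_ids=stream.source_ids,
        sample_rate=stream.sample_rate,
        stage="digital",
        channel_names=list(stream.channel_names),
    )
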