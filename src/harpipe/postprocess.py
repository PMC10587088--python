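"""Scatter-matrix post-processing of the selected features.

The scatter matrix is the unnormalized sum of centered outer products over
samples (n times the biased covariance); its diagonal yields per-feature
scales used to z-score the features.  The summary is fitted on the training
split only and then applied frozen to the test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["ScatterSummary", "scatter_matrix", "normalize", "denormalize"]

logger = logging.getLogger(__name__)


@dataclass
class ScatterSummary:
    """Mean vector, scatter matrix and the derived normalization scales."""

    mean: np.ndarray              # length d
    scatter: np.ndarray           # (d, d), symmetric PSD
    scale: np.ndarray             # sqrt(diag(scatter)/n); zero-variance -> 1
    n_samples: int


def scatter_matrix(samples: np.ndarray) -> ScatterSummary:
    """Scatter matrix sum_i (x_i - mean)(x_i - mean)^T over sample vectors.

    A single sample yields the zero matrix (with a warning); the result is
    exactly symmetric and positive semi-definite.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    n, d = X.shape
    if n < 1:
        raise ValueError("need at least one sample vector")
    mean = X.mean(axis=0)
    centered = X - mean
    scatter = centered.T @ centered
    scatter = (scatter + scatter.T) / 2  # exact symmetry against rounding
    if n == 1:
        logger.warning("scatter matrix of a single sample is identically zero")
    var = np.diag(scatter) / n
    scale = np.sqrt(var)
    zero = scale <= 0
    if zero.any():
        logger.info("%d zero-variance feature(s); scale set to 1", int(zero.sum()))
        scale = np.where(zero, 1.0, scale)
    return ScatterSummary(mean=mean, scatter=scatter, scale=scale, n_samples=n)


def normalize(features: np.ndarray, summary: ScatterSummary) -> np.ndarray:
    """Z-score columns with the fitted mean and scatter-diagonal scales."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != summary.mean.size:
        raise ValueError(
            f"feature dimension {X.shape[1]} != fitted dimension {summary.mean.size}"
        )
    return (X - summary.mean) / summary.scale


def denormalize(features: np.ndarray, summary: ScatterSummary) -> np.ndarray:
    """Inverse of :func:`normalize` (exact where scales are nonzero)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    return X * summary.scale + summary.mean
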