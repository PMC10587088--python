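"""Evaluation metrics: one-vs-rest confusion counts, accuracy, precision,
recall and F-score (reported as percentages), with macro averaging across
classes.  Zero-denominator cases report 0 with an ``undefined`` flag rather
than NaN."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "MetricReport",
    "confusion_counts",
    "compute_metrics",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class ClassMetrics:
    """Percent metrics for one one-vs-rest table."""

    accuracy: float
    precision: float
    recall: float
    f_score: float
    undefined: list[str] = field(default_factory=list)


def compute_metrics(counts: ConfusionCounts) -> ClassMetrics:
    """Accuracy, precision, recall, F-score in percent from one table.

    accuracy  = (TP + TN) / (TP + FN + TN + FP) * 100
    precision = TP / (TP + FP) * 100
    recall    = TP / (TP + FN) * 100
    F-score   = 2 * precision * recall / (precision + recall)

    A zero denominator yields 0 for that metric and its name is appended to
    ``undefined``.
    """
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den * 100.0

    acc = ratio(counts.TP + counts.TN, counts.n, "accuracy")
    prec = ratio(counts.TP, counts.TP + counts.FP, "precision")
    rec = ratio(counts.TP, counts.TP + counts.FN, "recall")
    if prec + rec == 0:
        undefined.append("f_score")
        f = 0.0
    else:
        f = 2 * prec * rec / (prec + rec)
    return ClassMetrics(accuracy=acc, precision=prec, recall=rec, f_score=f,
                        undefined=undefined)


def confusion_counts(
    y_true: np.ndarray, y_pred: np.ndarray, class_ids: np.ndarray | None = None
) -> dict[int, ConfusionCounts]:
    """Per-class one-vs-rest counts; each table sums to n_samples."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must align")
    if class_ids is None:
        class_ids = np.unique(np.concatenate([y_true, y_pred]))
    out = {}
    for c in class_ids:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        tn = int(np.sum((y_true != c) & (y_pred != c)))
        out[int(c)] = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
    return out


@dataclass
class MetricReport:
    """Overall and per-class evaluation of a prediction set (percentages)."""

    accuracy: float                       # multi-class accuracy
    macro_precision: float
    macro_recall: float
    macro_f_score: float
    per_class: dict[int, ClassMetrics]
    n_samples: int
    seed: int | None = None
    config_hash: str | None = None
    split_sizes: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": round(self.accuracy, 3),
            "macro_precision": round(self.macro_precision, 3),
            "macro_recall": round(self.macro_recall, 3),
            "macro_f_score": round(self.macro_f_score, 3),
            "n_samples": self.n_samples,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "split_sizes": self.split_sizes,
            "per_class": {
                str(c): {
                    "accuracy": round(m.accuracy, 3),
                    "precision": round(m.precision, 3),
                    "recall": round(m.recall, 3),
                    "f_score": round(m.f_score, 3),
                    "undefined": m.undefined,
                }
                for c, m in self.per_class.items()
            },
        }


def evaluate_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, class_ids: np.ndarray | None = None
) -> MetricReport:
    """Full report: multi-class accuracy plus macro one-vs-rest metrics."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    counts = confusion_counts(y_true, y_pred, class_ids)
    per_class = {c: compute_metrics(cc) for c, cc in counts.items()}
    accuracy = float(np.mean(y_true == y_pred) * 100.0)
    return MetricReport(
        accuracy=accuracy,
        macro_precision=float(np.mean([m.precision for m in per_class.values()])),
        macro_recall=float(np.mean([m.recall for m in per_class.values()])),
        macro_f_score=float(np.mean([m.f_score for m in per_class.values()])),
        per_class=per_class,
        n_samples=len(y_true),
    )
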