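"""Confusion-matrix scores and average silhouette width."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import silhouette_score


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count the four joint outcomes of binary truth vs prediction."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    for name, a in (("y_true", t), ("y_pred", p)):
        if not np.isin(a, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def scores(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, f1).

    accuracy = (TP+TN)/(TP+TN+FP+FN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); f1 = 2TP/(2TP+FP+FN).  A zero denominator
    yields 0 with a warning, so an all-negative classifier scores
    recall 0 and F1 0 rather than NaN.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")

    def safe(num, den, name):
        if den == 0:
            warnings.warn(f"{name} denominator is 0; returning 0", stacklevel=3)
            return 0.0
        return num / den

    accuracy = (c.tp + c.tn) / c.total
    precision = safe(c.tp, c.tp + c.fp, "precision")
    recall = safe(c.tp, c.tp + c.fn, "recall")
    f1 = safe(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1")
    return accuracy, precision, recall, f1


def silhouette(points, labels) -> float:
    """Average silhouette width under Euclidean distance, in [-1, 1].

    Per-point s(i) = (b(i) - a(i)) / max(a(i), b(i)); singleton clusters
    contribute 0.
    """
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires >= 2 clusters")
    return float(silhouette_score(points, labels, metric="euclidean"))
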