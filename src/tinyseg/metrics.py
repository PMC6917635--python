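"""Segmentation quality metrics computed from a pixel confusion matrix.

All four metrics derive from the c x c confusion matrix N, where
``N[i, j]`` counts pixels of true class i predicted as class j:

- pixel accuracy      = sum_i N[i, i] / sum_ij N[i, j]
- mean IoU            = (1/c) sum_i N[i, i] / (row_i + col_i - N[i, i])
- average precision   = (1/c) sum_i N[i, i] / col_i
- average recall      = (1/c) sum_i N[i, i] / row_i

with ``row_i`` / ``col_i`` the i-th row and column sums.  When a class
contributes a zero denominator, its per-class term is defined as 1 if
the class is entirely absent (no true and no predicted pixels — the
model was vacuously correct about it) and 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "pixel_accuracy",
    "mean_iou",
    "average_precision",
    "average_recall",
    "evaluate_confusion",
]


@dataclass
class ConfusionMatrix:
    """Accumulates pixel counts N[true, predicted] over many images."""

    n_classes: int
    counts: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.counts is None:
            self.counts = np.zeros((self.n_classes, self.n_classes), np.int64)
        else:
            self.counts = np.asarray(self.counts, np.int64)
            if self.counts.shape != (self.n_classes, self.n_classes):
                raise ValueError("counts shape does not match n_classes")

    def accumulate(self, true_labels: np.ndarray, pred_labels: np.ndarray) -> None:
        t = np.asarray(true_labels).ravel()
        p = np.asarray(pred_labels).ravel()
        if t.shape != p.shape:
            raise ValueError("true and predicted label maps differ in size")
        if t.min() < 0 or t.max() >= self.n_classes or p.min() < 0 or p.max() >= self.n_classes:
            raise ValueError(f"labels outside [0, {self.n_classes})")
        np.add.at(self.counts, (t, p), 1)

    @property
    def total_pixels(self) -> int:
        return int(self.counts.sum())


def _as_counts(cm) -> np.ndarray:
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("confusion matrix must be square")
    if counts.sum() == 0:
        raise ValueError("confusion matrix is empty")
    return counts.astype(np.float64)


def _per_class(numer: np.ndarray, denom: np.ndarray, absent: np.ndarray) -> np.ndarray:
    """Safe per-class ratio with the zero-denominator convention."""
    out = np.zeros_like(numer)
    nz = denom > 0
    out[nz] = numer[nz] / denom[nz]
    out[~nz] = np.where(absent[~nz], 1.0, 0.0)
    return out


def pixel_accuracy(cm) -> float:
    n = _as_counts(cm)
    return float(np.trace(n) / n.sum())


def _terms(cm):
    n = _as_counts(cm)
    diag = np.diag(n)
    row, col = n.sum(axis=1), n.sum(axis=0)
    absent = (row == 0) & (col == 0)
    return diag, row, col, absent


def mean_iou(cm) -> float:
    diag, row, col, absent = _terms(cm)
    return float(_per_class(diag, row + col - diag, absent).mean())


def average_precision(cm) -> float:
    diag, row, col, absent = _terms(cm)
    return float(_per_class(diag, col, absent).mean())


def average_recall(cm) -> float:
    diag, row, col, absent = _terms(cm)
    return float(_per_class(diag, row, absent).mean())


def evaluate_confusion(cm) -> dict:
    """All four metrics plus bookkeeping, as a plain dict."""
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm)
    return {
        "pixel_accuracy": pixel_accuracy(counts),
        "mean_iou": mean_iou(counts),
        "average_precision": average_precision(counts),
        "average_recall": average_recall(counts),
        "n_classes": int(counts.shape[0]),
        "total_pixels": int(counts.sum()),
    }
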