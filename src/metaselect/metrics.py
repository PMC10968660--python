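"""Imbalance-aware evaluation metrics: accuracy, weighted F1, AUC.

The weighted F1 averages per-class F1 scores with weights proportional to
each class's support in the true labels,

    F1_wg = sum_c F1_c * N_c / N,

which keeps the score honest under the roughly 40/60 class split of the
diagnosis task.  AUC is the midrank Mann-Whitney statistic
P(score_pos > score_neg) + 0.5 * P(tie) computed on positive-class scores.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data import InvalidInputError


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given labels (e.g. AUC
    with a single class present)."""


@dataclass
class EvalReport:
    """One evaluation row: a classifier scored on a held-out test set."""

    accuracy: float
    weighted_f1: float
    auc: float
    n_selected: int
    seconds: float

    def __post_init__(self):
        for name in ("accuracy", "weighted_f1", "auc"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise InvalidInputError(f"{name}={v} outside [0, 1]")


def _check_pair(y_true, other):
    y_true = np.asarray(y_true, dtype=object)
    other = np.asarray(other)
    if len(y_true) == 0:
        raise InvalidInputError("empty input")
    if len(y_true) != len(other):
        raise InvalidInputError("length mismatch between y_true and predictions")
    return y_true, other


def accuracy(y_true, y_pred) -> float:
    """Fraction of correct predictions."""
    y_true, y_pred = _check_pair(y_true, np.asarray(y_pred, dtype=object))
    return float(np.mean(y_true == y_pred))


def class_f1(y_true, y_pred, cls) -> float:
    """One-vs-rest F1 for one class; 0 when precision + recall = 0."""
    tp = np.sum((y_true == cls) & (y_pred == cls))
    fp = np.sum((y_true != cls) & (y_pred == cls))
    fn = np.sum((y_true == cls) & (y_pred != cls))
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else 0.0


def weighted_f1(y_true, y_pred) -> float:
    """Support-weighted average of per-class F1 scores."""
    y_true, y_pred = _check_pair(y_true, np.asarray(y_pred, dtype=object))
    classes = list(dict.fromkeys(y_true))
    n = len(y_true)
    total = 0.0
    for cls in classes:
        support = int(np.sum(y_true == cls))
        total += class_f1(y_true, y_pred, cls) * support / n
    return float(total)


def auc(y_true, scores, positive=None) -> float:
    """Midrank Mann-Whitney AUC of positive-class scores.

    ``positive`` defaults to the first label in order of appearance in
    ``y_true`` (the declaration-order convention used throughout).
    """
    y_true, scores = _check_pair(y_true, np.asarray(scores, dtype=float))
    if positive is None:
        # first declared class: order of appearance in y_true
        positive = next(iter(dict.fromkeys(y_true)))
    pos = y_true == positive
    n_pos = int(pos.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes present in y_true")
    ranks = rankdata(scores)  # midranks for ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


class Stopwatch:
    """Wall-clock timer for the selection phase of an experiment."""

    def __enter__(self):
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.seconds = time.perf_counter() - self._t0
        return False
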