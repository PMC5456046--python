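"""Confusion-matrix construction and evaluation metrics for imbalanced binary
classification.

The central quantity is the Matthews correlation coefficient (MCC), the
Pearson correlation between the binary truth and the binary prediction:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

In population terms, with prevalence ``pi = P(Y=1)`` and predicted-positive
rate ``gamma = P(theta=1)``, the same coefficient reduces to

    MCC = (TP - gamma*pi) / sqrt(gamma*(1-gamma)*pi*(1-pi))

where ``TP = P(Y=1, theta=1)``.  The MCC is undefined whenever one of the
four marginal sums (TP+FN, TP+FP, TN+FP, TN+FN) is zero; such results carry
``defined=False`` with a fallback value of 0 so that metric sweeps involving
constant predictors remain tabulable.

Two notions of accuracy coexist in the imbalanced-classification literature
and both are exposed under explicit names: :func:`accuracy_plain` is the
proportion of correct predictions, :func:`accuracy_balanced` is
``(TPR + TNR)/2``.  Neither is ever called plain "accuracy" here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricValue",
    "PopulationRates",
    "confusion_from_labels",
    "mcc",
    "mcc_reduced",
    "pearson_binary",
    "accuracy_plain",
    "accuracy_balanced",
    "precision",
    "recall",
    "f1",
    "auc_rank",
    "metric_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """The four cells of a 2x2 confusion matrix, as exact integers.

    The minority (positive) class is coded 1: ``tp`` counts true 1s
    predicted 1, ``fp`` true 0s predicted 1, ``tn`` true 0s predicted 0,
    ``fn`` true 1s predicted 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"confusion cell {name!r} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_rates(self) -> "PopulationRates":
        """Normalize the cells to empirical (TP, gamma, pi) probabilities."""
        n = self.total
        return PopulationRates(
            tp=self.tp / n,
            gamma=(self.tp + self.fp) / n,
            pi=(self.tp + self.fn) / n,
        )


@dataclass(frozen=True)
class MetricValue:
    """A metric result plus a flag recording whether it was defined.

    When ``defined`` is False, ``value`` holds the documented fallback
    (0 for MCC, so constant classifiers plot as a flat zero curve).
    """

    value: float
    defined: bool = True

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class PopulationRates:
    """Population-level rates: tp = P(Y=1, theta=1), gamma = P(theta=1), pi = P(Y=1)."""

    tp: float
    gamma: float
    pi: float

    def __post_init__(self) -> None:
        eps = 1e-9  # tolerate float roundoff from summing probabilities
        if not (-eps <= self.gamma <= 1.0 + eps and -eps <= self.pi <= 1.0 + eps):
            raise ValueError(f"gamma and pi must lie in [0, 1]; got gamma={self.gamma}, pi={self.pi}")
        object.__setattr__(self, "gamma", min(max(self.gamma, 0.0), 1.0))
        object.__setattr__(self, "pi", min(max(self.pi, 0.0), 1.0))
        if not (-eps <= self.tp <= min(self.gamma, self.pi) + eps):
            raise ValueError(
                f"tp must satisfy 0 <= tp <= min(gamma, pi); got tp={self.tp}, gamma={self.gamma}, pi={self.pi}"
            )
        object.__setattr__(self, "tp", min(max(self.tp, 0.0), min(self.gamma, self.pi)))


def _as_binary(vec, name: str) -> np.ndarray:
    arr = np.asarray(vec)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{name} has non-binary entry {arr[idx]!r} at index {idx}")
    return arr.astype(np.int64)


def confusion_from_labels(y_true, y_pred) -> ConfusionCounts:
    """Tally the confusion matrix of 0/1 prediction vector against 0/1 truth."""
    yt = _as_binary(y_true, "y_true")
    yp = _as_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: y_true has {yt.size} entries, y_pred has {yp.size}")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def mcc(counts: ConfusionCounts) -> MetricValue:
    """Matthews correlation coefficient from confusion counts.

    Undefined (flagged, fallback 0) when any of the four marginal sums
    TP+FN, TP+FP, TN+FP, TN+FN is zero — e.g. for a constant predictor
    or a single-class truth vector.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom2 = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return MetricValue(0.0, defined=False)
    value = (tp * tn - fp * fn) / math.sqrt(denom2)
    return MetricValue(float(value), defined=True)


def mcc_reduced(rates: PopulationRates) -> MetricValue:
    """MCC in its reduced population form (TP - gamma*pi)/sqrt(gamma(1-gamma)pi(1-pi)).

    Algebraically identical to :func:`mcc` on normalized counts; undefined
    when gamma or pi is degenerate (0 or 1).
    """
    g, p = rates.gamma, rates.pi
    if g <= 0.0 or g >= 1.0 or p <= 0.0 or p >= 1.0:
        return MetricValue(0.0, defined=False)
    value = (rates.tp - g * p) / math.sqrt(g * (1.0 - g) * p * (1.0 - p))
    return MetricValue(float(value), defined=True)


def pearson_binary(x, y) -> float:
    """Sample Pearson correlation of two binary vectors.

    For 0/1 vectors this coincides exactly with the MCC of the implied
    confusion matrix.  Raises if either vector is constant (the correlation
    is then undefined).
    """
    xa = _as_binary(x, "x").astype(float)
    ya = _as_binary(y, "y").astype(float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(xa, ya)[0, 1])


def accuracy_plain(counts: ConfusionCounts) -> MetricValue:
    """Proportion of correct predictions, (TP+TN)/n.

    This is the quantity that rewards majority-class guessing under
    imbalance (0.90 for the constant-negative predictor at 10% positives).
    """
    return MetricValue((counts.tp + counts.tn) / counts.total, defined=True)


def accuracy_balanced(counts: ConfusionCounts) -> MetricValue:
    """Balanced accuracy (TPR + TNR)/2; undefined if either class is absent."""
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    if pos == 0 or neg == 0:
        return MetricValue(0.0, defined=False)
    tpr = counts.tp / pos
    tnr = counts.tn / neg
    return MetricValue((tpr + tnr) / 2.0, defined=True)


def recall(counts: ConfusionCounts) -> MetricValue:
    """TP/(TP+FN); undefined when there are no true positives in the data."""
    denom = counts.tp + counts.fn
    if denom == 0:
        return MetricValue(0.0, defined=False)
    return MetricValue(counts.tp / denom, defined=True)


def precision(counts: ConfusionCounts) -> MetricValue:
    """TP/(TP+FP); undefined when nothing is predicted positive."""
    denom = counts.tp + counts.fp
    if denom == 0:
        return MetricValue(0.0, defined=False)
    return MetricValue(counts.tp / denom, defined=True)


def f1(counts: ConfusionCounts) -> MetricValue:
    """Harmonic mean of precision and recall, 2/(1/recall + 1/precision).

    Undefined whenever precision or recall is undefined or zero.
    """
    p = precision(counts)
    r = recall(counts)
    if not (p.defined and r.defined) or p.value == 0.0 or r.value == 0.0:
        return MetricValue(0.0, defined=False)
    return MetricValue(2.0 / (1.0 / r.value + 1.0 / p.value), defined=True)


def auc_rank(y_true, scores) -> float:
    """Area under the ROC curve as the Mann-Whitney rank statistic.

    Equals P(score_pos > score_neg) + 0.5 * P(tie) over random
    positive/negative pairs.  Requires both classes present.
    """
    yt = _as_binary(y_true, "y_true")
    sc = np.asarray(scores, dtype=float)
    if yt.shape != sc.shape:
        raise ValueError("y_true and scores must have equal length")
    if yt.min() == yt.max():
        raise ValueError("AUC undefined: y_true contains a single class")
    return float(roc_auc_score(yt, sc))


def metric_table(counts: ConfusionCounts, y_true=None, scores=None) -> pd.DataFrame:
    """Tidy table of all evaluation metrics for one classifier run.

    Columns ``metric, value, defined``.  The AUC row is included only when
    ``y_true`` and ``scores`` are supplied (it needs scores, not counts) and
    is marked undefined for single-class truth.
    """
    rows = [
        ("mcc", mcc(counts)),
        ("f1", f1(counts)),
        ("accuracy_plain", accuracy_plain(counts)),
        ("accuracy_balanced", accuracy_balanced(counts)),
        ("precision", precision(counts)),
        ("recall", recall(counts)),
    ]
    if y_true is not None and scores is not None:
        try:
            rows.append(("auc", MetricValue(auc_rank(y_true, scores))))
        except ValueError:
            rows.append(("auc", MetricValue(0.5, defined=False)))
    return pd.DataFrame(
        {
            "metric": [name for name, _ in rows],
            "value": [mv.value for _, mv in rows],
            "defined": [mv.defined for _, mv in rows],
        }
    )
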