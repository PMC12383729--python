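"""Classifier evaluation: confusion metrics, ROC/AUC, the paired DeLong test
and stratified k-fold assignment.

AUC uses the Mann-Whitney convention (ties count one half), so the
trapezoidal area under the tie-grouped ROC step curve equals the pairwise
statistic exactly.  The DeLong test compares two correlated AUCs computed on
the same observations through the covariance of their placement values.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    InvalidInputError,
    PairingError,
    StratificationError,
    UndefinedMetricError,
)

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "RocResult",
    "DeLongResult",
    "confusion_metrics",
    "confusion_from_scores",
    "auc_mann_whitney",
    "roc_curve",
    "delong_test",
    "stratified_kfold",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _percent(x: float) -> float:
    # half-up, matching how printed percentages are conventionally rounded
    return float(Decimal(x * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float

    def as_percent(self) -> "Metrics":
        """The same metrics as percentages rounded half-up to 2 decimals."""
        return Metrics(
            _percent(self.accuracy), _percent(self.sensitivity), _percent(self.specificity)
        )


def confusion_metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, sensitivity and specificity as proportions in [0, 1]."""
    if cm.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positives")
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negatives")
    return Metrics(
        accuracy=(cm.tp + cm.tn) / cm.total,
        sensitivity=cm.tp / (cm.tp + cm.fn),
        specificity=cm.tn / (cm.tn + cm.fp),
    )


def confusion_from_scores(scores, labels, threshold: float = 0.5) -> ConfusionMatrix:
    """Confusion matrix from probabilistic scores at a decision threshold
    (score >= threshold predicts positive)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pred = s >= threshold
    pos = y == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _split_classes(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y != 1]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedMetricError("AUC undefined: both classes must be present")
    return pos, neg


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney probability of concordance.

    (number of positive-negative pairs where the positive scores higher, with
    ties counting one half) / (n_pos * n_neg); computed via mid-ranks.
    """
    pos, neg = _split_classes(scores, labels)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float(
        (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0)
        / (pos.size * neg.size)
    )


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray  # descending unique score values
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores, labels) -> RocResult:
    """ROC step curve over unique thresholds (ties grouped), starting at
    (0,0) and ending at (1,1); the trapezoidal area equals the Mann-Whitney
    AUC."""
    pos, neg = _split_classes(scores, labels)
    s = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    distinct = np.nonzero(np.diff(s))[0]
    last = np.r_[distinct, s.size - 1]
    tp_cum = np.cumsum(y)[last]
    fp_cum = np.cumsum(1.0 - y)[last]
    tpr = np.r_[0.0, tp_cum / pos.size]
    fpr = np.r_[0.0, fp_cum / neg.size]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=s[last], fpr=fpr, tpr=tpr, auc=auc)


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    delta: float
    variance: float
    z: float
    p_value: float


def _placements(scores, labels):
    """Per-positive and per-negative placement values (structural components).

    V10[i] = mean_j psi(pos_i, neg_j); V01[j] = mean_i psi(pos_i, neg_j)
    with psi = 1, 1/2, 0 for win/tie/loss.  Computed via mid-ranks.
    """
    pos, neg = _split_classes(scores, labels)
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Paired DeLong comparison of two AUCs measured on the same observations.

    Builds the placement values of each score vector, their 2x2 empirical
    covariances over positives and negatives, the variance of the AUC
    difference, and the two-sided normal p-value.  Identical score vectors
    return delta 0 with p = 1 by convention; zero variance with a nonzero
    delta is an error.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels)
    if a.shape != b.shape or a.shape != y.shape:
        raise PairingError("scores_a, scores_b and labels must be equal-length")
    v10_a, v01_a = _placements(a, y)
    v10_b, v01_b = _placements(b, y)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    delta = auc_a - auc_b
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    var = float(max(var, 0.0))
    if var == 0.0:
        if delta != 0.0:
            raise DegenerateVarianceError(
                "zero DeLong variance with a nonzero AUC difference"
            )
        return DeLongResult(auc_a, auc_b, 0.0, 0.0, 0.0, 1.0)
    z = delta / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, delta, var, float(z), p)


def stratified_kfold(labels, k: int, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Shuffles each class independently (seeded) and deals its members
    round-robin over the k folds, so per-fold class counts are within one of
    perfectly stratified counts.  Returns one fold index in [0, k) per
    observation.
    """
    y = np.asarray(labels)
    if k < 2:
        raise StratificationError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise StratificationError(
                f"class {cls!r} has {idx.size} members, fewer than k={k}"
            )
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds
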