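"""Confusion-matrix statistics, MCC, ROC/AUC and seeded cross-validation.

MCC follows the standard confusion-matrix correlation

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the documented convention that a zero factor in the denominator gives
MCC = 0. AUC is the area under the ROC curve, equivalently the normalized
Mann-Whitney U statistic (ties handled by ranks); the computation is
delegated to scikit-learn.

Cross-validation uses stratified folds; the fold-pooled confusion matrix
yields the MCC (robust to folds with empty cells) and pooled scores yield
the AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "confusion_from_predictions",
    "mcc",
    "roc_auc",
    "CVResult",
    "cross_validate",
]


@dataclass
class ConfusionCounts:
    """2x2 confusion table; positive = case."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/label length mismatch")
    return ConfusionCounts(
        tp=int(((y_pred == 1) & (y_true == 1)).sum()),
        tn=int(((y_pred == 0) & (y_true == 0)).sum()),
        fp=int(((y_pred == 1) & (y_true == 0)).sum()),
        fn=int(((y_pred == 0) & (y_true == 1)).sum()),
    )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 on zero denominator."""
    tp, tn, fp, fn = (
        float(counts.tp),
        float(counts.tn),
        float(counts.fp),
        float(counts.fn),
    )
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve of *scores* against binary *labels*."""
    labels = np.asarray(labels, dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


@dataclass
class CVResult:
    mcc: float
    auc: float
    folds: list[dict] = field(default_factory=list)


def cross_validate(
    X,
    y,
    estimator_factory: Callable[[int], object],
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation with pooled MCC/AUC.

    *estimator_factory* takes a fold-specific seed and returns a fresh
    estimator exposing ``fit(X, y)``, ``predict(X)`` and
    ``predict_scores(X)`` (positive-class score). Any per-feature
    standardization is the estimator's own responsibility and must be
    fitted on the training fold only.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < k:
        raise ValueError(
            f"every class needs at least k={k} samples, got {class_counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = ConfusionCounts(0, 0, 0, 0)
    all_scores = np.empty(len(y), dtype=np.float64)
    folds = []
    for f, (train, test) in enumerate(skf.split(X, y)):
        est = estimator_factory((seed * 10007 + f) % (2**31))
        est.fit(X[train], y[train])
        pred = np.asarray(est.predict(X[test]), dtype=np.int64)
        scores = np.asarray(est.predict_scores(X[test]), dtype=np.float64)
        all_scores[test] = scores
        cm = confusion_from_predictions(y[test], pred)
        pooled = pooled + cm
        folds.append(
            {
                "fold": f,
                "n_test": int(len(test)),
                "tp": cm.tp,
                "tn": cm.tn,
                "fp": cm.fp,
                "fn": cm.fn,
                "mcc": mcc(cm),
            }
        )
    return CVResult(mcc=mcc(pooled), auc=roc_auc(all_scores, y), folds=folds)
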