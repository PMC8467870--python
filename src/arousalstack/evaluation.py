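"""Confusion-matrix metrics, ROC/AUROC, and the cross-validation harness.

Metrics follow the standard binary definitions

    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)
    precision   = TP / (TP + FP)

with an undefined ratio (zero denominator) reported as NaN with a warning.
AUROC is the area under the TP-rate vs FP-rate curve (trapezoidal over all
score thresholds, scikit-learn backend), equal to the Mann-Whitney
concordance probability; the test suite checks that identity against a
brute-force pairwise count.

Cross-validation folds are assigned at the *record* level so that segments
from one subject never appear on both sides of a split (within-subject
leakage would inflate every metric).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "metrics",
    "auroc",
    "roc_points",
    "record_folds",
    "train_test_record_split",
    "crossval",
]


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    """Metrics of one evaluation; rates in [0, 1] (``as_percent`` for %)."""

    cm: ConfusionMatrix
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    auroc: float = np.nan
    folds: list["EvalReport"] = field(default_factory=list)

    def as_percent(self) -> dict[str, float]:
        """Rates as percentages rounded to 2 decimals, table-style."""
        return {
            k: round(100.0 * getattr(self, k), 2)
            for k in ("accuracy", "sensitivity", "specificity", "precision", "auroc")
        }

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.cm.tp, "tn": self.cm.tn,
                          "fp": self.cm.fp, "fn": self.cm.fn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "auroc": self.auroc,
            "folds": [f.to_dict() for f in self.folds],
        }


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionMatrix:
    """Exact TP/TN/FP/FN counts for Boolean labels and predictions."""
    y = np.asarray(labels).astype(bool)
    p = np.asarray(predictions).astype(bool)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    if y.size == 0:
        raise ValueError("empty input")
    return ConfusionMatrix(
        tp=int(np.sum(y & p)),
        tn=int(np.sum(~y & ~p)),
        fp=int(np.sum(~y & p)),
        fn=int(np.sum(y & ~p)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """Accuracy, sensitivity, specificity, precision from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return EvalReport(
        cm=cm,
        accuracy=_ratio(cm.tp + cm.tn, cm.total, "accuracy"),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        specificity=_ratio(cm.tn, cm.fp + cm.tn, "specificity"),
        precision=_ratio(cm.tp, cm.tp + cm.fp, "precision"),
    )


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve; requires both classes present."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


def roc_points(labels: np.ndarray, scores: np.ndarray):
    """(fpr, tpr, thresholds) of the ROC curve."""
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int), scores)
    return fpr, tpr, thr


def evaluate(labels: np.ndarray, predictions: np.ndarray,
             scores: np.ndarray | None = None) -> EvalReport:
    """Full report from hard predictions and (optionally) scores for AUROC."""
    report = metrics(confusion(labels, predictions))
    if scores is not None:
        report.auroc = auroc(labels, scores)
    return report


def record_folds(record_ids: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Assign each segment a fold index by its source record.

    Records are shuffled deterministically and dealt round-robin so fold
    sizes differ by at most one record; every segment of a record lands in
    the same fold.
    """
    record_ids = np.asarray(record_ids)
    unique = np.unique(record_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(unique) < k:
        raise ValueError(f"need at least {k} records for {k} folds, have {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    fold_of = {unique[j]: i % k for i, j in enumerate(order)}
    return np.array([fold_of[r] for r in record_ids])


def train_test_record_split(record_ids: np.ndarray, test_fraction: float = 0.2,
                            seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (train_mask, test_mask) holding out a fraction of records."""
    record_ids = np.asarray(record_ids)
    unique = np.unique(record_ids)
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_fraction * len(unique))))
    test_records = set(rng.permutation(unique)[:n_test].tolist())
    test_mask = np.array([r in test_records for r in record_ids])
    return ~test_mask, test_mask


def crossval(
    fit_predict,
    labels: np.ndarray,
    record_ids: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Record-disjoint k-fold cross-validation of an arbitrary pipeline.

    ``fit_predict(train_idx, test_idx) -> (predictions, scores)`` trains on
    the train indices and returns hard predictions and continuous scores for
    the test indices.  The summary report averages the per-fold metrics
    (unweighted) and keeps the per-fold breakdown.
    """
    labels = np.asarray(labels).astype(int)
    folds = record_folds(record_ids, k, seed)
    fold_reports = []
    for f in range(k):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        pred, scores = fit_predict(train_idx, test_idx)
        fold_reports.append(evaluate(labels[test_idx], pred, scores))
    mean = lambda attr: float(np.nanmean([getattr(r, attr) for r in fold_reports]))
    cm_total = ConfusionMatrix(
        tp=sum(r.cm.tp for r in fold_reports),
        tn=sum(r.cm.tn for r in fold_reports),
        fp=sum(r.cm.fp for r in fold_reports),
        fn=sum(r.cm.fn for r in fold_reports),
    )
    return EvalReport(
        cm=cm_total,
        accuracy=mean("accuracy"),
        sensitivity=mean("sensitivity"),
        specificity=mean("specificity"),
        precision=mean("precision"),
        auroc=mean("auroc"),
        folds=fold_reports,
    )
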