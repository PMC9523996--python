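"""Stratified k-fold evaluation and the confusion-derived metric suite.

Metrics follow the standard confusion-matrix definitions:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

For multiclass problems precision and recall are macro-averaged over
one-vs-rest per-class values and F1 is the harmonic mean of the two
macro values. The reported fold variance is the population variance of
per-fold held-out accuracies on the fractional scale, and the
overfitting gap is train minus test accuracy in percentage points.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_score, recall_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data_model import FeatureTable
from .errors import DataError, ModelError, StratificationError

__all__ = [
    "FoldPlan",
    "MetricSet",
    "stratified_kfold",
    "confusion_metrics",
    "f1_from_precision_recall",
    "overfit_diff",
    "fold_variance",
    "roc_auc",
    "cross_validate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldPlan:
    """A stratified partition of samples into k folds.

    Fold sizes differ by at most one and per-fold class counts match the
    global class proportions to within one sample per class.
    """

    k: int
    assignments: np.ndarray  # fold index per sample
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments",
                           np.asarray(self.assignments, dtype=int))


@dataclass(frozen=True)
class MetricSet:
    """Cross-validated performance of one classifier on one feature set.

    Accuracies are percentages; precision/recall/F1/AUC are fractions;
    ``variance`` is the population variance of the per-fold held-out
    accuracies on the 0–1 scale. ``auc`` is NaN when undefined (a fold
    with a single observed class).
    """

    train_accuracy: float
    test_accuracy: float
    overfit_diff: float
    precision: float
    recall: float
    f1: float
    auc: float
    variance: float
    n_features: int
    classification_time: float

    def as_dict(self, include_timings: bool = True) -> dict[str, float]:
        out = {
            "train_accuracy_pct": self.train_accuracy,
            "test_accuracy_pct": self.test_accuracy,
            "overfit_diff_pct": self.overfit_diff,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "variance": self.variance,
            "n_features": self.n_features,
        }
        if include_timings:
            out["classification_time_s"] = self.classification_time
        return out


def stratified_kfold(labels: Sequence[str], k: int, seed: int) -> FoldPlan:
    """Assign samples to k shuffled, stratified folds."""
    labels = np.asarray([str(l) for l in labels])
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < k]
    if too_small.size:
        raise StratificationError(
            f"class(es) {list(too_small)} have fewer than k={k} members"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def confusion_metrics(y_true: Sequence, y_pred: Sequence):
    """(precision, recall, f1, accuracy) from predictions.

    Binary inputs use the plain TP/FP/FN/TN definitions; multiclass
    inputs macro-average one-vs-rest precision and recall and take F1 as
    their harmonic mean. A class never predicted (or never present)
    contributes 0 to the corresponding macro average, with a warning.
    """
    y_true = np.asarray([str(v) for v in y_true])
    y_pred = np.asarray([str(v) for v in y_pred])
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise DataError(
            f"label vectors must be equal-length and non-empty "
            f"(got {y_true.size} and {y_pred.size})"
        )
    classes = np.unique(np.concatenate([y_true, y_pred]))
    if len(classes) == 2:
        # positive class = the second in sorted order, matching the
        # one-vs-rest convention; the macro path generalizes this.
        pos = classes[1]
        tp = np.sum((y_true == pos) & (y_pred == pos))
        fp = np.sum((y_true != pos) & (y_pred == pos))
        fn = np.sum((y_true == pos) & (y_pred != pos))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        if (tp + fp == 0) or (tp + fn == 0):
            logger.warning("zero-denominator precision/recall set to 0")
    else:
        precision = precision_score(y_true, y_pred, average="macro", zero_division=0)
        recall = recall_score(y_true, y_pred, average="macro", zero_division=0)
    f1 = f1_from_precision_recall(precision, recall)
    accuracy = float(np.mean(y_true == y_pred))
    return float(precision), float(recall), float(f1), accuracy


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    denom = precision + recall
    return 2.0 * precision * recall / denom if denom else 0.0


def overfit_diff(train_acc_pct: float, test_acc_pct: float) -> float:
    """Training minus test accuracy, in percentage points (may be negative)."""
    return train_acc_pct - test_acc_pct


def fold_variance(fold_accuracies: Sequence[float]) -> float:
    """Population variance (divide by k) of per-fold accuracies."""
    accs = np.asarray(fold_accuracies, dtype=float)
    if accs.size == 0:
        raise DataError("fold_variance needs at least one fold score")
    if np.ptp(accs) == 0.0:  # exact zero for identical folds, no float dust
        return 0.0
    return float(np.var(accs))


def roc_auc(y_true: Sequence, scores: np.ndarray) -> float:
    """Area under the ROC curve; macro one-vs-rest for multiclass.

    ``scores`` is (n_samples,) or (n_samples, 1) for binary problems —
    higher means more likely the larger class label — or
    (n_samples, n_classes) column-per-class. Returns NaN when y_true
    holds a single class.
    """
    y_true = np.asarray([str(v) for v in y_true])
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(y_true)
    if classes.size < 2:
        logger.warning("roc_auc undefined for single-class labels; returning NaN")
        return float("nan")
    if scores.ndim == 2 and scores.shape[1] == 1:
        scores = scores[:, 0]
    if classes.size == 2:
        if scores.ndim == 2:
            scores = scores[:, 1]
        return float(roc_auc_score(y_true == classes[1], scores))
    if scores.ndim != 2 or scores.shape[1] != classes.size:
        raise DataError(
            f"multiclass roc_auc needs a (n, {classes.size}) score matrix, "
            f"got shape {scores.shape}"
        )
    per_class = [
        roc_auc_score(y_true == c, scores[:, j]) for j, c in enumerate(sorted(classes))
    ]
    return float(np.mean(per_class))


def _scores_for_auc(model, X: np.ndarray, classes_in_fold: int) -> np.ndarray:
    """Probability estimates when available, else min-max scaled decisions."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)
    raw = np.asarray(model.decision_function(X), dtype=float)
    lo, hi = raw.min(), raw.max()
    scaled = (raw - lo) / (hi - lo) if hi > lo else np.full_like(raw, 0.5)
    if scaled.ndim == 1 and classes_in_fold > 2:
        raise ModelError("decision_function gave 1-D scores for a multiclass fold")
    return scaled


def cross_validate(table: FeatureTable, classifier, plan: FoldPlan) -> MetricSet:
    """Evaluate a classifier over a fold plan; fields are fold means.

    ``classifier`` is a zero-argument factory returning a fresh
    scikit-learn style estimator (fit/predict, and predict_proba or
    decision_function for AUC). Train accuracy is measured on each
    fold's training portion; variance is the population variance of the
    per-fold test accuracies.
    """
    if plan.assignments.shape[0] != table.n_samples:
        raise DataError("fold plan does not cover the table's rows")
    y = np.asarray(table.labels)
    train_accs, test_accs, precs, recs, f1s, aucs = [], [], [], [], [], []
    t0 = time.perf_counter()
    for fold in range(plan.k):
        test = plan.assignments == fold
        model = classifier()
        try:
            model.fit(table.values[~test], y[~test])
        except Exception as exc:
            raise ModelError(f"classifier failed to fit on fold {fold}: {exc}") from exc
        train_accs.append(float(np.mean(model.predict(table.values[~test]) == y[~test])))
        pred = model.predict(table.values[test])
        p, r, f1, acc = confusion_metrics(y[test], pred)
        test_accs.append(acc)
        precs.append(p)
        recs.append(r)
        f1s.append(f1)
        n_classes_model = len(getattr(model, "classes_", np.unique(y[~test])))
        scores = _scores_for_auc(model, table.values[test], n_classes_model)
        auc = roc_auc(y[test], scores)
        if not np.isnan(auc):
            aucs.append(auc)
    elapsed = time.perf_counter() - t0
    train_pct = 100.0 * float(np.mean(train_accs))
    test_pct = 100.0 * float(np.mean(test_accs))
    return MetricSet(
        train_accuracy=train_pct,
        test_accuracy=test_pct,
        overfit_diff=overfit_diff(train_pct, test_pct),
        precision=float(np.mean(precs)),
        recall=float(np.mean(recs)),
        f1=float(np.mean(f1s)),
        auc=float(np.mean(aucs)) if aucs else float("nan"),
        variance=fold_variance(test_accs),
        n_features=table.n_features,
        classification_time=elapsed,
    )
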