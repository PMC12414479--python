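"""Evaluation metrics for both classification tasks.

Seven metrics are reported throughout: accuracy, precision, recall, F1,
Matthews correlation coefficient (threshold metrics), and the areas under
the ROC and precision-recall curves (ranking metrics).

Conventions: scores at or above the threshold predict the positive class
(note the voters break exact-threshold ties toward class 0 instead; both
conventions are deliberate and documented). Precision, recall and F1 are
0 when their denominator is 0; MCC is 0 when any confusion-matrix
marginal is 0. The PR area uses the step-wise average-precision
estimator, which avoids the optimism of trapezoidal interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "mcc", "auroc", "aupr")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(labels, predictions) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
    )


def _validate(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if labels.size < 1:
        raise ValueError("need at least one sample")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return labels, scores


def classification_metrics(labels, scores, threshold: float = 0.5) -> dict[str, float]:
    """Threshold metrics from scores: accuracy, precision, recall, F1, MCC.

    Scores >= threshold predict class 1.
    """
    labels, scores = _validate(labels, scores)
    preds = (scores >= threshold).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-marginal MCC warns before returning 0
        return {
            "accuracy": float(accuracy_score(labels, preds)),
            "precision": float(precision_score(labels, preds, zero_division=0)),
            "recall": float(recall_score(labels, preds, zero_division=0)),
            "f1": float(f1_score(labels, preds, zero_division=0)),
            "mcc": float(matthews_corrcoef(labels, preds)),
        }


def auroc(labels, scores) -> float:
    """Area under the ROC curve: the probability that a random positive
    outscores a random negative, ties counting one half (equivalently the
    trapezoidal ROC area). Requires both classes present."""
    labels, scores = _validate(labels, scores)
    if labels.min() == labels.max():
        raise ValueError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def aupr(labels, scores) -> float:
    """Area under the precision-recall curve via the step-wise
    average-precision estimator. Requires at least one positive."""
    labels, scores = _validate(labels, scores)
    if labels.sum() == 0:
        raise ValueError("AUPR undefined: no positive labels")
    return float(average_precision_score(labels, scores))


def full_report(labels, scores, threshold: float = 0.5) -> dict[str, float]:
    """All seven metrics in one dictionary."""
    report = classification_metrics(labels, scores, threshold=threshold)
    labels_arr = np.asarray(labels, dtype=int)
    report["auroc"] = (
        auroc(labels, scores) if labels_arr.min() != labels_arr.max() else float("nan")
    )
    report["aupr"] = aupr(labels, scores) if labels_arr.sum() > 0 else float("nan")
    return report


def roc_curve_points(labels, scores) -> np.ndarray:
    """(fpr, tpr, threshold) rows for plotting/export."""
    from sklearn.metrics import roc_curve

    labels, scores = _validate(labels, scores)
    fpr, tpr, thr = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr, thr])


def pr_curve_points(labels, scores) -> np.ndarray:
    """(recall, precision) rows for plotting/export."""
    from sklearn.metrics import precision_recall_curve

    labels, scores = _validate(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    return np.column_stack([recall, precision])
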