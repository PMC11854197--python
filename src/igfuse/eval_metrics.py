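"""Confusion-matrix metrics, AUC variants and the confidence score.

Two AUC conventions are reported side by side: ``trapezoid`` is the
standard rank statistic (area under the empirical ROC curve, ties
averaged) and ``eq_single_point`` evaluates (1 + TPR - FPR)/2 at the
0.5 decision threshold, a single-operating-point summary sometimes
reported in place of the ROC integral.

The confidence score turns the mean base-2 Bernoulli entropy of the
predicted probabilities into a 0-1 score:

    score = 1 - (1/N) * sum_i H2(p_i)

so 0 means every prediction sits at p = 0.5 (maximal uncertainty) and
1 means every prediction is fully confident.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import DataError, MetricError
from .model import bernoulli_entropy_bits


@dataclass(frozen=True)
class EvalReport:
    """Scalar evaluation summary for one labeled corpus."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc_trapezoid: float
    auc_single_point: float
    entropy_score: float

    def to_dict(self, percent: bool = False) -> dict:
        d = asdict(self)
        if percent:
            for key in (
                "accuracy", "precision", "recall", "f1",
                "auc_trapezoid", "auc_single_point", "entropy_score",
            ):
                d[key + "_percent"] = 100.0 * d[key]
        return d


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if np.setdiff1d(labels, [0, 1]).size:
        raise DataError(f"labels must be in {{0,1}}, got {np.unique(labels)}")
    return labels.astype(int)


def confusion_counts(
    labels: np.ndarray, predicted: np.ndarray
) -> tuple[int, int, int, int]:
    labels = _check_binary(labels)
    predicted = _check_binary(predicted)
    if labels.shape != predicted.shape or labels.size == 0:
        raise DataError("labels and predictions must be equal-length, nonempty")
    tp = int(((labels == 1) & (predicted == 1)).sum())
    fp = int(((labels == 0) & (predicted == 1)).sum())
    fn = int(((labels == 1) & (predicted == 0)).sum())
    tn = int(((labels == 0) & (predicted == 0)).sum())
    return tp, fp, fn, tn


def confusion_metrics(
    labels: np.ndarray, predicted: np.ndarray
) -> tuple[float, float, float, float]:
    """Accuracy, precision, recall, F1 from hard predictions.

    Zero-denominator cases (e.g. no positive predictions) yield 0 for
    the affected metric with a warning, not an exception.
    """
    tp, fp, fn, tn = confusion_counts(labels, predicted)
    n = tp + fp + fn + tn
    acc = (tp + tn) / n
    if tp + fp == 0:
        warnings.warn("no positive predictions: precision set to 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no positive labels: recall set to 0", stacklevel=2)
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return acc, precision, recall, f1


def auc(
    scores: np.ndarray,
    labels: np.ndarray,
    method: str = "trapezoid",
    threshold: float = 0.5,
) -> float:
    """AUC of continuous scores against binary labels.

    ``trapezoid`` integrates the empirical ROC curve (rank statistic,
    ties averaged); ``single_point`` evaluates (1 + TPR - FPR)/2 with
    hard predictions at ``threshold``.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise MetricError("AUC undefined: only one class present")
    if method == "trapezoid":
        return float(roc_auc_score(labels, scores))
    if method in ("single_point", "eq33"):
        predicted = (scores > threshold).astype(int)
        tp, fp, fn, tn = confusion_counts(labels, predicted)
        tpr = tp / (tp + fn)
        specificity = tn / (tn + fp)
        fpr = 1.0 - specificity
        return float((1.0 + tpr - fpr) / 2.0)
    raise DataError(f"unknown AUC method {method!r}")


def entropy_score(probabilities: np.ndarray) -> float:
    """Normalized prediction-entropy confidence score in [0, 1]."""
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise DataError("entropy_score needs at least one probability")
    if p.min() < 0 or p.max() > 1:
        raise DataError("probabilities must lie in [0,1]")
    return float(1.0 - bernoulli_entropy_bits(p).mean())


def evaluate(
    labels: np.ndarray,
    probabilities: np.ndarray,
    threshold: float = 0.5,
) -> EvalReport:
    """Full evaluation of probabilistic predictions on a labeled set."""
    labels = _check_binary(labels)
    probabilities = np.asarray(probabilities, dtype=float)
    predicted = (probabilities > threshold).astype(int)
    tp, fp, fn, tn = confusion_counts(labels, predicted)
    acc, precision, recall, f1 = confusion_metrics(labels, predicted)
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=acc, precision=precision, recall=recall, f1=f1,
        auc_trapezoid=auc(probabilities, labels, "trapezoid"),
        auc_single_point=auc(probabilities, labels, "single_point", threshold),
        entropy_score=entropy_score(probabilities),
    )
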