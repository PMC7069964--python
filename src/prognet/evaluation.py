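"""ROC/AUC, Youden-index cut-off selection, reclassification and
confusion-matrix metrics.

The positive class is death throughout: scores are predicted death
probabilities and a patient is classified as death when the score is at
least the cut-off (default 0.5). Reclassification replaces 0.5 with the
threshold maximizing the Youden index J = sensitivity + specificity - 1,
computed on a held-out (validation) split and then frozen.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

__all__ = ["ROCResult", "CutoffDecision", "MetricsReport", "roc_and_auc",
           "youden_cutoff", "classify_at", "classification_metrics"]


@dataclass
class ROCResult:
    """Thresholds (descending, sentinel first) with TPR/FPR per threshold
    and the trapezoidal area under the curve (equal to the pairwise
    concordance probability with ties counted 1/2)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class CutoffDecision:
    cutoff: float
    youden_j: float


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    precision_undefined: bool = False

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "tp": self.tp,
                "fp": self.fp, "tn": self.tn, "fn": self.fn}


def roc_and_auc(scores, labels) -> ROCResult:
    """Full threshold sweep (no interpolation) and trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(thr, tpr, fpr, float(_trapezoid_auc(fpr, tpr)))


def youden_cutoff(roc: ROCResult) -> CutoffDecision:
    """Threshold maximizing J = TPR - FPR; ties resolved toward the
    smaller cut-off (the more sensitive operating point)."""
    j = roc.tpr - roc.fpr
    best = j >= j.max() - 1e-12
    cut = float(np.min(roc.thresholds[best]))
    return CutoffDecision(min(max(cut, 0.0), 1.0), float(j.max()))


def classify_at(scores, cutoff: float = 0.5) -> np.ndarray:
    """Predict death (1) iff score >= cutoff."""
    return (np.asarray(scores, dtype=float) >= cutoff).astype(int)


def classification_metrics(pred, truth) -> MetricsReport:
    """Standard confusion-matrix metrics with death as positive class.

    Precision with no predicted positives is reported as 0 and flagged;
    F1 is 0 when precision + recall is 0.
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    tp = int(((pred == 1) & (truth == 1)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    n = tp + fp + tn + fn
    undefined = (tp + fp) == 0
    precision = 0.0 if undefined else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    f1 = (0.0 if precision + recall == 0.0
          else 2.0 * precision * recall / (precision + recall))
    return MetricsReport((tp + tn) / n, precision, recall, f1,
                         tp, fp, tn, fn, precision_undefined=undefined)
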