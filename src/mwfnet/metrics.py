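"""Classification metrics: confusion matrix, accuracy, per-class/macro F1.

Computed from first principles (the test suite cross-checks them against
scikit-learn on random predictions).  Macro-F1 is the unweighted mean of
per-class F1 scores; classes absent from both truth and prediction get
an F1 of 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["confusion_matrix", "per_class_f1", "EvaluationReport", "evaluate_predictions"]


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     labels: list | None = None) -> tuple[np.ndarray, list]:
    """Counts[i, j] = samples of true class i predicted as class j."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if labels is None:
        labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm, list(labels)


def per_class_f1(cm: np.ndarray) -> np.ndarray:
    """F1 per class from a confusion matrix (0 where undefined)."""
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
    return f1


@dataclass
class EvaluationReport:
    """Per-split classification summary."""

    accuracy: float
    per_class_f1: np.ndarray
    macro_f1: float
    confusion: np.ndarray
    labels: list = field(default_factory=list)
    per_fold: list | None = None

    def to_dict(self) -> dict:
        out = {
            "accuracy": float(self.accuracy),
            "macro_f1": float(self.macro_f1),
            "per_class_f1": [float(v) for v in self.per_class_f1],
            "confusion": self.confusion.tolist(),
            "labels": [str(l) for l in self.labels],
        }
        if self.per_fold is not None:
            out["per_fold"] = [r.to_dict() for r in self.per_fold]
        return out


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                         labels: list | None = None) -> EvaluationReport:
    """Build an :class:`EvaluationReport`; accuracy = trace / total."""
    if len(np.asarray(y_true)) == 0:
        raise ValueError("cannot evaluate an empty test set")
    cm, labs = confusion_matrix(y_true, y_pred, labels)
    f1 = per_class_f1(cm)
    return EvaluationReport(
        accuracy=float(np.trace(cm) / cm.sum()),
        per_class_f1=f1,
        macro_f1=float(f1.mean()),
        confusion=cm,
        labels=labs,
    )
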