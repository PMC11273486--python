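"""Evaluation: accuracy, normalized confusion matrices, repeat summaries.

Accuracy is the percentage of correct predictions. Confusion matrices are
row-normalized by true class, so each row of a class with test support sums
to one and the label-weighted mean of the diagonal equals accuracy/100.
Repeated-run summaries report mean, sample standard deviation (n-1
denominator) and best accuracy, the format used for repeated from-scratch
training runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nirs_io import CLASS_NAMES, WindowedSample, stack_windows

__all__ = [
    "EvaluationReport",
    "accuracy",
    "confusion_matrix",
    "summarize_runs",
    "evaluate_model",
]


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Percentage of predictions that match the labels."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if predictions.size == 0:
        raise ValueError("cannot compute accuracy of an empty prediction set")
    return 100.0 * float(np.mean(predictions == labels))


def confusion_matrix(
    predictions: np.ndarray,
    labels: np.ndarray,
    n_classes: int = len(CLASS_NAMES),
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized confusion matrix and a mask of rows with test support.

    Entry ``(i, j)`` is the fraction of true-class-``i`` samples predicted as
    class ``j``. Rows of classes with zero support are all-zero and flagged
    ``False`` in the returned mask.
    """
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if np.any((labels < 0) | (labels >= n_classes)):
        raise ValueError("label out of range")
    if np.any((predictions < 0) | (predictions >= n_classes)):
        raise ValueError("prediction out of range")
    counts = np.zeros((n_classes, n_classes))
    np.add.at(counts, (labels, predictions), 1.0)
    support = counts.sum(axis=1)
    has_support = support > 0
    if not normalize:
        return counts, has_support
    out = np.zeros_like(counts)
    out[has_support] = counts[has_support] / support[has_support, None]
    return out, has_support


def summarize_runs(accuracies: list[float]) -> dict[str, float]:
    """Mean / sample STD (n-1 denominator) / best over repeated runs."""
    if not accuracies:
        raise ValueError("need at least one run")
    a = np.asarray(accuracies, dtype=float)
    std = float(a.std(ddof=1)) if a.size > 1 else 0.0
    return {"mean": float(a.mean()), "std": std, "best": float(a.max())}


@dataclass
class EvaluationReport:
    """Per-split classification report."""

    accuracy: float
    per_class_accuracy: np.ndarray
    confusion: np.ndarray
    class_support: np.ndarray
    n_test: int
    class_names: tuple[str, ...] = CLASS_NAMES
    runs: dict[str, float] | None = field(default=None)

    def to_dict(self) -> dict:
        out = {
            "accuracy_percent": self.accuracy,
            "n_test": self.n_test,
            "class_names": list(self.class_names),
            "per_class_accuracy_percent": self.per_class_accuracy.tolist(),
            "confusion_row_normalized": self.confusion.tolist(),
            "class_support": self.class_support.tolist(),
        }
        if self.runs is not None:
            out["runs"] = self.runs
        return out


def evaluate_model(model, samples: list[WindowedSample]) -> EvaluationReport:
    """Predict a labelled window set and assemble the report."""
    X, y = stack_windows(samples)
    if np.any(y < 0):
        raise ValueError("evaluation windows must all be labelled")
    pred = model.predict(X)
    conf, has_support = confusion_matrix(pred, y)
    counts, _ = confusion_matrix(pred, y, normalize=False)
    return EvaluationReport(
        accuracy=accuracy(pred, y),
        per_class_accuracy=100.0 * np.where(has_support, np.diag(conf), np.nan),
        confusion=conf,
        class_support=counts.sum(axis=1).astype(int),
        n_test=len(samples),
    )
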