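"""Confusion-matrix evaluation: accuracy, per-class precision and recall.

Rows of the 3x3 matrix are true classes, columns are predictions, in the
fixed order (grunt, squeal, cough).  Accuracy is trace/total, precision
is column-wise TP/(TP+FP), recall is row-wise TP/(TP+FN), and the macro
average is the unweighted class mean.  Percentages are rounded to one
decimal, half away from zero, matching conventional report tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import CLASS_NAMES, ValidationError

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "accuracy",
    "precision_per_class",
    "recall_per_class",
    "macro_average",
    "round1",
    "report",
    "format_table",
]


def round1(x: float) -> float:
    """Round to 1 decimal, half away from zero."""
    if np.isnan(x):
        return float("nan")
    return float(np.floor(abs(x) * 10.0 + 0.5) / 10.0 * np.sign(x)) if x else 0.0


@dataclass
class ConfusionMatrix:
    """3x3 count table; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.class_names)
        if self.counts.shape != (n, n):
            raise ValidationError(f"confusion matrix must be {n}x{n}")
        if np.any(self.counts < 0):
            raise ValidationError("confusion counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValidationError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count table from parallel true/predicted label sequences."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValidationError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(CLASS_NAMES)}
    counts = np.zeros((3, 3), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValidationError(f"unknown label in ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent: 100 * trace / total, 1-decimal."""
    return round1(100.0 * np.trace(cm.counts) / cm.total)


def precision_per_class(cm: ConfusionMatrix) -> np.ndarray:
    """Column-wise precision percentages; NaN where a class was never predicted."""
    col = cm.counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 100.0 * np.diag(cm.counts) / col
    p = np.where(col == 0, np.nan, p)
    return np.array([round1(v) for v in p])


def recall_per_class(cm: ConfusionMatrix) -> np.ndarray:
    """Row-wise recall percentages; every true class must appear."""
    row = cm.counts.sum(axis=1)
    if np.any(row == 0):
        empty = [cm.class_names[i] for i in np.flatnonzero(row == 0)]
        raise ValidationError(f"no true samples for class(es): {empty}")
    r = 100.0 * np.diag(cm.counts) / row
    return np.array([round1(v) for v in r])


def macro_average(values: np.ndarray) -> float:
    """Unweighted mean of the three class percentages, 1-decimal.

    An undefined (NaN) class value propagates to an undefined average.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (3,):
        raise ValidationError("expected exactly 3 class values")
    if np.any(np.isnan(values)):
        return float("nan")
    return round1(float(values.mean()))


def report(cm: ConfusionMatrix, variant: str | None = None) -> dict:
    """Machine-readable metrics report for one confusion matrix."""
    p = precision_per_class(cm)
    r = recall_per_class(cm)
    return {
        "variant": variant,
        "classes": list(cm.class_names),
        "confusion": cm.counts.tolist(),
        "accuracy": accuracy(cm),
        "precision": [None if np.isnan(v) else v for v in p],
        "recall": [None if np.isnan(v) else v for v in r],
        "macro_precision": None if np.isnan(macro_average(p)) else macro_average(p),
        "macro_recall": None if np.isnan(macro_average(r)) else macro_average(r),
    }


def format_table(cm: ConfusionMatrix) -> str:
    """Human-readable table in the customary true-by-predicted layout."""
    p = precision_per_class(cm)
    r = recall_per_class(cm)
    names = [c.capitalize() for c in cm.class_names]
    lines = ["Type of Vocalization\t" + "\t".join(names) + "\tTotal\tRecall/%"]
    for i, name in enumerate(names):
        row = cm.counts[i]
        lines.append(f"{name}\t" + "\t".join(str(v) for v in row) + f"\t{row.sum()}\t{r[i]:.1f}")
    col = cm.counts.sum(axis=0)
    lines.append("Total\t" + "\t".join(str(v) for v in col))
    lines.append("Precision/%\t" + "\t".join("--" if np.isnan(v) else f"{v:.1f}" for v in p))
    lines.append(f"Accuracy/%\t{accuracy(cm):.1f}")
    return "\n".join(lines)
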