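"""Classification evaluation: confusion matrix and derived metrics.

Convention: confusion-matrix rows are the *actual* classes, columns the
*predicted* classes.  Per-class precision is the diagonal count over its
column sum, recall the diagonal over its row sum, F1 their harmonic mean;
macro-F1 (MF1) is the unweighted mean of per-class F1 and accuracy the
trace over the grand total.  Metrics are kept at full precision internally;
display rounds percentages to one decimal using round-half-even.  A class
with an empty row or column yields an *undefined* metric (NaN), never a
silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_matrix",
           "per_class_metrics", "accuracy", "macro_f1"]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                       # (n_classes, n_classes) ints
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"counts must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")
        n = self.counts.shape[0]
        if not self.class_names:
            self.class_names = [str(i) for i in range(n)]
        if len(self.class_names) != n:
            raise ValueError(f"{len(self.class_names)} class names for "
                             f"{n} classes")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(y_true, y_pred, n_classes: int,
                     class_names: list[str] | None = None) -> ConfusionMatrix:
    """Count matrix with rows = actual labels, columns = predictions."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError(f"label sequences must be equal-length 1-D arrays, "
                         f"got {y_true.shape} and {y_pred.shape}")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside "
                             f"[0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, class_names or [])


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1, macro-F1 and accuracy, as percentages.

    Arrays hold full-precision values; NaN marks an undefined metric
    (empty predicted column or actual row).  ``round1`` applies the
    display rounding (one decimal, round-half-even).
    """

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    accuracy: float
    confusion: ConfusionMatrix

    @staticmethod
    def round1(x: float) -> float:
        return float(np.round(x, 1))

    def to_dict(self) -> dict:
        def clean(v):
            return None if np.isnan(v) else float(v)
        return {
            "class_names": self.confusion.class_names,
            "precision": [clean(v) for v in self.precision],
            "recall": [clean(v) for v in self.recall],
            "f1": [clean(v) for v in self.f1],
            "macro_f1": clean(self.macro_f1),
            "accuracy": clean(self.accuracy),
            "confusion": self.confusion.counts.tolist(),
        }

    def format_table(self) -> str:
        """Aligned text table: counts with per-class PR/RE/F1 columns."""
        names = self.confusion.class_names
        width = max(7, max(len(n) for n in names) + 1)
        head = "".join(f"{n:>{width}}" for n in names)
        lines = [f"{'':>{width}}{head}{'PR':>{width}}{'RE':>{width}}"
                 f"{'F1':>{width}}"]
        for i, name in enumerate(names):
            row = "".join(f"{int(c):>{width}}" for c in self.confusion.counts[i])
            fmt = (lambda v: f"{'--':>{width}}" if np.isnan(v)
                   else f"{self.round1(v):>{width}.1f}")
            lines.append(f"{name:>{width}}{row}{fmt(self.precision[i])}"
                         f"{fmt(self.recall[i])}{fmt(self.f1[i])}")
        lines.append(f"accuracy {self.round1(self.accuracy):.1f}   "
                     f"MF1 {self.round1(self.macro_f1):.1f}")
        return "\n".join(lines)


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    counts = cm.counts.astype(np.float64)
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, np.nan) * 100.0
        recall = np.where(row > 0, diag / row, np.nan) * 100.0
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, np.nan)
        # both undefined, or defined-but-zero precision and recall
        f1 = np.where(np.isnan(precision) | np.isnan(recall), np.nan, f1)
        zero_both = (~np.isnan(precision)) & (~np.isnan(recall)) & (denom == 0)
        f1 = np.where(zero_both, 0.0, f1)
    acc = float(diag.sum() / counts.sum() * 100.0)
    mf1 = float(np.mean(f1))
    return MetricsReport(precision, recall, f1, mf1, acc, cm)


def accuracy(cm: ConfusionMatrix) -> float:
    """Trace over grand total, as a percent."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total * 100.0)


def macro_f1(report: MetricsReport) -> float:
    """Unweighted mean of the per-class F1 scores, as a percent."""
    return float(np.mean(report.f1))
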