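"""Confusion matrices and the four standard classification scores.

Conventions follow clinical usage: class 1 (sick) is the positive class.
Accuracy = (TP+TN)/total, recall = TP/(TP+FN), precision = TP/(TP+FP),
F-measure = harmonic mean of recall and precision.  Percentages are rendered
at two decimals with round-half-up; a metric whose denominator is zero is
reported as an explicit "undefined" marker, never silently as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics",
    "percent",
    "format_report_table",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN counts with class 1 ("Yes", diabetic) as positive."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(f"{name} must be a non-negative integer")
            object.__setattr__(self, name, int(value))

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def actual_positives(self) -> int:
        return self.tp + self.fn

    @property
    def actual_negatives(self) -> int:
        return self.fp + self.tn

    @property
    def predicted_positives(self) -> int:
        """How often the classifier said "yes"."""
        return self.tp + self.fp

    @property
    def predicted_negatives(self) -> int:
        return self.fn + self.tn


def confusion(predicted, actual) -> ConfusionMatrix:
    """Count TP/FN/FP/TN from parallel 0/1 prediction and truth vectors."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape or predicted.ndim != 1:
        raise ValueError("predicted and actual must be equal-length 1-D vectors")
    if predicted.size == 0:
        raise ValueError("cannot build a confusion matrix from no predictions")
    for name, vec in (("predicted", predicted), ("actual", actual)):
        if not np.isin(vec, (0, 1)).all():
            raise ValueError(f"{name} labels must be 0/1")
    return ConfusionMatrix(
        tp=int(((predicted == 1) & (actual == 1)).sum()),
        fn=int(((predicted == 0) & (actual == 1)).sum()),
        fp=int(((predicted == 1) & (actual == 0)).sum()),
        tn=int(((predicted == 0) & (actual == 0)).sum()),
    )


def percent(value: float) -> float:
    """Render a [0, 1] ratio as a percentage, two decimals, round-half-up."""
    return float(
        Decimal(repr(value * 100)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, recall, precision and F-measure; ``None`` marks undefined."""

    accuracy: float
    recall: float | None
    precision: float | None
    f_measure: float | None

    def as_percentages(self) -> dict[str, float | str]:
        out: dict[str, float | str] = {}
        for name in ("accuracy", "recall", "precision", "f_measure"):
            value = getattr(self, name)
            out[name] = "undefined" if value is None else percent(value)
        return out

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "f_measure": self.f_measure,
            "percent": self.as_percentages(),
        }


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The four scores from a confusion matrix, with explicit undefined markers."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    accuracy = (cm.tp + cm.tn) / cm.total
    recall = cm.tp / cm.actual_positives if cm.actual_positives else None
    prec = cm.tp / cm.predicted_positives if cm.predicted_positives else None
    if recall is None or prec is None or (recall + prec) == 0:
        f_measure = None
    else:
        f_measure = 2 * recall * prec / (recall + prec)
    return MetricsReport(accuracy, recall, prec, f_measure)


_ROW_NAMES = (
    ("accuracy", "Accuracy"),
    ("recall", "Recall"),
    ("precision", "Precision"),
    ("f_measure", "F-measure"),
)


def format_report_table(reports: dict[str, MetricsReport]) -> str:
    """Aligned plain-text table: per classifier, one row per performance measure."""
    lines = [f"{'':14s}{'Performance Measure':22s}{'Percentage':>10s}"]
    for label, report in reports.items():
        pct = report.as_percentages()
        for i, (key, pretty) in enumerate(_ROW_NAMES):
            head = label if i == 0 else ""
            value = pct[key]
            rendered = f"{value:.2f}%" if isinstance(value, float) else str(value)
            lines.append(f"{head:14s}{pretty:22s}{rendered:>10s}")
    return "\n".join(lines)


def write_report_json(
    path: str | Path, reports: dict[str, MetricsReport], matrices: dict[str, ConfusionMatrix]
) -> None:
    payload = {
        label: {
            "confusion": {
                "tp": matrices[label].tp,
                "fn": matrices[label].fn,
                "fp": matrices[label].fp,
                "tn": matrices[label].tn,
            },
            "metrics": reports[label].to_dict(),
        }
        for label in reports
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
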