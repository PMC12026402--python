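"""Confusion matrices and two-class performance statistics.

Conventions match standard cytometry-classifier reporting: percentages,
half-up rounding to 1 decimal place in tables (accuracy additionally at
2 dp in prose), per-class precision/recall/F1 plus support-weighted
averages, and row-/column-normalized confusion-matrix views (rows ⇒
recall, columns ⇒ precision).

Definitions (as percentages):

* accuracy  = 100·(TP+TN)/(TP+TN+FP+FN)
* precision = 100·TP/(TP+FP)
* recall    = 100·TP/(TP+FN)      (sensitivity / true-positive rate)
* F1        = harmonic mean of precision and recall

Undefined metrics (zero denominator) are reported as missing — never as
0, which would silently distort weighted averages.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "accuracy",
    "precision",
    "recall",
    "f1",
    "weighted_average",
    "report",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Half-up decimal rounding (the convention of printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Two-class confusion counts with a named positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = "cd41_pos"
    negative_class: str = "cd41_neg"

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def support_positive(self) -> int:
        return self.tp + self.fn

    @property
    def support_negative(self) -> int:
        return self.tn + self.fp

    def swapped(self) -> "ConfusionMatrix":
        """The same counts viewed with the other class as positive."""
        return ConfusionMatrix(
            tp=self.tn,
            fp=self.fn,
            tn=self.tp,
            fn=self.fp,
            positive_class=self.negative_class,
            negative_class=self.positive_class,
        )

    def as_array(self) -> np.ndarray:
        """Rows = true class (pos, neg); columns = predicted class."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], float)

    def row_normalized(self) -> np.ndarray:
        """Rows sum to 1 — the recall view."""
        a = self.as_array()
        sums = a.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(sums > 0, a / sums, np.nan)

    def column_normalized(self) -> np.ndarray:
        """Columns sum to 1 — the precision view."""
        a = self.as_array()
        sums = a.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(sums > 0, a / sums, np.nan)


def confusion_matrix(
    true_labels,
    predicted_labels,
    positive_class: str,
    negative_class: str | None = None,
) -> ConfusionMatrix:
    """Exact integer confusion counts from parallel label vectors."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    classes = set(true_labels) | set(predicted_labels)
    others = classes - {positive_class}
    if negative_class is None:
        if len(others) > 1:
            raise ValueError(f"labels not binary: {sorted(classes)}")
        negative_class = next(iter(others)) if others else "negative"
    unknown = classes - {positive_class, negative_class}
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    tp = fp = tn = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fp, tn, fn, positive_class, negative_class)


def accuracy(cm: ConfusionMatrix) -> float:
    """Percentage of correct classifications."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.total


def precision(cm: ConfusionMatrix) -> float:
    """100·TP/(TP+FP); NaN with a warning when no positive predictions."""
    if cm.tp + cm.fp == 0:
        warnings.warn("precision undefined: no predicted positives", stacklevel=2)
        return math.nan
    return 100.0 * cm.tp / (cm.tp + cm.fp)


def recall(cm: ConfusionMatrix) -> float:
    """100·TP/(TP+FN); NaN with a warning when the class has no support."""
    if cm.tp + cm.fn == 0:
        warnings.warn("recall undefined: no true positives in data", stacklevel=2)
        return math.nan
    return 100.0 * cm.tp / (cm.tp + cm.fn)


def f1(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall (both in percent)."""
    if math.isnan(precision_pct) or math.isnan(recall_pct):
        return math.nan
    if precision_pct + recall_pct == 0:
        warnings.warn("F1 undefined: precision and recall both 0", stacklevel=2)
        return 0.0
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def weighted_average(values, supports) -> float:
    """Support-weighted arithmetic mean (exact before any rounding)."""
    values = np.asarray(values, float)
    supports = np.asarray(supports, float)
    if supports.sum() <= 0:
        raise ValueError("total support must be positive")
    if (supports < 0).any():
        raise ValueError("supports must be non-negative")
    return float((values * supports).sum() / supports.sum())


@dataclass
class MetricsReport:
    """Per-class and support-weighted statistics for one data split."""

    per_class: dict[str, dict[str, float | int | None]]
    weighted: dict[str, float | None]
    accuracy_pct: float
    row_normalized: list[list[float]]
    column_normalized: list[list[float]]
    decimals: int = 1
    extra: dict = field(default_factory=dict)

    def rounded(self) -> dict:
        def r(v, nd=self.decimals):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return round_half_up(v, nd)

        return {
            "per_class": {
                c: {
                    "support": m["support"],
                    "precision_pct": r(m["precision_pct"]),
                    "recall_pct": r(m["recall_pct"]),
                    "f1_pct": r(m["f1_pct"]),
                }
                for c, m in self.per_class.items()
            },
            "weighted": {k: r(v) for k, v in self.weighted.items()},
            "accuracy_pct": r(self.accuracy_pct, 2),
            "row_normalized": self.row_normalized,
            "column_normalized": self.column_normalized,
            **self.extra,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.rounded(), indent=2, allow_nan=False)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def report(cm: ConfusionMatrix, decimals: int = 1) -> MetricsReport:
    """Full two-class report: per-class stats, weighted row, matrix views.

    The weighted metric is the exact support-weighted mean of *unrounded*
    per-class values; rounding happens only at presentation time.
    """
    per_class: dict[str, dict] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for view in (cm, cm.swapped()):
            p, r = precision(view), recall(view)
            per_class[view.positive_class] = {
                "support": view.support_positive,
                "precision_pct": p,
                "recall_pct": r,
                "f1_pct": f1(p, r),
            }
    supports = [m["support"] for m in per_class.values()]
    weighted: dict[str, float | None] = {}
    for key in ("precision_pct", "recall_pct", "f1_pct"):
        vals = [m[key] for m in per_class.values()]
        if any(math.isnan(v) for v in vals) or sum(supports) == 0:
            weighted[key] = None
        else:
            weighted[key] = weighted_average(vals, supports)

    def _clean(a: np.ndarray) -> list[list[float]]:
        return [[None if math.isnan(v) else v for v in row] for row in a.tolist()]

    return MetricsReport(
        per_class=per_class,
        weighted=weighted,
        accuracy_pct=accuracy(cm),
        row_normalized=_clean(cm.row_normalized()),
        column_normalized=_clean(cm.column_normalized()),
        decimals=decimals,
    )
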