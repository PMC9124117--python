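"""Confusion-matrix bookkeeping and the six reported performance measures.

The positive class is graft survival (label 1). Accuracy, precision, recall
and F-measure follow the universal confusion-count definitions; RMSE and MAE
are computed by default between the predicted survival probabilities and the
0/1 labels (hard-label errors available via a flag). Degenerate
zero-denominator cases return 0 with a logged warning.

Note on precision: the source literature for this model family occasionally
misprints precision as tp/(tn+fp); ``strict_paper=True`` reproduces that
variant for auditing comparisons, while the default is the standard
tp/(tp+fp).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "accuracy",
    "precision",
    "recall",
    "f_measure",
    "rmse",
    "mae",
    "compute_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_binary(y, name: str) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if not np.isin(y, (0, 1)).all():
        raise DataError(f"{name} must be binary 0/1")
    return y


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Count tp/tn/fp/fn with class 1 (survive) as the positive class."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise DataError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise DataError("cannot evaluate empty predictions")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); returning 0", what)
        return 0.0
    return num / den


def accuracy(c: ConfusionCounts) -> float:
    """(tp + tn) / (tp + fp + tn + fn)."""
    if c.total == 0:
        raise DataError("accuracy undefined for zero counts")
    return (c.tp + c.tn) / c.total


def precision(c: ConfusionCounts, strict_paper: bool = False) -> float:
    """tp / (tp + fp); ``strict_paper`` selects the misprinted tp/(tn+fp)."""
    if strict_paper:
        return _ratio(c.tp, c.tn + c.fp, "precision(strict_paper)")
    return _ratio(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    """tp / (tp + fn)."""
    return _ratio(c.tp, c.tp + c.fn, "recall")


def f_measure(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall: 2PR / (P + R)."""
    p = precision(c)
    r = recall(c)
    if p + r == 0:
        logger.warning("f_measure undefined (precision + recall = 0); returning 0")
        return 0.0
    return 2 * p * r / (p + r)


def rmse(y_true, scores) -> float:
    """Root mean squared error between scores and 0/1 labels."""
    y_true = np.asarray(y_true, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise DataError("y_true and scores must have equal length")
    return float(math.sqrt(np.mean((scores - y_true) ** 2)))


def mae(y_true, scores) -> float:
    """Mean absolute error between scores and 0/1 labels."""
    y_true = np.asarray(y_true, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise DataError("y_true and scores must have equal length")
    return float(np.mean(np.abs(scores - y_true)))


@dataclass
class MetricsReport:
    """Confusion counts plus the six derived measures."""

    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    rmse: float
    mae: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "tp", "tn", "fp", "fn",
                    "accuracy", "precision", "recall", "f_measure",
                    "rmse", "mae",
                ],
                "value": [
                    self.counts.tp, self.counts.tn, self.counts.fp, self.counts.fn,
                    self.accuracy, self.precision, self.recall, self.f_measure,
                    self.rmse, self.mae,
                ],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __str__(self) -> str:
        c = self.counts
        lines = [
            f"confusion  tp={c.tp} tn={c.tn} fp={c.fp} fn={c.fn}",
            f"accuracy   {self.accuracy:.4f}",
            f"precision  {self.precision:.4f}",
            f"recall     {self.recall:.4f}",
            f"f-measure  {self.f_measure:.4f}",
            f"rmse       {self.rmse:.4f}",
            f"mae        {self.mae:.4f}",
        ]
        return "\n".join(lines)


def compute_report(
    y_true,
    y_pred,
    scores=None,
    strict_paper: bool = False,
    hard_label_errors: bool = False,
) -> MetricsReport:
    """Full report; RMSE/MAE use probabilities when given, labels otherwise.

    ``hard_label_errors`` forces RMSE/MAE onto the 0/1 predictions even
    when probability scores are available.
    """
    c = confusion_counts(y_true, y_pred)
    if scores is None or hard_label_errors:
        err_scores = np.asarray(y_pred, dtype=float)
    else:
        err_scores = np.asarray(scores, dtype=float)
    return MetricsReport(
        counts=c,
        accuracy=accuracy(c),
        precision=precision(c, strict_paper=strict_paper),
        recall=recall(c),
        f_measure=f_measure(c),
        rmse=rmse(y_true, err_scores),
        mae=mae(y_true, err_scores),
    )
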