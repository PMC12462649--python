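"""Confusion-matrix metrics, ROC/AUC and cross-validation fold summaries.

Scalar metrics follow the standard definitions
``sensitivity = TP / (TP + FN)``, ``specificity = TN / (TN + FP)``,
``accuracy = (TP + TN) / total``; a zero denominator yields NaN (the
metric is undefined, not zero) with a warning. Fold summaries take the
unweighted mean and median of the per-fold metrics — not pooled counts —
which is what reproduces published fold-table arithmetic exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve as sk_roc_curve

__all__ = [
    "ConfusionCounts", "RocCurve", "FoldSummary",
    "confusion", "sens_spec_acc", "roc_auc", "fold_summary", "round_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class FoldSummary:
    """Per-fold metric rows plus their unweighted mean and median."""

    per_fold: pd.DataFrame
    mean: dict[str, float]
    median: dict[str, float]


def confusion(decisions: Sequence[int], labels: Sequence[int]) -> ConfusionCounts:
    """Standard confusion counts from binary decisions and labels."""
    d = np.asarray(decisions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if d.shape != y.shape or d.size == 0:
        raise ValueError(f"decisions and labels must have equal length >= 1, got {d.shape} vs {y.shape}")
    return ConfusionCounts(
        TP=int(((d == 1) & (y == 1)).sum()),
        FP=int(((d == 1) & (y == 0)).sum()),
        TN=int(((d == 0) & (y == 0)).sum()),
        FN=int(((d == 0) & (y == 1)).sum()),
    )


def sens_spec_acc(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) as exact ratios; NaN where a
    denominator is zero."""
    if c.total < 1:
        raise ValueError("metric evaluation requires at least one observation")

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); returning NaN", stacklevel=3)
            return math.nan
        return num / den

    sens = _ratio(c.TP, c.TP + c.FN, "sensitivity")
    spec = _ratio(c.TN, c.TN + c.FP, "specificity")
    acc = (c.TP + c.TN) / c.total
    return sens, spec, acc


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve and trapezoidal AUC over the unique-score threshold
    sweep (tied scores step simultaneously).

    Equivalent to the Mann-Whitney pairwise comparison probability: the
    chance a random positive outscores a random negative, ties counting
    half.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, thr = sk_roc_curve(y, s, drop_intermediate=False)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(sk_auc(fpr, tpr)))


def round_report(x: float, decimals: int = 2) -> float:
    """Round half away from zero for report output (0.725 -> 0.73)."""
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fold_summary(rows: Sequence[ConfusionCounts], k: int = 5) -> FoldSummary:
    """Summarise k validation folds.

    Each fold's sensitivity/specificity/accuracy is computed from its
    own counts; the summary is the unweighted mean and median across the
    k folds, computed at full precision (use :func:`round_report` for
    2-decimal report output).
    """
    if len(rows) != k:
        raise ValueError(f"expected {k} fold rows, got {len(rows)}")
    records = []
    for i, c in enumerate(rows, start=1):
        sens, spec, acc = sens_spec_acc(c)
        records.append({"fold": i, "TN": c.TN, "FP": c.FP, "FN": c.FN, "TP": c.TP,
                        "accuracy": acc, "sensitivity": sens, "specificity": spec})
    df = pd.DataFrame.from_records(records).set_index("fold")
    metrics = ["accuracy", "sensitivity", "specificity"]
    mean = {m: float(df[m].mean()) for m in metrics}
    median = {m: float(df[m].median()) for m in metrics}
    return FoldSummary(per_fold=df, mean=mean, median=median)
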