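"""Confusion-matrix metrics and the distance-stratified accuracy report.

Metrics follow the standard binary-classification definitions, reported
as percentages:

    Acc = (TP + TN) / (TP + FP + TN + FN)
    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

Any undefined ratio (zero denominator) is reported as 0 and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: distance-bin edges in kb, half-open (lo, hi]
DEFAULT_DISTANCE_BINS_KB = [0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0, math.inf]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass(frozen=True)
class MetricsReport:
    """Acc/Sn/Sp as percentages, MCC as a percentage in [-100, 100]."""

    acc: float
    sn: float
    sp: float
    mcc: float
    auc: float | None = None
    undefined: tuple[str, ...] = field(default=())


def confusion_metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricsReport:
    """Acc, Sn, Sp and MCC (all x100) from a confusion matrix."""
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return 100.0 * num / den

    acc = ratio(cm.tp + cm.tn, cm.total, "acc")
    sn = ratio(cm.tp, cm.tp + cm.fn, "sn")
    sp = ratio(cm.tn, cm.tn + cm.fp, "sp")
    denom = (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tp + cm.fp) * (cm.tn + cm.fn)
    if denom == 0:
        undefined.append("mcc")
        mcc = 0.0
    else:
        mcc = 100.0 * (cm.tp * cm.tn - cm.fn * cm.fp) / math.sqrt(denom)
    return MetricsReport(acc, sn, sp, mcc, auc=auc, undefined=tuple(undefined))


def stratified_distance_report(
    y_true,
    y_pred,
    distances_bp,
    bin_edges_kb: list[float] | None = None,
) -> pd.DataFrame:
    """Per-distance-bin accuracy table.

    Bins are half-open ``(lo, hi]`` in kb, so a record at exactly 2.0 kb
    falls in the 0-2 bin.  Empty bins are flagged (`n = 0`, accuracy NaN).
    """
    edges = bin_edges_kb if bin_edges_kb is not None else DEFAULT_DISTANCE_BINS_KB
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    d_kb = np.asarray(distances_bp, dtype=float) / 1000.0
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (d_kb > lo) & (d_kb <= hi)
        n = int(mask.sum())
        acc = 100.0 * (y_true[mask] == y_pred[mask]).mean() if n else float("nan")
        label = f"{lo:g}-{hi:g}" if math.isfinite(hi) else f">{lo:g}"
        rows.append({"bin_kb": label, "n": n, "accuracy": acc, "empty": n == 0})
    return pd.DataFrame(rows)
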