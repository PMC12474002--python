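"""Per-point classification metrics and reconstruction summary tables.

The positive class is 1 = pruned.  Zero-denominator metrics return 0
rather than NaN so that aggregation over many trees stays stable.
Percentages round half-up to a fixed number of decimals using exact
decimal arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "metrics", "percent", "reconstruction_summary"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float


def confusion(truth, pred) -> ConfusionCounts:
    """Standard confusion counts for binary per-point labels."""
    truth = np.asarray(truth).ravel()
    pred = np.asarray(pred).ravel()
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction lengths differ")
    if not (np.isin(truth, (0, 1)).all() and np.isin(pred, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    tp = int(((truth == 1) & (pred == 1)).sum())
    fp = int(((truth == 0) & (pred == 1)).sum())
    tn = int(((truth == 0) & (pred == 0)).sum())
    fn = int(((truth == 1) & (pred == 0)).sum())
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F1; any 0/0 is 0 by convention."""
    if c.total == 0:
        raise ValueError("no evaluated points")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else 0.0

    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    f1 = 2.0 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return MetricsReport(
        accuracy=ratio(c.tp + c.tn, c.total),
        precision=precision,
        recall=recall,
        f1=f1,
    )


def percent(k: int, n: int, decimals: int = 1) -> float:
    """100 k / n rounded half-up to ``decimals`` using exact decimal arithmetic."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100 * k) / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))


def reconstruction_summary(pre_ok: int, post_ok: int, both_ok: int, annotated: int, total: int) -> pd.DataFrame:
    """Counts and percentages of successfully reconstructed / annotated models.

    Columns: pre-pruning, post-pruning, both reconstructed, annotated; rows:
    raw counts and their percentage of ``total``.
    """
    counts = {"pre_pruning": pre_ok, "post_pruning": post_ok, "both_reconstructed": both_ok, "annotated": annotated}
    if total <= 0:
        raise ValueError("total must be > 0")
    if any(v < 0 or v > total for v in counts.values()):
        raise ValueError("counts must lie in [0, total]")
    if annotated > both_ok:
        raise ValueError("annotated models cannot exceed models with both reconstructions")
    if both_ok > min(pre_ok, post_ok):
        raise ValueError("both-reconstructed count cannot exceed either single count")
    return pd.DataFrame(
        {name: [v, percent(v, total)] for name, v in counts.items()},
        index=["count", "percent"],
    )
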