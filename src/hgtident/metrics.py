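"""Confusion-matrix bookkeeping: Recall and Mean error (balanced error rate).

Recall = 100 * TP / (TP + FN) is the detection rate on the HGT class.
Mean error = 100 * 0.5 * (FN/(FN+TP) + FP/(FP+TN)) — the average of the
false-negative and false-positive rates, i.e. 100 minus the balanced
accuracy in percent.  Fold averages are macro (mean of per-fold values);
pooled-count micro averaging is available via ``micro=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding as used when formatting result tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts are all zero")

    @staticmethod
    def from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return ConfusionCounts(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def recall(c: ConfusionCounts) -> float:
    """Detection rate in percent: 100 * TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise ValueError("recall undefined: no positive examples (tp + fn == 0)")
    return 100.0 * c.tp / (c.tp + c.fn)


def mean_error(c: ConfusionCounts) -> float:
    """Balanced error rate in percent: 100 * (FNR + FPR) / 2."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("mean error undefined: one class is empty")
    fnr = c.fn / (c.fn + c.tp)
    fpr = c.fp / (c.fp + c.tn)
    return 100.0 * 0.5 * (fnr + fpr)


@dataclass
class EvalResult:
    """Per-fold confusion counts with macro-averaged Recall and Mean error."""

    per_fold: list[ConfusionCounts]
    recall_pct: float
    mean_error_pct: float

    def fold_recalls(self) -> list[float]:
        return [recall(c) for c in self.per_fold]

    def fold_mean_errors(self) -> list[float]:
        return [mean_error(c) for c in self.per_fold]


def aggregate_folds(folds: list[ConfusionCounts], micro: bool = False) -> EvalResult:
    """Average fold results: macro (default, mean of fold values) or micro (pooled)."""
    if not folds:
        raise ValueError("no folds to aggregate")
    if micro:
        pooled = ConfusionCounts(
            tp=sum(c.tp for c in folds),
            fp=sum(c.fp for c in folds),
            tn=sum(c.tn for c in folds),
            fn=sum(c.fn for c in folds),
        )
        return EvalResult(list(folds), recall(pooled), mean_error(pooled))
    r = float(np.mean([recall(c) for c in folds]))
    e = float(np.mean([mean_error(c) for c in folds]))
    return EvalResult(list(folds), r, e)


def table_deltas(
    before: list[tuple[float, float]], after: list[tuple[float, float]]
) -> tuple[float, float]:
    """Mean paired improvement between two result columns.

    Each element is a (Recall, Mean error) pair in percent.  Returns
    (mean Recall gain, mean Mean-error reduction), both rounded to 2
    decimals half-up — positive when ``after`` has higher Recall and
    lower Mean error.
    """
    if len(before) != len(after):
        raise ValueError(f"length mismatch: {len(before)} vs {len(after)}")
    if not before:
        raise ValueError("empty result lists")
    d_recall = float(np.mean([a[0] - b[0] for b, a in zip(before, after)]))
    d_err = float(np.mean([b[1] - a[1] for b, a in zip(before, after)]))
    return round_half_up(d_recall), round_half_up(d_err)


def format_eval_table(rows: list[tuple[str, EvalResult]]) -> str:
    """TSV in the result-table layout: genome, Recall, Mean error (2 decimals)."""
    lines = ["genome\tRecall\tMean error"]
    for name, res in rows:
        lines.append(
            f"{name}\t{round_half_up(res.recall_pct):.2f}\t"
            f"{round_half_up(res.mean_error_pct):.2f}"
        )
    return "\n".join(lines) + "\n"
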