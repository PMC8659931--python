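"""Confusion-matrix metrics for the 3-class decoding problem.

Classes are reported in the fixed order (resting, picking, coordination).
Per class: PPV (precision), TPR (recall), FNR = 1 - TPR, FDR = 1 - PPV;
overall: total prediction accuracy = trace / m.  Percentages can be
formatted either with round-half-even or truncation at two decimals, since
published tables mix both conventions (e.g. 89/120 printed as 74.16).
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .synthetic import CONDITIONS

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "class_metrics",
    "channel_comparison",
    "format_percent",
    "first_order_errors_only",
]


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Tally the 3x3 confusion matrix in the fixed class order."""
    true = np.asarray(true_labels, dtype=object)
    pred = np.asarray(predicted_labels, dtype=object)
    if len(true) != len(pred):
        raise ValueError("true and predicted label lists differ in length")
    unknown = (set(np.unique(true)) | set(np.unique(pred))) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    counts = _sk_confusion(true.astype(str), pred.astype(str), labels=list(CONDITIONS))
    return ConfusionMatrix(counts=counts)


def class_metrics(cm: ConfusionMatrix) -> dict:
    """Per-class PPV/TPR/FNR/FDR (fractions) and total accuracy.

    PPV is ``None`` (undefined, never 0) for a class that was never
    predicted; FDR is ``None`` alongside it.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    rows, cols = cm.row_totals(), cm.col_totals()
    per_class: dict[str, dict[str, float | None]] = {}
    for j, label in enumerate(cm.labels):
        diag = cm.counts[j, j]
        ppv = diag / cols[j] if cols[j] > 0 else None
        tpr = diag / rows[j] if rows[j] > 0 else None
        per_class[label] = {
            "ppv": ppv,
            "tpr": tpr,
            "fnr": None if tpr is None else 1.0 - tpr,
            "fdr": None if ppv is None else 1.0 - ppv,
        }
    return {
        "per_class": per_class,
        "accuracy": float(np.trace(cm.counts) / cm.total),
        "n_correct": int(np.trace(cm.counts)),
        "total": cm.total,
    }


def format_percent(fraction: float | None, decimals: int = 2, mode: str = "half_even") -> float | None:
    """Express a fraction as a percentage at fixed precision.

    ``half_even`` is banker's rounding; ``truncate`` drops the remaining
    digits (some published tables truncate: 89/120 -> 74.16).
    """
    if fraction is None:
        return None
    pct = float(fraction) * 100.0
    scale = 10 ** decimals
    if mode == "half_even":
        # decimal-exact half-even on the printed digits
        from decimal import Decimal, ROUND_HALF_EVEN
        q = Decimal(repr(pct)).quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_EVEN)
        return float(q)
    if mode == "truncate":
        return math.floor(pct * scale + 1e-9) / scale
    raise ValueError(f"unknown rounding mode '{mode}'")


def channel_comparison(per_channel: dict[str, tuple[float, int]]) -> dict:
    """Best-vs-worst channel gap.

    ``per_channel`` maps channel name -> (accuracy percentage, correct count).
    Returns the gap in percentage points and in correctly predicted epochs.
    """
    if len(per_channel) < 2:
        raise ValueError("need at least two channels to compare")
    best = max(per_channel, key=lambda c: per_channel[c][0])
    worst = min(per_channel, key=lambda c: per_channel[c][0])
    return {
        "best_channel": best,
        "worst_channel": worst,
        "gap_percentage_points": round(per_channel[best][0] - per_channel[worst][0], 10),
        "gap_correct_counts": per_channel[best][1] - per_channel[worst][1],
    }


def first_order_errors_only(cm: ConfusionMatrix) -> bool:
    """True when confusions only occur between adjacent reasoning depths:
    resting is never mistaken for coordination and vice versa."""
    i_rest = cm.labels.index("resting")
    i_coord = cm.labels.index("coordination")
    return bool(cm.counts[i_rest, i_coord] == 0 and cm.counts[i_coord, i_rest] == 0)
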