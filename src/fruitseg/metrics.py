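"""Pixel-level detection metrics and ROC construction.

TPR is the fraction of fruit pixels detected; FPR the fraction of
background pixels wrongly detected.  The F-score balances the two:

    F(TPR, FPR) = 2 * TPR * (1 - FPR) / (TPR + (1 - FPR))

which is the harmonic mean of TPR and the true-negative rate.  ROC curves
sweep evenly spaced candidate thresholds for one color dimension; the
classification-rule direction says whether fruit lies above (GT) or below
(LT) the threshold.
"""

from __future__ import annotations

import enum
from typing import NamedTuple

import numpy as np


class UndefinedMetricError(ValueError):
    """A rate's denominator class is empty (no fruit / no background)."""


class Direction(enum.Enum):
    """Side of the threshold on which fruit pixels lie."""

    GT = "gt"  # fruit: value > threshold
    LT = "lt"  # fruit: value < threshold


class RocPoint(NamedTuple):
    threshold: float
    tpr: float
    fpr: float


def as_binary(mask: np.ndarray) -> np.ndarray:
    """Validate and return a boolean view of a {0, 1} mask."""
    arr = np.asarray(mask)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask is not binary; found values {uniq[:5]}")
        arr = arr.astype(bool)
    return arr


def tpr(pred: np.ndarray, truth: np.ndarray) -> float:
    """True positive rate: detected fruit pixels / actual fruit pixels."""
    p, t = as_binary(pred), as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    n_fruit = int(t.sum())
    if n_fruit == 0:
        raise UndefinedMetricError("truth contains no fruit pixels")
    return float((p & t).sum() / n_fruit)


def fpr(pred: np.ndarray, truth: np.ndarray) -> float:
    """False positive rate: falsely detected pixels / background pixels."""
    p, t = as_binary(pred), as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    n_bg = int((~t).sum())
    if n_bg == 0:
        raise UndefinedMetricError("truth contains no background pixels")
    return float((p & ~t).sum() / n_bg)


def f_score(tpr_value: float, fpr_value: float) -> float:
    """Balanced F-score of a (TPR, FPR) pair; 0 when the denominator is 0."""
    tnr = 1.0 - fpr_value
    den = tpr_value + tnr
    if den == 0:
        return 0.0
    return 2.0 * tpr_value * tnr / den


def roc_curve(
    fruit_values: np.ndarray,
    bg_values: np.ndarray,
    direction: Direction = Direction.GT,
    n_levels: int = 256,
    value_range: tuple[float, float] | None = None,
) -> list[RocPoint]:
    """Sweep ``n_levels`` evenly spaced thresholds and record (TPR, FPR).

    Classification is strict: a pixel is fruit when its value is strictly
    above (GT) or strictly below (LT) the candidate threshold.  By default
    the sweep spans the observed value range of both classes; pass
    ``value_range`` to pin it to the channel's declared range instead.
    """
    fruit = np.sort(np.asarray(fruit_values, dtype=np.float64).ravel())
    bg = np.sort(np.asarray(bg_values, dtype=np.float64).ravel())
    if fruit.size == 0 or bg.size == 0:
        raise UndefinedMetricError("both classes need at least one value")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if value_range is None:
        lo = min(fruit[0], bg[0])
        hi = max(fruit[-1], bg[-1])
    else:
        lo, hi = value_range
    if hi <= lo:
        hi = lo + 1.0
    thresholds = np.linspace(lo, hi, n_levels)
    if direction is Direction.GT:
        tp = fruit.size - np.searchsorted(fruit, thresholds, side="right")
        fp = bg.size - np.searchsorted(bg, thresholds, side="right")
    elif direction is Direction.LT:
        tp = np.searchsorted(fruit, thresholds, side="left")
        fp = np.searchsorted(bg, thresholds, side="left")
    else:  # pragma: no cover - guarded by the enum
        raise ValueError(f"unknown direction {direction!r}")
    return [
        RocPoint(float(t), float(a) / fruit.size, float(b) / bg.size)
        for t, a, b in zip(thresholds, tp, fp)
    ]


def roc_to_csv(points: list[RocPoint], path) -> None:
    """Write a ROC curve as CSV with columns threshold, tpr, fpr."""
    import pandas as pd

    pd.DataFrame(points, columns=["threshold", "tpr", "fpr"]).to_csv(
        path, index=False
    )
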