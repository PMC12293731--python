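"""Evaluation metrics: interval Dice, R^2, MAE, MSE, BCE, confusion metrics.

Boundary overlap is scored with the Dice coefficient applied to the slice
*index sets* of predicted versus annotated aneurysm intervals along the
axial axis:

    Dice = 2 TP / (2 TP + FP + FN)

with TP = |pred ∩ truth|, FP = |pred \\ truth|, FN = |truth \\ pred|.
Start/end slice placement and volume agreement are scored with
R^2 = 1 - RSS/TSS, MAE and MSE; probabilistic slice labels with binary
cross-entropy.  A mask-level (2D) Dice is provided for mask-vs-mask
comparisons.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import BoundaryInterval, ConfusionTable, PairedSeries

__all__ = [
    "interval_dice",
    "mask_dice",
    "r2",
    "mae",
    "mse",
    "bce",
    "classification_metrics",
    "boundary_report",
]

BCE_EPS = 1e-7


def interval_dice(
    pred: Optional[BoundaryInterval], truth: BoundaryInterval
) -> float:
    """Dice overlap of two inclusive slice intervals; an absent prediction scores 0."""
    if pred is None:
        return 0.0
    tp = max(0, min(pred.end, truth.end) - max(pred.start, truth.start) + 1)
    fp = len(pred) - tp
    fn = len(truth) - tp
    return 2 * tp / (2 * tp + fp + fn)


def mask_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap of two binary masks of identical shape."""
    pred = np.asarray(pred) != 0
    truth = np.asarray(truth) != 0
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    tp = int(np.sum(pred & truth))
    denom = int(pred.sum()) + int(truth.sum())
    if denom == 0:
        return 1.0  # two empty masks agree perfectly
    return 2 * tp / denom


def r2(series: PairedSeries) -> float:
    """Coefficient of determination 1 - RSS/TSS of predicted vs true values."""
    if series.n < 2:
        raise ValueError("R^2 needs at least 2 samples")
    yt, yp = series.y_true, series.y_pred
    tss = float(np.sum((yt - yt.mean()) ** 2))
    if tss == 0:
        raise ValueError("R^2 undefined for constant y_true")
    rss = float(np.sum((yt - yp) ** 2))
    return 1.0 - rss / tss


def mae(series: PairedSeries) -> float:
    return float(np.mean(np.abs(series.y_true - series.y_pred)))


def mse(series: PairedSeries) -> float:
    return float(np.mean((series.y_true - series.y_pred) ** 2))


def bce(series: PairedSeries) -> float:
    """Mean binary cross-entropy; predictions are clipped to [eps, 1-eps]."""
    yt = series.y_true
    if not np.all((yt == 0) | (yt == 1)):
        raise ValueError("BCE requires binary y_true")
    yp = np.clip(series.y_pred, BCE_EPS, 1 - BCE_EPS)
    return float(-np.mean(yt * np.log(yp) + (1 - yt) * np.log(1 - yp)))


def _safe_div(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def classification_metrics(cm: ConfusionTable) -> dict[str, Optional[float]]:
    """Accuracy, precision, recall, specificity and F1 from a 2x2 table.

    A metric whose denominator is zero is reported as None (undefined),
    never silently as 0.
    """
    acc = (cm.tp + cm.tn) / cm.total
    precision = _safe_div(cm.tp, cm.tp + cm.fp)
    recall = _safe_div(cm.tp, cm.tp + cm.fn)
    specificity = _safe_div(cm.tn, cm.tn + cm.fp)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": acc,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
    }


def boundary_report(
    predictions: Sequence[Optional[BoundaryInterval]],
    truths: Sequence[BoundaryInterval],
    volumes_pred: Optional[Sequence[float]] = None,
    volumes_true: Optional[Sequence[float]] = None,
    detector: str = "detector",
) -> pd.DataFrame:
    """One-row performance table for a boundary detector.

    Columns: R^2 start/end, MAE start/end, MSE start/end, mean interval
    Dice, volume R^2, and the number of absent predictions (absent
    predictions score Dice 0 and are excluded from the start/end and volume
    regressions).
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must align")
    dice_scores = [interval_dice(p, t) for p, t in zip(predictions, truths)]
    kept = [i for i, p in enumerate(predictions) if p is not None]
    if not kept:
        raise ValueError("no valid predictions to report on")
    n_absent = len(predictions) - len(kept)

    def _reg(extract_true, extract_pred) -> PairedSeries:
        return PairedSeries(
            y_true=[extract_true(i) for i in kept],
            y_pred=[extract_pred(i) for i in kept],
        )

    starts = _reg(lambda i: truths[i].start, lambda i: predictions[i].start)
    ends = _reg(lambda i: truths[i].end, lambda i: predictions[i].end)
    row = {
        "detector": detector,
        "r2_start": r2(starts),
        "r2_end": r2(ends),
        "mae_start": mae(starts),
        "mae_end": mae(ends),
        "mse_start": mse(starts),
        "mse_end": mse(ends),
        "dice": float(np.mean(dice_scores)),
        "r2_volume": math.nan,
        "n_absent": n_absent,
    }
    if volumes_pred is not None and volumes_true is not None:
        vols = PairedSeries(
            y_true=[volumes_true[i] for i in kept],
            y_pred=[volumes_pred[i] for i in kept],
        )
        row["r2_volume"] = r2(vols)
    return pd.DataFrame([row])
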