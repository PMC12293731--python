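"""Core domain containers shared across the pipeline.

The whole package operates on one humble object: the *area signal*, the
per-axial-slice count of segmented aortic-lumen pixels, ordered from the
thoracic aorta (index 0) down to the iliac bifurcation.  A fusiform
abdominal aortic aneurysm shows up in this 1D signal as a sustained bulge;
an upstream segmentation model trained only on normal anatomy shows up as a
sustained dropout (counts collapsing to zero).  Everything downstream —
screening, boundary detection, surrogate volumetrics, evaluation — consumes
these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "AreaSignal",
    "BoundaryInterval",
    "MaskStack",
    "ConfusionTable",
    "PairedSeries",
    "VolumeReport",
]


@dataclass(frozen=True)
class BoundaryInterval:
    """Inclusive [start, end] slice interval of an aneurysm.

    Slice indices are 0-based and axial, increasing from the thoracic aorta
    toward the iliac bifurcation.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}]: "
                "need 0 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def slices(self) -> range:
        return range(self.start, self.end + 1)

    def validate_for(self, n: int) -> None:
        if self.end >= n:
            raise ValueError(
                f"interval [{self.start}, {self.end}] out of range for "
                f"signal of {n} slices"
            )


@dataclass
class AreaSignal:
    """A patient's ordered per-slice segmented pixel counts."""

    patient_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a nonempty 1D sequence")
        if np.any(self.counts < 0):
            raise ValueError("pixel counts must be nonnegative")
        self.counts = self.counts.astype(np.int64)

    @property
    def n(self) -> int:
        return int(self.counts.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AreaSignal):
            return NotImplemented
        return self.patient_id == other.patient_id and np.array_equal(
            self.counts, other.counts
        )


@dataclass
class MaskStack:
    """An ordered stack of same-sized binary (0/1) segmentation masks."""

    patient_id: str
    slices: np.ndarray  # (n_slices, height, width), values 0/1

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValueError("slices must be a nonempty (n, h, w) array")
        # any nonzero input pixel maps to 1
        self.slices = (self.slices != 0).astype(np.uint8)

    @property
    def n(self) -> int:
        return int(self.slices.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return (int(self.slices.shape[1]), int(self.slices.shape[2]))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 classification counts with aneurysm as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion table must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class PairedSeries:
    """Aligned true/predicted numeric sequences for regression metrics."""

    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, dtype=float)
        self.y_pred = np.asarray(self.y_pred, dtype=float)
        if self.y_true.shape != self.y_pred.shape or self.y_true.ndim != 1:
            raise ValueError("y_true and y_pred must be 1D and equal length")
        if self.y_true.size < 1:
            raise ValueError("series must be nonempty")

    @property
    def n(self) -> int:
        return int(self.y_true.size)


@dataclass
class VolumeReport:
    """Surrogate aneurysm volume versus the interpolated normal baseline.

    Volumes are unit-less pixel-slice sums (the pixel-count surrogate is
    proportional to physical lumen volume but carries no mm^3 calibration).
    """

    observed_volume: float
    baseline_volume: float
    enlargement_pct: float
    interval: BoundaryInterval
    patient_id: Optional[str] = None
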