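"""Surrogate aneurysm volume and enlargement versus an interpolated baseline.

The surrogate volume of an aneurysm spanning slices s..e is the plain sum
of segmented pixel counts over that interval,

    Vol = sum_{i=s}^{e} P_i ,

a unit-less pixel-slice quantity proportional to true lumen volume (no
voxel-size calibration is attempted).  The *normal* aorta the patient would
have had without the aneurysm is estimated by linearly interpolating the
pixel counts between the start and end slices; the area between the
observed signal and that line quantifies enlargement, reported as a
percentage of the observed volume.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .types import AreaSignal, BoundaryInterval, VolumeReport

__all__ = [
    "surrogate_volume",
    "interpolated_baseline",
    "enlargement_percent",
    "volume_report",
    "cohort_enlargement_stats",
]


def surrogate_volume(signal: AreaSignal, interval: BoundaryInterval) -> float:
    """Sum of pixel counts over the inclusive slice interval."""
    interval.validate_for(signal.n)
    return float(signal.counts[interval.start:interval.end + 1].sum())


def interpolated_baseline(
    signal: AreaSignal, interval: BoundaryInterval
) -> tuple[np.ndarray, float]:
    """Linear normal-aorta baseline across the interval and its volume.

    Returns the per-slice baseline (linear interpolation between the
    measured counts at the start and end slices) and its sum, which equals
    (counts[start] + counts[end]) / 2 * interval length exactly.
    """
    interval.validate_for(signal.n)
    c0 = float(signal.counts[interval.start])
    c1 = float(signal.counts[interval.end])
    length = len(interval)
    baseline = np.linspace(c0, c1, length)
    # arithmetic-series identity keeps the volume exact
    baseline_volume = (c0 + c1) / 2.0 * length
    return baseline, baseline_volume


def enlargement_percent(observed_volume: float, baseline_volume: float) -> float:
    """Percentage of the observed volume attributable to enlargement.

    Computed as 100 * (observed - baseline) / observed; undefined (error)
    when the observed volume is zero.
    """
    if observed_volume <= 0:
        raise ValueError("enlargement undefined for observed_volume <= 0")
    return 100.0 * (observed_volume - baseline_volume) / observed_volume


def volume_report(signal: AreaSignal, interval: BoundaryInterval) -> VolumeReport:
    """Observed volume, interpolated baseline volume and enlargement percent."""
    observed = surrogate_volume(signal, interval)
    _, baseline = interpolated_baseline(signal, interval)
    return VolumeReport(
        observed_volume=observed,
        baseline_volume=baseline,
        enlargement_pct=enlargement_percent(observed, baseline),
        interval=interval,
        patient_id=signal.patient_id,
    )


def cohort_enlargement_stats(reports: Sequence[VolumeReport]) -> dict:
    """Sample mean, median and standard deviation (n-1) of enlargement percentages."""
    if not reports:
        raise ValueError("no volume reports supplied")
    pcts = np.array([r.enlargement_pct for r in reports], dtype=float)
    single = pcts.size == 1
    return {
        "n": int(pcts.size),
        "mean_pct": float(pcts.mean()),
        "median_pct": float(np.median(pcts)),
        "sd_pct": 0.0 if single else float(pcts.std(ddof=1)),
        "sd_undefined": single,
    }
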