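"""Segmentation-failure screening: flag scans with a persistent signal anomaly.

A segmentation model trained only on normal aortic anatomy stops producing
masks when the vessel wall turns pathological, so its per-slice pixel-count
signal collapses (or, less commonly, balloons) over the diseased region.
The screening rule keeps a rolling average of the counts over the last few
*non-anomalous* slices as the normal baseline and flags any slice that
drops below ``low_frac`` (default 50%) or exceeds ``high_frac`` (default
140%) of it.  Only deviations persisting over ``persistence`` consecutive
slices (default 4) count as an anomaly; the first flagged slice marks the
aneurysm start and the last flagged slice before recovery marks its end.

Excluding flagged slices from the rolling average is essential: a dropout
region fed back into the baseline would drag it to zero and un-flag itself.
Equivalently, the baseline freezes at its pre-anomaly value until
``persistence`` consecutive slices agree with it again.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .metrics import classification_metrics
from .types import AreaSignal, BoundaryInterval, ConfusionTable

__all__ = ["ScreeningRule", "ScreeningResult", "screen_signal", "evaluate_screening"]


@dataclass(frozen=True)
class ScreeningRule:
    window: int = 4
    low_frac: float = 0.50
    high_frac: float = 1.40
    persistence: int = 4

    def __post_init__(self) -> None:
        if self.window < 1 or self.persistence < 1:
            raise ValueError("window and persistence must be positive")
        if not self.low_frac < 1 < self.high_frac:
            raise ValueError("need low_frac < 1 < high_frac")


@dataclass
class ScreeningResult:
    is_aneurysm: bool
    anomaly: Optional[BoundaryInterval]
    baseline_trace: np.ndarray  # per-slice baseline used (nan before warm-up)

    def __post_init__(self) -> None:
        if self.is_aneurysm != (self.anomaly is not None):
            raise ValueError("anomaly must be present iff is_aneurysm")


def _deviates(count: float, baseline: float, rule: ScreeningRule) -> bool:
    if baseline == 0:
        return count > 0  # any reappearance against an empty baseline is anomalous
    return count < rule.low_frac * baseline or count > rule.high_frac * baseline


def screen_signal(signal: AreaSignal, rule: ScreeningRule = ScreeningRule()) -> ScreeningResult:
    """Scan a signal left to right for a persistent relative anomaly.

    The first ``window`` slices seed the baseline and are never flagged.
    When several disjoint anomaly runs occur, the longest (earliest on ties)
    is reported.
    """
    n = signal.n
    if n <= rule.window + rule.persistence:
        raise ValueError(
            f"signal of {n} slices too short for window {rule.window} + "
            f"persistence {rule.persistence}"
        )
    counts = signal.counts.astype(float)
    history: deque[float] = deque(counts[:rule.window], maxlen=rule.window)
    baseline_trace = np.full(n, np.nan)

    runs: list[tuple[int, int]] = []  # closed anomaly runs [first, last] flagged
    pending_start: Optional[int] = None   # first slice of current flagged streak
    pending_len = 0
    active: Optional[tuple[int, int]] = None  # open anomaly (start, last flagged)
    recovery_buffer: list[float] = []

    for i in range(rule.window, n):
        baseline = float(np.mean(history))
        baseline_trace[i] = baseline
        flagged = _deviates(counts[i], baseline, rule)

        if active is None:
            if flagged:
                if pending_len == 0:
                    pending_start = i
                pending_len += 1
                if pending_len >= rule.persistence:
                    active = (pending_start, i)
            else:
                pending_len = 0
                history.append(counts[i])
        else:
            if flagged:
                active = (active[0], i)
                recovery_buffer.clear()  # recovery streak broken
            else:
                recovery_buffer.append(counts[i])
                if len(recovery_buffer) >= rule.persistence:
                    runs.append(active)
                    active = None
                    pending_len = 0
                    history.extend(recovery_buffer)
                    recovery_buffer.clear()

    if active is not None:
        runs.append(active)

    if not runs:
        return ScreeningResult(False, None, baseline_trace)
    start, end = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    return ScreeningResult(True, BoundaryInterval(start, end), baseline_trace)


def evaluate_screening(
    results: Sequence[tuple[ScreeningResult, bool]]
) -> ConfusionTable:
    """2x2 confusion counts over (result, true label) pairs; aneurysm = positive."""
    if not results:
        raise ValueError("no screening results supplied")
    tp = fp = fn = tn = 0
    for res, truth in results:
        if res.is_aneurysm and truth:
            tp += 1
        elif res.is_aneurysm and not truth:
            fp += 1
        elif not res.is_aneurysm and truth:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
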