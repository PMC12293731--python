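"""Rule-based aneurysm boundary detector on continuous area signals.

The expert rule scans the per-slice pixel-count signal with a sliding
window (default 4 slices).  A candidate *start* is a slice where the counts
exceed 120% of the running average of the preceding window consistently
across the whole window; a candidate *end* is a slice where they drop below
80% of it, again across the whole window.  The running average is anchored
at the candidate: all ``window`` slices are compared against the single
mean of the ``window`` slices preceding the candidate (a per-slice rolling
mean would absorb the rise within two or three slices and could never stay
exceeded for four in a row).

Among all valid (start, end) candidate pairs the rule keeps the largest
abnormality window — the pair maximizing the span, earliest start on ties —
and reports the inclusive interval from the rise up to the slice before the
sustained drop.  ``grid_search_expert`` tunes the window and the two
thresholds against annotated signals by mean interval Dice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import interval_dice
from .types import AreaSignal, BoundaryInterval

__all__ = [
    "ExpertRule",
    "detect_expert",
    "candidate_starts",
    "candidate_ends",
    "grid_search_expert",
    "DEFAULT_GRID",
]

#: default tuning grid (the operating point window=4, 120%/80% sits inside it)
DEFAULT_GRID = {
    "window": (3, 4, 5, 6),
    "start_frac": (1.10, 1.15, 1.20, 1.25, 1.30, 1.40),
    "end_frac": (0.60, 0.70, 0.75, 0.80, 0.85, 0.90),
}


@dataclass(frozen=True)
class ExpertRule:
    window: int = 4
    start_frac: float = 1.20
    end_frac: float = 0.80

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be positive")
        if not self.end_frac < 1 < self.start_frac:
            raise ValueError("need end_frac < 1 < start_frac")


def _window_means(counts: np.ndarray, window: int) -> np.ndarray:
    """means[i] = mean(counts[i-window:i]) for i in [window, n]."""
    csum = np.concatenate(([0.0], np.cumsum(counts, dtype=float)))
    return (csum[window:] - csum[:-window]) / window


def candidate_starts(counts: np.ndarray, rule: ExpertRule) -> np.ndarray:
    """Slices i where counts[i:i+window] all exceed start_frac * mean(counts[i-window:i])."""
    n = counts.size
    w = rule.window
    means = _window_means(counts, w)  # means[k] anchors candidate i = k + w
    valid = []
    for i in range(w, n - w + 1):
        thr = rule.start_frac * means[i - w]
        if np.all(counts[i:i + w] > thr):
            valid.append(i)
    return np.asarray(valid, dtype=int)


def candidate_ends(counts: np.ndarray, rule: ExpertRule) -> np.ndarray:
    """Slices j where counts[j:j+window] all fall below end_frac * mean(counts[j-window:j])."""
    n = counts.size
    w = rule.window
    means = _window_means(counts, w)
    valid = []
    for j in range(w, n - w + 1):
        thr = rule.end_frac * means[j - w]
        if np.all(counts[j:j + w] < thr):
            valid.append(j)
    return np.asarray(valid, dtype=int)


def detect_expert(
    signal: AreaSignal, rule: ExpertRule = ExpertRule()
) -> Optional[BoundaryInterval]:
    """Detect the aneurysm interval [rise, sustained-drop - 1], or None.

    The returned pair maximizes the span end-start over all valid
    candidates (ties broken by the earliest start); with valid starts S and
    valid drops E this is simply (min S, max {j in E : j > min S}).
    """
    if signal.n <= 2 * rule.window:
        raise ValueError(
            f"signal of {signal.n} slices too short for window {rule.window}"
        )
    counts = signal.counts.astype(float)
    starts = candidate_starts(counts, rule)
    ends = candidate_ends(counts, rule)
    if starts.size == 0 or ends.size == 0:
        return None
    i = int(starts.min())
    later = ends[ends > i]
    if later.size == 0:
        return None
    j = int(later.max())
    return BoundaryInterval(i, j - 1)


def grid_search_expert(
    cohort: Sequence[tuple[AreaSignal, BoundaryInterval]],
    grid: dict | None = None,
) -> tuple[ExpertRule, pd.DataFrame]:
    """Exhaustively tune the rule by mean interval Dice over annotated signals.

    Returns the best rule and the full score table.  Ties are broken by
    smaller window, then start_frac nearest 1.20, then end_frac nearest
    0.80 (the rule's canonical operating point).
    """
    if not cohort:
        raise ValueError("empty cohort")
    grid = dict(DEFAULT_GRID if grid is None else grid)
    combos = list(itertools.product(
        grid["window"], grid["start_frac"], grid["end_frac"]
    ))
    if not combos:
        raise ValueError("empty grid")
    rows = []
    for w, sf, ef in combos:
        rule = ExpertRule(window=int(w), start_frac=float(sf), end_frac=float(ef))
        scores = []
        for sig, truth in cohort:
            pred = detect_expert(sig, rule) if sig.n > 2 * rule.window else None
            scores.append(interval_dice(pred, truth))
        rows.append({
            "window": rule.window,
            "start_frac": rule.start_frac,
            "end_frac": rule.end_frac,
            "mean_dice": float(np.mean(scores)),
        })
    table = pd.DataFrame(rows)
    best = table.loc[
        table.assign(
            _d=lambda t: -t.mean_dice,
            _sf=lambda t: np.abs(t.start_frac - 1.20),
            _ef=lambda t: np.abs(t.end_frac - 0.80),
        ).sort_values(["_d", "window", "_sf", "_ef"], kind="stable").index[0]
    ]
    rule = ExpertRule(
        window=int(best.window),
        start_frac=float(best.start_frac),
        end_frac=float(best.end_frac),
    )
    return rule, table
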