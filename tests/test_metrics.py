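import math

import numpy as np
import pytest
from sklearn.metrics import r2_score

from aaaquant.metrics import (
    bce,
    boundary_report,
    classification_metrics,
    interval_dice,
    mae,
    mask_dice,
    mse,
    r2,
)
from aaaquant.types import BoundaryInterval, ConfusionTable, PairedSeries


# --- independent brute-force oracles ---------------------------------------

def dice_oracle(pred, truth):
    if pred is None:
        return 0.0
    a = set(range(pred.start, pred.end + 1))
    b = set(range(truth.start, truth.end + 1))
    tp, fp, fn = len(a & b), len(a - b), len(b - a)
    return 2 * tp / (2 * tp + fp + fn)


def r2_oracle(yt, yp):
    mean = sum(yt) / len(yt)
    rss = sum((t - p) ** 2 for t, p in zip(yt, yp))
    tss = sum((t - mean) ** 2 for t in yt)
    return 1 - rss / tss


def mae_oracle(yt, yp):
    return sum(abs(t - p) for t, p in zip(yt, yp)) / len(yt)


def mse_oracle(yt, yp):
    return sum((t - p) ** 2 for t, p in zip(yt, yp)) / len(yt)


def bce_oracle(yt, yp, eps=1e-7):
    total = 0.0
    for t, p in zip(yt, yp):
        p = min(max(p, eps), 1 - eps)
        total += t * math.log(p) + (1 - t) * math.log(1 - p)
    return -total / len(yt)


class TestIntervalDice:
    def test_identical_intervals(self):
        iv = BoundaryInterval(5, 25)
        assert interval_dice(iv, iv) == 1.0

    def test_disjoint_intervals(self):
        assert interval_dice(BoundaryInterval(0, 4), BoundaryInterval(10, 14)) == 0.0

    def test_partial_overlap_hand_case(self):
        got = interval_dice(BoundaryInterval(10, 20), BoundaryInterval(15, 25))
        assert got == pytest.approx(12 / 22, abs=1e-15)

    def test_absent_prediction_scores_zero(self):
        assert interval_dice(None, BoundaryInterval(0, 9)) == 0.0

    def test_symmetry_and_identity_on_random_intervals(self, rng):
        for _ in range(200):
            a = sorted(rng.integers(0, 80, size=2))
            b = sorted(rng.integers(0, 80, size=2))
            pa, pb = BoundaryInterval(*a), BoundaryInterval(*b)
            assert interval_dice(pa, pb) == interval_dice(pb, pa)
            assert interval_dice(pa, pb) == pytest.approx(
                dice_oracle(pa, pb), abs=1e-15
            )
            assert (interval_dice(pa, pb) == 1.0) == (pa == pb)


class TestRegressionMetrics:
    def test_hand_cases(self):
        s = PairedSeries([1, 2, 3, 4], [2, 2, 3, 3])
        assert r2(s) == pytest.approx(0.6, abs=1e-12)   # 1 - 2/5
        assert mae(s) == pytest.approx(0.5)
        assert mse(s) == pytest.approx(0.5)

    def test_perfect_and_mean_predictors(self, rng):
        yt = rng.normal(size=50)
        assert r2(PairedSeries(yt, yt)) == 1.0
        assert r2(PairedSeries(yt, np.full(50, yt.mean()))) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_constant_offset_closed_form(self, rng):
        yt = rng.normal(size=30)
        d = 2.75
        s = PairedSeries(yt, yt + d)
        assert mae(s) == pytest.approx(d, abs=1e-12)
        assert mse(s) == pytest.approx(d * d, abs=1e-12)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError):
            r2(PairedSeries([3, 3, 3], [1, 2, 3]))

    def test_agreement_with_oracles_and_sklearn(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 40))
            yt = rng.normal(size=n) * 10
            yp = yt + rng.normal(size=n)
            if np.allclose(yt, yt[0]):
                continue
            s = PairedSeries(yt, yp)
            assert r2(s) == pytest.approx(r2_oracle(yt, yp), abs=1e-12)
            assert r2(s) == pytest.approx(r2_score(yt, yp), abs=1e-10)
            assert mae(s) == pytest.approx(mae_oracle(yt, yp), abs=1e-12)
            assert mse(s) == pytest.approx(mse_oracle(yt, yp), abs=1e-12)


class TestBce:
    def test_confident_correct_is_near_zero(self):
        assert bce(PairedSeries([1.0], [1.0])) < 1e-6

    def test_half_probability(self):
        assert bce(PairedSeries([1.0], [0.5])) == pytest.approx(
            math.log(2), abs=1e-12
        )
        yt = np.array([0, 1, 1, 0], dtype=float)
        assert bce(PairedSeries(yt, np.full(4, 0.5))) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_nonbinary_truth_rejected(self):
        with pytest.raises(ValueError):
            bce(PairedSeries([0.3, 0.7], [0.5, 0.5]))

    def test_agreement_with_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 30))
            yt = rng.integers(0, 2, size=n).astype(float)
            yp = rng.random(size=n)
            got = bce(PairedSeries(yt, yp))
            assert got == pytest.approx(bce_oracle(yt, yp), abs=1e-12)


class TestClassificationMetrics:
    def test_printed_confusion_table(self):
        m = classification_metrics(ConfusionTable(tp=15, fp=2, fn=2, tn=14))
        assert m["accuracy"] == pytest.approx(0.879, abs=5e-4)
        assert m["precision"] == pytest.approx(0.882, abs=5e-4)
        assert m["recall"] == pytest.approx(0.882, abs=5e-4)
        assert m["specificity"] == pytest.approx(0.875, abs=5e-4)
        assert m["f1"] == pytest.approx(0.882, abs=5e-4)

    def test_perfect_diagonal(self):
        m = classification_metrics(ConfusionTable(tp=5, fp=0, fn=0, tn=5))
        assert all(v == 1.0 for v in m.values())

    def test_uniform_counts(self):
        m = classification_metrics(ConfusionTable(tp=1, fp=1, fn=1, tn=1))
        assert all(v == pytest.approx(0.5) for v in m.values())

    def test_count_scale_invariance(self):
        a = classification_metrics(ConfusionTable(tp=3, fp=1, fn=2, tn=4))
        b = classification_metrics(ConfusionTable(tp=30, fp=10, fn=20, tn=40))
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)

    def test_zero_denominator_reported_undefined(self):
        m = classification_metrics(ConfusionTable(tp=0, fp=0, fn=3, tn=5))
        assert m["precision"] is None
        assert m["f1"] is None
        assert m["accuracy"] == pytest.approx(5 / 8)


class TestMaskDice:
    def test_identical_and_empty_masks(self, rng):
        m = rng.random((16, 16)) < 0.4
        assert mask_dice(m, m) == 1.0
        assert mask_dice(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0

    def test_known_overlap(self):
        a = np.zeros((4, 4)); a[:2] = 1   # 8 pixels
        b = np.zeros((4, 4)); b[1:3] = 1  # 8 pixels, 4 shared
        assert mask_dice(a, b) == pytest.approx(0.5)


class TestBoundaryReport:
    def _cohort(self, rng, n=10):
        truths = []
        for _ in range(n):
            s = int(rng.integers(10, 60))
            truths.append(BoundaryInterval(s, s + int(rng.integers(10, 30))))
        return truths

    def test_perfect_predictions(self, rng):
        truths = self._cohort(rng)
        rep = boundary_report(truths, truths).iloc[0]
        assert rep.r2_start == 1.0 and rep.r2_end == 1.0
        assert rep.mae_start == 0 and rep.mse_end == 0
        assert rep.dice == 1.0 and rep.n_absent == 0

    def test_constant_shift_closed_form(self, rng):
        truths = self._cohort(rng)
        preds = [BoundaryInterval(t.start + 5, t.end + 5) for t in truths]
        rep = boundary_report(preds, truths).iloc[0]
        assert rep.mae_start == pytest.approx(5)
        assert rep.mae_end == pytest.approx(5)
        assert rep.mse_start == pytest.approx(25)
        starts_t = [t.start for t in truths]
        assert rep.r2_start == pytest.approx(
            r2_oracle(starts_t, [s + 5 for s in starts_t]), abs=1e-12
        )

    def test_report_columns_match_comparison_layout(self, rng):
        truths = self._cohort(rng)
        rep = boundary_report(truths, truths, [1.0] * 10, [1.0, 2] * 5)
        expected = ["detector", "r2_start", "r2_end", "mae_start", "mae_end",
                    "mse_start", "mse_end", "dice", "r2_volume", "n_absent"]
        assert list(rep.columns) == expected

    def test_absent_predictions_counted_and_excluded(self, rng):
        truths = self._cohort(rng)
        preds = list(truths)
        preds[0] = None
        rep = boundary_report(preds, truths).iloc[0]
        assert rep.n_absent == 1
        assert rep.dice == pytest.approx(9 / 10)
        assert rep.r2_start == 1.0  # regression over the 9 kept patients

    def test_no_valid_predictions_rejected(self, rng):
        truths = self._cohort(rng, n=3)
        with pytest.raises(ValueError):
            boundary_report([None, None, None], truths)
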