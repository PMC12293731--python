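import numpy as np
import pytest

from aaaquant.lstm import (
    BiLstmLabeler,
    LstmConfig,
    ResampleMap,
    encode_input,
    encode_target,
    predict_lstm,
    sequence_loss,
    soft_jaccard,
    train_lstm,
    crossvalidate,
    save_model,
    load_model,
    TrainedModel,
)
from aaaquant.synthetic import CohortSpec, simulate_cohort
from aaaquant.types import AreaSignal, BoundaryInterval


def tiny_cfg(**kw):
    base = dict(hidden_units=16, head_layers=(8,), out_len=64,
                max_epochs=5, patience=50, batch_size=5, seed=0)
    base.update(kw)
    return LstmConfig(**base)


@pytest.fixture(scope="module")
def small_cohort():
    spec = CohortSpec(
        n_patients=30, noise_cv=0.02, peak_ratio_range=(2.0, 3.0),
        n_slices_range=(80, 120), aneurysm_len_range=(20, 40), seed=17,
    )
    return simulate_cohort(spec)


class TestEncoding:
    def test_identity_length_scaled_by_max(self):
        counts = np.arange(1, 201)
        x, mapping = encode_input(AreaSignal("p", counts), out_len=200)
        assert np.allclose(x, counts / 200)
        assert mapping.n == 200 and mapping.out_len == 200

    def test_affine_map_halves_positions(self):
        t = encode_target(BoundaryInterval(100, 199), n=400, out_len=200)
        on = np.flatnonzero(t)
        assert on.min() == 50 and on.max() == 99

    def test_all_zero_signal_guarded(self):
        x, _ = encode_input(AreaSignal("p", np.zeros(50, dtype=int)), out_len=64)
        assert np.all(x == 0)

    def test_target_extremes(self):
        assert encode_target(BoundaryInterval(0, 99), 100, 64).sum() == 64
        assert encode_target(None, 100, 64).sum() == 0

    def test_single_slice_signal_rejected(self):
        with pytest.raises(ValueError):
            encode_input(AreaSignal("p", [5]), out_len=64)

    def test_decode_inverts_encode_within_granularity(self, rng):
        for _ in range(50):
            n = int(rng.integers(50, 400))
            s = int(rng.integers(0, n - 10))
            e = int(rng.integers(s + 5, n))
            t = encode_target(BoundaryInterval(s, e), n, 200)
            if not t.any():
                continue
            on = np.flatnonzero(t)
            dec = ResampleMap(n, 200).decode_run(int(on[0]), int(on[-1]))
            tol = int(np.ceil(n / 200)) + 1
            assert abs(dec.start - s) <= tol
            assert abs(dec.end - e) <= tol


class TestLoss:
    def test_empty_target_convention(self):
        # confident all-negative prediction vs all-zero target: both terms ~0
        logits = np.full((2, 10), -20.0)
        targets = np.zeros((2, 10))
        loss, grad = sequence_loss(logits, targets, jaccard_weight=1.0)
        assert loss < 1e-6
        assert soft_jaccard(np.zeros(5), np.zeros(5)) == 1.0

    def test_perfect_prediction_low_loss(self):
        targets = np.zeros((1, 10))
        targets[0, 3:7] = 1
        logits = np.where(targets > 0, 20.0, -20.0)
        loss, _ = sequence_loss(logits, targets)
        assert loss < 1e-6

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(2, 6))
        targets = (rng.random((2, 6)) > 0.5).astype(float)
        _, grad = sequence_loss(logits, targets, jaccard_weight=0.7)
        eps = 1e-6
        for idx in [(0, 0), (1, 3), (0, 5)]:
            lp = logits.copy(); lp[idx] += eps
            lm = logits.copy(); lm[idx] -= eps
            fd = (sequence_loss(lp, targets, 0.7)[0]
                  - sequence_loss(lm, targets, 0.7)[0]) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, abs=1e-6)


class TestNetworkGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """End-to-end gradient check of the BiLSTM + head on a tiny config."""
        cfg = tiny_cfg(hidden_units=4, head_layers=(3,), out_len=8)
        model = BiLstmLabeler(cfg)
        # float64 params for a clean finite-difference comparison
        model.params = {k: v.astype(np.float64) for k, v in model.params.items()}
        x = rng.random((2, 8)).astype(np.float64)
        targets = (rng.random((2, 8)) > 0.5).astype(float)

        def loss_of(params):
            saved = model.params
            model.params = params
            logits, _ = model.forward(x)
            val, _ = sequence_loss(logits, targets)
            model.params = saved
            return val

        logits, cache = model.forward(x, want_cache=True)
        _, dlogits = sequence_loss(logits, targets)
        grads = model.backward(cache, dlogits)
        eps = 1e-6
        for name in ("l0f_Wx", "l0b_Wh", "l1f_b", "head0_W", "head1_b"):
            p = model.params[name]
            flat_idx = rng.integers(0, p.size, size=3)
            for fi in flat_idx:
                pp = {k: v.copy() for k, v in model.params.items()}
                pp[name].flat[fi] += eps
                pm = {k: v.copy() for k, v in model.params.items()}
                pm[name].flat[fi] -= eps
                fd = (loss_of(pp) - loss_of(pm)) / (2 * eps)
                assert grads[name].flat[fi] == pytest.approx(fd, abs=2e-5), name


class TestTraining:
    def test_overfits_identical_easy_patients(self, small_cohort):
        cohort = [small_cohort[0]] * 10
        cfg = tiny_cfg(max_epochs=120, batch_size=5, lr=0.003)
        trained = train_lstm(cohort, cfg)
        assert trained.log.train_loss.iloc[-1] < 0.1

    def test_same_seed_identical_logs(self, small_cohort):
        cfg = tiny_cfg(max_epochs=4)
        a = train_lstm(small_cohort, cfg)
        b = train_lstm(small_cohort, cfg)
        assert a.log.equals(b.log)

    def test_early_stopping_restores_best_epoch(self, small_cohort):
        cfg = tiny_cfg(max_epochs=30, patience=3)
        trained = train_lstm(small_cohort, cfg)
        assert trained.best_val_loss == trained.log.val_loss.min()
        assert trained.best_epoch == int(
            trained.log.val_loss.idxmin() + 1
        )

    def test_small_cohort_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="2 x batch_size"):
            train_lstm(small_cohort[:5], tiny_cfg(batch_size=10))
        with pytest.raises(ValueError):
            train_lstm([], tiny_cfg())


class TestPrediction:
    @pytest.fixture(scope="class")
    def trained(self, small_cohort):
        return train_lstm(small_cohort, tiny_cfg(max_epochs=60, lr=0.003))

    def test_predicts_interval_overlapping_truth(self, trained, small_cohort):
        from aaaquant.metrics import interval_dice
        dices = []
        for p in small_cohort:
            _, pred = predict_lstm(trained, p.signal)
            dices.append(interval_dice(pred, p.truth))
        assert np.mean(dices) > 0.6  # in-sample sanity on a tiny model

    def test_all_low_probs_absent(self, small_cohort):
        cfg = tiny_cfg()
        untrained = TrainedModel(
            model=BiLstmLabeler(cfg), cfg=LstmConfig(
                **{**cfg.__dict__, "threshold": 0.999}
            ),
            log=None, best_epoch=0, best_val_loss=np.nan,
        )
        probs, pred = predict_lstm(untrained, small_cohort[0].signal)
        assert pred is None
        assert np.all(probs.probs < 0.999)

    def test_threshold_monotonicity(self, trained, small_cohort):
        sig = small_cohort[3].signal
        prev_len = None
        for thr in (0.2, 0.5, 0.8):
            t2 = TrainedModel(
                model=trained.model,
                cfg=LstmConfig(**{**trained.cfg.__dict__, "threshold": thr}),
                log=None, best_epoch=0, best_val_loss=np.nan,
            )
            _, pred = predict_lstm(t2, sig)
            run = 0 if pred is None else len(pred)
            if prev_len is not None:
                assert run <= prev_len
            prev_len = run

    def test_longest_run_selected(self):
        from aaaquant.lstm import _longest_run
        mask = np.zeros(50, dtype=bool)
        mask[5:15] = True   # length 10
        mask[20:50] = True  # length 30
        assert _longest_run(mask) == (20, 49)
        mask2 = np.zeros(10, dtype=bool)
        mask2[1:4] = mask2[6:9] = True  # tie -> earliest
        assert _longest_run(mask2) == (1, 3)


class TestCrossvalidate:
    def test_partition_properties(self, small_cohort):
        cfg = tiny_cfg(max_epochs=2)
        per_fold, pooled, preds = crossvalidate(small_cohort, cfg, k=5)
        assert len(per_fold) == 5
        # folds partition the cohort: every patient exactly once
        assert sorted(preds.patient_id) == sorted(
            p.signal.patient_id for p in small_cohort
        )
        assert preds.groupby("fold").size().tolist() == [6] * 5

    def test_k_below_two_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            crossvalidate(small_cohort, tiny_cfg(), k=1)


class TestPersistence:
    def test_save_load_round_trip(self, small_cohort, tmp_path):
        trained = train_lstm(small_cohort, tiny_cfg(max_epochs=2))
        save_model(trained, tmp_path / "w.npz")
        loaded = load_model(tmp_path / "w.npz")
        p1, _ = predict_lstm(trained, small_cohort[0].signal)
        p2, _ = predict_lstm(loaded, small_cohort[0].signal)
        assert np.array_equal(p1.probs, p2.probs)
        assert loaded.cfg == trained.cfg
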