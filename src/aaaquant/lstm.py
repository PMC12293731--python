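"""Trainable bidirectional-LSTM per-slice aneurysm labeler.

The labeler reads a patient's area signal, resampled to a fixed number of
positions (default 200) spanning the thoracic aorta to the iliac
bifurcation and scaled by the per-sequence maximum, and emits a per-position
probability that the slice is aneurysmal.  The architecture is

* ``num_layers`` stacked bidirectional LSTM layers of ``hidden_units`` each
  (forward and backward hidden states concatenated between layers),
* a shared fully connected ReLU head applied at every position
  (2*hidden_units -> head_layers -> 1 logit),
* a sigmoid output, thresholded at ``threshold``; the longest contiguous
  positive run is mapped back to original slice indices as the predicted
  aneurysm interval.

Training minimizes binary cross-entropy plus a soft-Jaccard term,

    loss = BCE(p, t) + jaccard_weight * (1 - sum(p*t) / sum(p + t - p*t)),

with Adam, patient-level train/validation splitting, and early stopping on
validation loss (the best-validation weights are returned).  The network,
backpropagation through time, and the optimizer are implemented directly
in NumPy; given a config seed, training is bit-reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import AreaSignal, BoundaryInterval

__all__ = [
    "LstmConfig",
    "ResampleMap",
    "SliceProbabilities",
    "BiLstmLabeler",
    "TrainedModel",
    "encode_input",
    "encode_target",
    "soft_jaccard",
    "sequence_loss",
    "train_lstm",
    "predict_lstm",
    "crossvalidate",
    "save_model",
    "load_model",
]

F = np.float32


@dataclass
class LstmConfig:
    """Hyperparameters of the labeler and its training loop."""

    hidden_units: int = 600
    num_layers: int = 2
    head_layers: tuple[int, ...] = (256, 64)
    out_len: int = 200
    threshold: float = 0.5
    lr: float = 0.0003
    batch_size: int = 10
    max_epochs: int = 1000
    patience: int = 50
    jaccard_weight: float = 1.0
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if min(self.hidden_units, self.num_layers, self.out_len,
               self.batch_size, self.max_epochs, self.patience) < 1:
            raise ValueError("size/count hyperparameters must be positive")
        if self.lr <= 0 or self.jaccard_weight < 0:
            raise ValueError("lr must be positive and jaccard_weight >= 0")
        self.head_layers = tuple(int(h) for h in self.head_layers)


def _subseed(seed: int, label: str) -> np.random.SeedSequence:
    """Derive an independent named stream from a base seed."""
    return np.random.SeedSequence((int(seed), zlib.crc32(label.encode())))


# ---------------------------------------------------------------------------
# input/target encoding

@dataclass(frozen=True)
class ResampleMap:
    """Affine relation between model positions and original slice indices."""

    n: int
    out_len: int

    def pos_to_slice(self, pos) -> np.ndarray:
        return np.asarray(pos, dtype=float) * (self.n - 1) / (self.out_len - 1)

    def slice_to_pos(self, idx) -> np.ndarray:
        return np.asarray(idx, dtype=float) * (self.out_len - 1) / (self.n - 1)

    def decode_run(self, p_first: int, p_last: int) -> BoundaryInterval:
        """Map a positive position run back to an inclusive slice interval.

        Uses the run's half-open edges so that encode -> decode round-trips
        an interval to within the resampling granularity.
        """
        scale = (self.n - 1) / (self.out_len - 1)
        start = int(np.ceil((p_first - 0.5) * scale))
        end = int(np.floor((p_last + 0.5) * scale))
        start = max(0, min(start, self.n - 1))
        end = max(start, min(end, self.n - 1))
        return BoundaryInterval(start, end)


@dataclass
class SliceProbabilities:
    probs: np.ndarray
    mapping: ResampleMap

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.size != self.mapping.out_len:
            raise ValueError("probs length must equal out_len")


def encode_input(signal: AreaSignal, out_len: int = 200) -> tuple[np.ndarray, ResampleMap]:
    """Resample a signal to ``out_len`` positions, scaled by its maximum."""
    if signal.n < 2:
        raise ValueError("need at least 2 slices to resample")
    mapping = ResampleMap(n=signal.n, out_len=out_len)
    grid = mapping.pos_to_slice(np.arange(out_len))
    x = np.interp(grid, np.arange(signal.n), signal.counts.astype(float))
    peak = x.max()
    if peak > 0:
        x = x / peak
    return x.astype(F), mapping


def encode_target(
    truth: Optional[BoundaryInterval], n: int, out_len: int = 200
) -> np.ndarray:
    """Binary per-position target: 1 where the mapped slice lies in the interval."""
    mapping = ResampleMap(n=n, out_len=out_len)
    if truth is None:
        return np.zeros(out_len, dtype=F)
    truth.validate_for(n)
    mapped = mapping.pos_to_slice(np.arange(out_len))
    return ((mapped >= truth.start) & (mapped <= truth.end)).astype(F)


# ---------------------------------------------------------------------------
# network

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(F)


class BiLstmLabeler:
    """Stacked bidirectional LSTM + shared per-position FC head, in NumPy."""

    def __init__(self, cfg: LstmConfig):
        self.cfg = cfg
        rng = np.random.default_rng(_subseed(cfg.seed, "init"))
        H = cfg.hidden_units
        self.params: dict[str, np.ndarray] = {}
        for layer in range(cfg.num_layers):
            d_in = 1 if layer == 0 else 2 * H
            for direction in ("f", "b"):
                key = f"l{layer}{direction}"
                self.params[f"{key}_Wx"] = _glorot(rng, d_in, 4 * H)
                self.params[f"{key}_Wh"] = _glorot(rng, H, 4 * H)
                bias = np.zeros(4 * H, dtype=F)
                bias[H:2 * H] = 1.0  # forget-gate bias
                self.params[f"{key}_b"] = bias
        widths = (2 * H, *cfg.head_layers, 1)
        for i in range(len(widths) - 1):
            self.params[f"head{i}_W"] = _glorot(rng, widths[i], widths[i + 1])
            self.params[f"head{i}_b"] = np.zeros(widths[i + 1], dtype=F)
        self.n_head = len(widths) - 1

    # -- forward -----------------------------------------------------------

    def _lstm_dir(self, x: np.ndarray, key: str):
        """One direction over x (T, B, D); returns hidden states and cache."""
        T, B, _ = x.shape
        H = self.cfg.hidden_units
        Wx, Wh, b = (self.params[f"{key}_{p}"] for p in ("Wx", "Wh", "b"))
        xp = x.reshape(T * B, -1) @ Wx
        xp = xp.reshape(T, B, 4 * H) + b
        hs = np.zeros((T, B, H), dtype=F)
        cs = np.zeros((T, B, H), dtype=F)
        gates = np.zeros((T, B, 4 * H), dtype=F)
        h = np.zeros((B, H), dtype=F)
        c = np.zeros((B, H), dtype=F)
        for t in range(T):
            z = xp[t] + h @ Wh
            i_g = _sigmoid(z[:, :H])
            f_g = _sigmoid(z[:, H:2 * H])
            g_g = np.tanh(z[:, 2 * H:3 * H])
            o_g = _sigmoid(z[:, 3 * H:])
            c = f_g * c + i_g * g_g
            h = o_g * np.tanh(c)
            gates[t, :, :H] = i_g
            gates[t, :, H:2 * H] = f_g
            gates[t, :, 2 * H:3 * H] = g_g
            gates[t, :, 3 * H:] = o_g
            cs[t] = c
            hs[t] = h
        return hs, (x, gates, cs, hs)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x (B, T) -> logits (B, T); optionally keep the backprop cache."""
        B, T = x.shape
        inp = np.ascontiguousarray(x.T, dtype=F)[:, :, None]  # (T, B, 1)
        cache: dict = {"layers": []}
        for layer in range(self.cfg.num_layers):
            hf, cf = self._lstm_dir(inp, f"l{layer}f")
            hb_rev, cb = self._lstm_dir(inp[::-1], f"l{layer}b")
            hb = hb_rev[::-1]
            out = np.concatenate([hf, hb], axis=2)
            cache["layers"].append((cf, cb))
            inp = out
        feat = inp.reshape(T * B, -1)
        acts = [feat]
        for i in range(self.n_head):
            z = feat @ self.params[f"head{i}_W"] + self.params[f"head{i}_b"]
            feat = np.maximum(z, 0) if i < self.n_head - 1 else z
            acts.append(feat)
        logits = feat.reshape(T, B).T  # (B, T)
        if not want_cache:
            return logits, None
        cache["acts"] = acts
        cache["shape"] = (B, T)
        return logits, cache

    # -- backward ----------------------------------------------------------

    def _lstm_dir_back(self, cache, dh_out: np.ndarray, key: str):
        x, gates, cs, hs = cache
        T, B, D = x.shape
        H = self.cfg.hidden_units
        Wx, Wh = self.params[f"{key}_Wx"], self.params[f"{key}_Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H, dtype=F)
        dz_all = np.zeros((T, B, 4 * H), dtype=F)
        dh_next = np.zeros((B, H), dtype=F)
        dc_next = np.zeros((B, H), dtype=F)
        for t in range(T - 1, -1, -1):
            i_g = gates[t, :, :H]
            f_g = gates[t, :, H:2 * H]
            g_g = gates[t, :, 2 * H:3 * H]
            o_g = gates[t, :, 3 * H:]
            c = cs[t]
            tanh_c = np.tanh(c)
            dh = dh_out[t] + dh_next
            do = dh * tanh_c
            dc = dh * o_g * (1 - tanh_c ** 2) + dc_next
            c_prev = cs[t - 1] if t > 0 else np.zeros_like(c)
            di = dc * g_g
            df = dc * c_prev
            dg = dc * i_g
            dc_next = dc * f_g
            dz = dz_all[t]
            dz[:, :H] = di * i_g * (1 - i_g)
            dz[:, H:2 * H] = df * f_g * (1 - f_g)
            dz[:, 2 * H:3 * H] = dg * (1 - g_g ** 2)
            dz[:, 3 * H:] = do * o_g * (1 - o_g)
            h_prev = hs[t - 1] if t > 0 else np.zeros((B, H), dtype=F)
            dWh += h_prev.T @ dz
            dh_next = dz @ Wh.T
        flat = dz_all.reshape(T * B, 4 * H)
        dWx = x.reshape(T * B, D).T @ flat
        db = flat.sum(axis=0)
        dx = (flat @ Wx.T).reshape(T, B, D)
        return dx, {f"{key}_Wx": dWx, f"{key}_Wh": dWh, f"{key}_b": db}

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        B, T = cache["shape"]
        grads: dict[str, np.ndarray] = {}
        acts = cache["acts"]
        dfeat = np.ascontiguousarray(dlogits.T, dtype=F).reshape(T * B, 1)
        for i in range(self.n_head - 1, -1, -1):
            if i < self.n_head - 1:  # ReLU on hidden head layers
                dfeat = dfeat * (acts[i + 1] > 0)
            grads[f"head{i}_W"] = acts[i].T @ dfeat
            grads[f"head{i}_b"] = dfeat.sum(axis=0)
            dfeat = dfeat @ self.params[f"head{i}_W"].T
        H = self.cfg.hidden_units
        dh = dfeat.reshape(T, B, 2 * H)
        for layer in range(self.cfg.num_layers - 1, -1, -1):
            cf, cb = cache["layers"][layer]
            dxf, gf = self._lstm_dir_back(cf, dh[:, :, :H], f"l{layer}f")
            dxb, gb = self._lstm_dir_back(cb, dh[::-1, :, H:], f"l{layer}b")
            grads.update(gf)
            grads.update(gb)
            dh = dxf + dxb[::-1]
        return grads


# ---------------------------------------------------------------------------
# loss

#: additive smoothing of the soft-Jaccard ratio; negligible against real
#: batch sums, and makes an empty-target/empty-prediction batch score 1
JACCARD_SMOOTH = 1.0


def soft_jaccard(probs: np.ndarray, targets: np.ndarray,
                 smooth: float = JACCARD_SMOOTH) -> float:
    """Differentiable Jaccard surrogate (sum(p*t)+s) / (sum(p+t-p*t)+s)."""
    inter = float(np.sum(probs * targets))
    union = float(np.sum(probs + targets - probs * targets))
    return (inter + smooth) / (union + smooth)


def sequence_loss(
    logits: np.ndarray, targets: np.ndarray, jaccard_weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """BCE + jaccard_weight*(1 - softJaccard) and its gradient w.r.t. logits."""
    probs = _sigmoid(logits.astype(np.float64))
    t = targets.astype(np.float64)
    n = probs.size
    eps = 1e-12
    bce_val = -np.mean(t * np.log(probs + eps) + (1 - t) * np.log(1 - probs + eps))
    dlogits = (probs - t) / n
    s = JACCARD_SMOOTH
    inter = np.sum(probs * t) + s
    union = np.sum(probs + t - probs * t) + s
    jac = inter / union
    djac_dp = (t * union - inter * (1 - t)) / union ** 2
    dlogits += -jaccard_weight * djac_dp * probs * (1 - probs)
    loss = float(bce_val + jaccard_weight * (1.0 - jac))
    return loss, dlogits.astype(F)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= (lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)).astype(F)


# ---------------------------------------------------------------------------
# training / prediction

@dataclass
class TrainedModel:
    model: BiLstmLabeler
    cfg: LstmConfig
    log: pd.DataFrame
    best_epoch: int
    best_val_loss: float


def _as_pairs(cohort) -> list[tuple[AreaSignal, Optional[BoundaryInterval]]]:
    pairs = []
    for item in cohort:
        if isinstance(item, tuple):
            pairs.append(item)
        else:  # SyntheticPatient-like
            pairs.append((item.signal, item.truth))
    return pairs


def _encode_cohort(pairs, out_len: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([encode_input(sig, out_len)[0] for sig, _ in pairs])
    Y = np.stack([encode_target(tr, sig.n, out_len) for sig, tr in pairs])
    return X, Y


def _dataset_loss(model: BiLstmLabeler, X, Y, jw: float, batch: int) -> float:
    total, count = 0.0, 0
    for lo in range(0, X.shape[0], batch):
        logits, _ = model.forward(X[lo:lo + batch])
        loss, _ = sequence_loss(logits, Y[lo:lo + batch], jw)
        total += loss * (min(lo + batch, X.shape[0]) - lo)
        count += min(lo + batch, X.shape[0]) - lo
    return total / count


def train_lstm(cohort, cfg: LstmConfig) -> TrainedModel:
    """Train the labeler with early stopping; returns the best-validation weights.

    The cohort is split at patient level into train/validation using
    ``val_fraction`` and randomness derived from ``cfg.seed``; two runs with
    the same cohort and config produce identical training logs.
    """
    pairs = _as_pairs(cohort)
    if not pairs:
        raise ValueError("empty cohort")
    if len(pairs) < 2 * cfg.batch_size:
        raise ValueError(
            f"need at least {2 * cfg.batch_size} patients "
            f"(2 x batch_size), got {len(pairs)}"
        )
    X, Y = _encode_cohort(pairs, cfg.out_len)
    split_rng = np.random.default_rng(_subseed(cfg.seed, "split"))
    perm = split_rng.permutation(len(pairs))
    n_val = max(1, int(round(cfg.val_fraction * len(pairs))))
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    model = BiLstmLabeler(cfg)
    opt = _Adam(model.params, cfg.lr)
    shuffle_rng = np.random.default_rng(_subseed(cfg.seed, "shuffle"))

    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    best_epoch = 0
    rows = []
    since_best = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = shuffle_rng.permutation(train_idx)
        epoch_loss, seen = 0.0, 0
        for lo in range(0, order.size, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            logits, cache = model.forward(X[idx], want_cache=True)
            loss, dlogits = sequence_loss(logits, Y[idx], cfg.jaccard_weight)
            grads = model.backward(cache, dlogits)
            opt.step(model.params, grads)
            epoch_loss += loss * idx.size
            seen += idx.size
        train_loss = epoch_loss / seen
        val_loss = _dataset_loss(
            model, X[val_idx], Y[val_idx], cfg.jaccard_weight, cfg.batch_size
        )
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.params = best_params
    return TrainedModel(
        model=model,
        cfg=cfg,
        log=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
    )


def _longest_run(mask: np.ndarray) -> Optional[tuple[int, int]]:
    """First and last index of the longest True run (earliest on ties)."""
    if not mask.any():
        return None
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2] - 1
    best = int(np.argmax(ends - starts))
    return int(starts[best]), int(ends[best])


def predict_lstm(
    trained: TrainedModel, signal: AreaSignal
) -> tuple[SliceProbabilities, Optional[BoundaryInterval]]:
    """Per-position probabilities and the decoded aneurysm interval (or None)."""
    cfg = trained.cfg
    x, mapping = encode_input(signal, cfg.out_len)
    logits, _ = trained.model.forward(x[None, :])
    probs = _sigmoid(logits.astype(np.float64))[0]
    run = _longest_run(probs > cfg.threshold)
    slice_probs = SliceProbabilities(probs=probs, mapping=mapping)
    if run is None:
        return slice_probs, None
    return slice_probs, mapping.decode_run(*run)


def crossvalidate(cohort, cfg: LstmConfig, k: int = 5):
    """k-fold cross-validation with strict patient-level separation.

    Returns ``(per_fold, pooled, predictions)`` where *per_fold* and
    *pooled* are metric tables and *predictions* is one row per patient
    (fold, truth, prediction, Dice, surrogate volumes over truth and
    predicted intervals).
    """
    from .metrics import boundary_report, interval_dice
    from .volumetrics import surrogate_volume

    pairs = _as_pairs(cohort)
    if k < 2:
        raise ValueError("k must be at least 2 (need a held-out set)")
    if len(pairs) < k:
        raise ValueError(f"need at least {k} patients for {k}-fold CV")
    fold_rng = np.random.default_rng(_subseed(cfg.seed, "folds"))
    perm = fold_rng.permutation(len(pairs))
    folds = np.array_split(perm, k)

    rows = []
    fold_tables = []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        fold_cfg = LstmConfig(**{**asdict(cfg), "seed": cfg.seed + 1000 * (fi + 1)})
        trained = train_lstm([pairs[i] for i in train_idx], fold_cfg)
        preds, truths, vp, vt = [], [], [], []
        for i in test_idx:
            sig, truth = pairs[i]
            if truth is None:
                continue
            _, pred = predict_lstm(trained, sig)
            preds.append(pred)
            truths.append(truth)
            vt.append(surrogate_volume(sig, truth))
            vp.append(surrogate_volume(sig, pred) if pred else np.nan)
            rows.append({
                "fold": fi,
                "patient_id": sig.patient_id,
                "n_slices": sig.n,
                "true_start": truth.start, "true_end": truth.end,
                "pred_start": pred.start if pred else -1,
                "pred_end": pred.end if pred else -1,
                "dice": interval_dice(pred, truth),
                "volume_true": vt[-1], "volume_pred": vp[-1],
            })
        table = boundary_report(preds, truths, vp, vt, detector=f"fold{fi}")
        fold_tables.append(table)
    per_fold = pd.concat(fold_tables, ignore_index=True)
    predictions = pd.DataFrame(rows)

    pooled_preds = [
        None if r.pred_start < 0 else BoundaryInterval(r.pred_start, r.pred_end)
        for r in predictions.itertuples()
    ]
    pooled_truths = [
        BoundaryInterval(r.true_start, r.true_end) for r in predictions.itertuples()
    ]
    pooled = boundary_report(
        pooled_preds, pooled_truths,
        predictions.volume_pred.tolist(), predictions.volume_true.tolist(),
        detector="pooled",
    )
    return per_fold, pooled, predictions


# ---------------------------------------------------------------------------
# persistence

def save_model(trained: TrainedModel, path: str | Path) -> None:
    """Save weights + config as a compressed npz with an embedded JSON config."""
    path = Path(path)
    cfg_json = json.dumps(asdict(trained.cfg))
    np.savez_compressed(
        path,
        __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
        **trained.model.params,
    )


def load_model(path: str | Path) -> TrainedModel:
    with np.load(Path(path)) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["head_layers"] = tuple(cfg_dict["head_layers"])
        cfg = LstmConfig(**cfg_dict)
        model = BiLstmLabeler(cfg)
        for k in model.params:
            model.params[k] = data[k]
    return TrainedModel(
        model=model, cfg=cfg, log=pd.DataFrame(), best_epoch=-1,
        best_val_loss=float("nan"),
    )
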