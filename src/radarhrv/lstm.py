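"""Bidirectional LSTM sequence labeller for heart-sound segmentation.

Architecture: two bidirectional LSTM layers (400 and 200 hidden units per
direction in the full configuration), dropout 0.2 after each recurrent
layer, then a fully-connected layer with softmax over the four cardiac
states. Training runs 50 epochs with batch size 64, initial learning rate
0.001 dropping by a factor of 10 every 20 epochs.

The network, backpropagation-through-time and the Adam optimiser are
implemented directly on numpy arrays. With a fixed seed and single-threaded
BLAS the whole training run is bit-reproducible. A reduced "desk"
configuration (64/32 units, 10 epochs) covers CPU-bound test runs.

The raw argmax path need not respect the cardiac cycle; a post-processing
decoder projects the per-frame posteriors onto the nearest legal cyclic
path (first-order Viterbi with self/advance transitions), which removes
isolated label flips and defines unambiguous S1 onsets.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import beats as beats_mod
from .errors import InvalidInputError
from .types import N_STATES, BeatList, CardiacState, FeatureTrack, StateSequence

#: Typical sojourn lengths in seconds used by the cycle-repair decoder's
#: transition prior (S1, SYS, S2, DIA at rest).
TYPICAL_DURATIONS_S = (0.10, 0.21, 0.08, 0.55)


@dataclass(frozen=True)
class LstmConfig:
    """Hyperparameters; defaults follow the full-scale configuration."""

    hidden_units: tuple[int, int] = (400, 200)
    dropout: float = 0.2
    epochs: int = 50
    batch_size: int = 64
    lr0: float = 1e-3
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 20
    seed: int = 0
    window_s: float = 10.0
    class_weighting: bool = True

    def __post_init__(self):
        if any(h <= 0 for h in self.hidden_units):
            raise InvalidInputError("hidden_units must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise InvalidInputError("dropout must be in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise InvalidInputError("epochs and batch_size must be >= 1")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate in 1-based epoch: lr0 * factor^((epoch-1)//every)."""
        return self.lr0 * self.lr_decay_factor ** ((epoch - 1) // self.lr_decay_every)

    @classmethod
    def desk(cls, **kw) -> "LstmConfig":
        """Reduced configuration for CPU-bound runs: 64/32 units, 10 epochs.

        Training windows are shortened to 2.5 s so that small simulated
        cohorts still provide enough batches per epoch for the fixed
        batch size of 64.
        """
        kw.setdefault("hidden_units", (64, 32))
        kw.setdefault("epochs", 10)
        kw.setdefault("window_s", 2.5)
        return cls(**kw)


# ---------------------------------------------------------------------------
# LSTM primitives (gate order: input, forget, cell, output)
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _init_direction(rng: np.random.Generator, d_in: int, h: int) -> dict:
    """Glorot-uniform weights, forget-gate bias 1."""
    def glorot(fan_in, fan_out, shape):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape).astype(np.float32)

    b = np.zeros(4 * h, dtype=np.float32)
    b[h:2 * h] = 1.0
    return {"W": glorot(d_in, 4 * h, (d_in, 4 * h)),
            "U": glorot(h, 4 * h, (h, 4 * h)),
            "b": b}


def _lstm_forward(x: np.ndarray, p: dict) -> tuple[np.ndarray, dict]:
    """Unidirectional pass over (B, T, D); returns hidden states and caches."""
    B, T, _ = x.shape
    h_dim = p["U"].shape[0]
    hs = np.zeros((B, T + 1, h_dim), dtype=np.float32)
    cs = np.zeros((B, T + 1, h_dim), dtype=np.float32)
    gates = np.zeros((B, T, 4 * h_dim), dtype=np.float32)
    xw = x @ p["W"] + p["b"]  # precompute the input projections
    for t in range(T):
        z = xw[:, t] + hs[:, t] @ p["U"]
        i = _sigmoid(z[:, :h_dim])
        f = _sigmoid(z[:, h_dim:2 * h_dim])
        g = np.tanh(z[:, 2 * h_dim:3 * h_dim])
        o = _sigmoid(z[:, 3 * h_dim:])
        c = f * cs[:, t] + i * g
        hs[:, t + 1] = o * np.tanh(c)
        cs[:, t + 1] = c
        gates[:, t, :h_dim] = i
        gates[:, t, h_dim:2 * h_dim] = f
        gates[:, t, 2 * h_dim:3 * h_dim] = g
        gates[:, t, 3 * h_dim:] = o
    cache = {"x": x, "hs": hs, "cs": cs, "gates": gates, "p": p}
    return hs[:, 1:], cache


def _lstm_backward(dh_out: np.ndarray, cache: dict) -> tuple[np.ndarray, dict]:
    """BPTT for one direction; returns input gradient and parameter grads."""
    x, hs, cs, gates, p = (cache["x"], cache["hs"], cache["cs"],
                           cache["gates"], cache["p"])
    B, T, _ = x.shape
    h_dim = p["U"].shape[0]
    dW = np.zeros_like(p["W"])
    dU = np.zeros_like(p["U"])
    db = np.zeros_like(p["b"])
    dx = np.zeros_like(x)
    dh_next = np.zeros((B, h_dim), dtype=np.float32)
    dc_next = np.zeros((B, h_dim), dtype=np.float32)
    for t in range(T - 1, -1, -1):
        i = gates[:, t, :h_dim]
        f = gates[:, t, h_dim:2 * h_dim]
        g = gates[:, t, 2 * h_dim:3 * h_dim]
        o = gates[:, t, 3 * h_dim:]
        c = cs[:, t + 1]
        tanh_c = np.tanh(c)
        dh = dh_out[:, t] + dh_next
        dc = dh * o * (1.0 - tanh_c ** 2) + dc_next
        dz = np.empty((B, 4 * h_dim), dtype=np.float32)
        dz[:, :h_dim] = dc * g * i * (1.0 - i)
        dz[:, h_dim:2 * h_dim] = dc * cs[:, t] * f * (1.0 - f)
        dz[:, 2 * h_dim:3 * h_dim] = dc * i * (1.0 - g ** 2)
        dz[:, 3 * h_dim:] = dh * tanh_c * o * (1.0 - o)
        dW += x[:, t].T @ dz
        dU += hs[:, t].T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ p["W"].T
        dh_next = dz @ p["U"].T
        dc_next = dc * f
    return dx, {"W": dW, "U": dU, "b": db}


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray],
             lr: float) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedSegmenter:
    """Learned parameters, the config used, and the per-epoch loss history."""

    layers: list[dict]            # per layer: {"fwd": params, "bwd": params}
    dense_w: np.ndarray
    dense_b: np.ndarray
    config: LstmConfig
    history: list[float] = field(default_factory=list)
    class_weights: np.ndarray | None = None
    n_features: int = 4
    feature_fs: float = 50.0

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """(B, T, D) -> class probabilities (B, T, 4) [+ caches if training]."""
        caches = []
        out = x.astype(np.float32)
        for layer in self.layers:
            h_f, cache_f = _lstm_forward(out, layer["fwd"])
            h_b, cache_b = _lstm_forward(out[:, ::-1], layer["bwd"])
            h = np.concatenate([h_f, h_b[:, ::-1]], axis=2)
            mask = None
            if train and self.config.dropout > 0:
                keep = 1.0 - self.config.dropout
                mask = (rng.random(h.shape) < keep).astype(np.float32) / keep
                h = h * mask
            caches.append((cache_f, cache_b, mask))
            out = h
        logits = out @ self.dense_w + self.dense_b
        logits -= logits.max(axis=2, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=2, keepdims=True)
        if train:
            return probs, (caches, out)
        return probs

    def save(self, path) -> None:
        arrays = {"dense_w": self.dense_w, "dense_b": self.dense_b,
                  "history": np.array(self.history),
                  "feature_fs": np.array(self.feature_fs)}
        if self.class_weights is not None:
            arrays["class_weights"] = self.class_weights
        for li, layer in enumerate(self.layers):
            for dname in ("fwd", "bwd"):
                for k, v in layer[dname].items():
                    arrays[f"layer{li}_{dname}_{k}"] = v
        import json
        np.savez(path, **arrays)
        base = str(path)[:-4] if str(path).endswith(".npz") else str(path)
        with open(base + ".json", "w") as fh:
            json.dump({f: getattr(self.config, f) for f in
                       ("hidden_units", "dropout", "epochs", "batch_size",
                        "lr0", "lr_decay_factor", "lr_decay_every", "seed",
                        "window_s", "class_weighting")}, fh)

    @classmethod
    def load(cls, path) -> "TrainedSegmenter":
        import json
        data = np.load(str(path) if str(path).endswith(".npz")
                       else str(path) + ".npz")
        base = str(path)[:-4] if str(path).endswith(".npz") else str(path)
        with open(base + ".json") as fh:
            cfg_d = json.load(fh)
        cfg_d["hidden_units"] = tuple(cfg_d["hidden_units"])
        cfg = LstmConfig(**cfg_d)
        layers = []
        for li in range(len(cfg.hidden_units)):
            layers.append({d: {k: data[f"layer{li}_{d}_{k}"]
                               for k in ("W", "U", "b")}
                           for d in ("fwd", "bwd")})
        cw = data["class_weights"] if "class_weights" in data else None
        return cls(layers=layers, dense_w=data["dense_w"],
                   dense_b=data["dense_b"], config=cfg,
                   history=list(data["history"]), class_weights=cw,
                   n_features=layers[0]["fwd"]["W"].shape[0],
                   feature_fs=float(data["feature_fs"]))


def _init_network(config: LstmConfig, n_features: int, feature_fs: float,
                  rng: np.random.Generator) -> TrainedSegmenter:
    layers = []
    d_in = n_features
    for h in config.hidden_units:
        layers.append({"fwd": _init_direction(rng, d_in, h),
                       "bwd": _init_direction(rng, d_in, h)})
        d_in = 2 * h
    lim = np.sqrt(6.0 / (d_in + N_STATES))
    dense_w = rng.uniform(-lim, lim, size=(d_in, N_STATES)).astype(np.float32)
    dense_b = np.zeros(N_STATES, dtype=np.float32)
    return TrainedSegmenter(layers=layers, dense_w=dense_w, dense_b=dense_b,
                            config=config, n_features=n_features,
                            feature_fs=feature_fs)


def _collect_params(net: TrainedSegmenter) -> list[np.ndarray]:
    params = []
    for layer in net.layers:
        for d in ("fwd", "bwd"):
            params.extend(layer[d][k] for k in ("W", "U", "b"))
    params.extend([net.dense_w, net.dense_b])
    return params


def _chunk_sequences(tracks: list[FeatureTrack], labels: list[StateSequence],
                     window_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Cut each (track, labels) pair into fixed-length windows for batching."""
    xs, ys = [], []
    for tr, lb in zip(tracks, labels):
        if tr.n_frames != len(lb):
            raise InvalidInputError(
                f"track has {tr.n_frames} frames but labels {len(lb)}")
        w = int(round(window_s * tr.feature_fs))
        for s0 in range(0, tr.n_frames - w + 1, w):
            xs.append(tr.features[s0:s0 + w])
            ys.append(lb.states[s0:s0 + w])
    if not xs:
        raise InvalidInputError("no full window of training data")
    return (np.stack(xs).astype(np.float32), np.stack(ys))


def train_lstm(train_tracks: list[FeatureTrack],
               train_labels: list[StateSequence],
               config: LstmConfig) -> TrainedSegmenter:
    """Train the bidirectional LSTM with Adam and the stepped learning rate.

    Deterministic given ``config.seed`` (initialisation, shuffling, and
    dropout masks all draw from one seeded generator) under single-threaded
    BLAS. The history records the mean weighted cross-entropy per epoch.
    """
    x, y = _chunk_sequences(train_tracks, train_labels, config.window_s)
    n_feat = x.shape[2]
    rng = np.random.default_rng(config.seed)
    net = _init_network(config, n_feat, train_tracks[0].feature_fs, rng)
    if config.class_weighting:
        counts = np.bincount(y.ravel(), minlength=N_STATES).astype(float)
        counts = np.maximum(counts, 1.0)
        weights = counts.sum() / (N_STATES * counts)
    else:
        weights = np.ones(N_STATES)
    weights = weights.astype(np.float32)
    net.class_weights = weights
    params = _collect_params(net)
    adam = _Adam(params)
    n = len(x)
    for epoch in range(1, config.epochs + 1):
        lr = config.lr_at_epoch(epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_frames_total = 0
        for b0 in range(0, n, config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            xb, yb = x[idx], y[idx]
            probs, (caches, last_h) = net.forward(xb, train=True, rng=rng)
            B, T, _ = probs.shape
            w_frame = weights[yb]  # (B, T)
            onehot = np.eye(N_STATES, dtype=np.float32)[yb]
            logp = np.log(np.maximum(probs, 1e-12))
            loss = -(w_frame * (onehot * logp).sum(axis=2)).sum() / w_frame.sum()
            epoch_loss += float(loss) * B * T
            n_frames_total += B * T
            # gradient of the weighted cross-entropy wrt logits
            dlogits = (probs - onehot) * w_frame[..., None] / w_frame.sum()
            d_dense_w = np.tensordot(last_h, dlogits, axes=([0, 1], [0, 1]))
            d_dense_b = dlogits.sum(axis=(0, 1))
            dh = dlogits @ net.dense_w.T
            grads_layers = []
            for layer, (cache_f, cache_b, mask) in zip(net.layers[::-1],
                                                       caches[::-1]):
                if mask is not None:
                    dh = dh * mask
                h_dim = layer["fwd"]["U"].shape[0]
                dx_f, g_f = _lstm_backward(dh[:, :, :h_dim], cache_f)
                dx_b, g_b = _lstm_backward(dh[:, ::-1, h_dim:], cache_b)
                grads_layers.append((g_f, g_b))
                dh = dx_f + dx_b[:, ::-1]
            grads = []
            for g_f, g_b in grads_layers[::-1]:
                for g in (g_f, g_b):
                    grads.extend(g[k] for k in ("W", "U", "b"))
            grads.extend([d_dense_w.astype(np.float32), d_dense_b])
            adam.step(params, grads, lr)
        net.history.append(epoch_loss / n_frames_total)
    return net


# ---------------------------------------------------------------------------
# Prediction and cycle repair
# ---------------------------------------------------------------------------

def repair_cycle(log_probs: np.ndarray, feature_fs: float,
                 typical_durations_s=TYPICAL_DURATIONS_S) -> np.ndarray:
    """Project per-frame log posteriors onto the nearest legal cyclic path.

    First-order Viterbi over the four states where a frame may either stay
    in its state or advance to the cyclic successor; the advance probability
    is 1/expected sojourn frames, so isolated label flips are absorbed
    rather than spawning spurious cycles.
    """
    T = log_probs.shape[0]
    dur_frames = np.maximum(np.array(typical_durations_s) * feature_fs, 1.5)
    p_adv = 1.0 / dur_frames
    log_stay = np.log(1.0 - p_adv)
    log_adv = np.log(p_adv)
    nxt = np.array([1, 2, 3, 0])
    delta = log_probs[0] - np.log(N_STATES)
    bp = np.zeros((T, N_STATES), dtype=np.int8)
    for t in range(1, T):
        stay = delta + log_stay
        adv = np.full(N_STATES, -np.inf)
        adv[nxt] = delta + log_adv
        new = np.where(stay >= adv, stay, adv)
        bp[t] = np.where(stay >= adv, np.arange(N_STATES),
                         np.argsort(nxt)[np.arange(N_STATES)])
        delta = new + log_probs[t]
    states = np.empty(T, dtype=int)
    states[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        states[t - 1] = bp[t, states[t]]
    return states


def predict_states(net: TrainedSegmenter, track: FeatureTrack,
                   ) -> tuple[np.ndarray, StateSequence]:
    """Per-frame class probabilities plus the cycle-repaired state sequence."""
    if track.features.shape[1] != net.n_features:
        raise InvalidInputError(
            f"track has {track.features.shape[1]} features, "
            f"model expects {net.n_features}")
    probs = net.forward(track.features[None])[0]
    states = repair_cycle(np.log(np.maximum(probs, 1e-12)),
                          track.feature_fs)
    return probs, StateSequence(states=states, feature_fs=track.feature_fs,
                                t0=track.t0)


def losocv_evaluate(subjects: list[tuple[FeatureTrack, StateSequence, BeatList]],
                    config: LstmConfig,
                    tolerance: float = beats_mod.DEFAULT_TOLERANCE,
                    ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Leave-one-subject-out cross-validation of the LSTM segmenter.

    Each subject is held out once; the model trains on all others and the
    held-out subject's detected beats are scored against its reference
    beats at the given tolerance. Returns the per-subject score table and
    the arithmetic-mean row.
    """
    if len(subjects) < 3:
        raise InvalidInputError(f"LOSOCV needs >= 3 subjects, got {len(subjects)}")
    rows = []
    for k, (track, _labels, ref) in enumerate(subjects):
        rest = [s for i, s in enumerate(subjects) if i != k]
        net = train_lstm([s[0] for s in rest], [s[1] for s in rest],
                         replace(config, seed=config.seed + k))
        _, seq = predict_states(net, track)
        det = beats_mod.states_to_beats(seq)
        m = beats_mod.match_beats(ref, det, tolerance=tolerance)
        row = {"subject": k, **beats_mod.scores(m),
               "tp": m.tp, "fp": m.fp, "fn": m.fn}
        rows.append(row)
    table = pd.DataFrame(rows).set_index("subject")
    mean = {c: float(table[c].mean())
            for c in ("sensitivity", "precision", "f1", "accuracy")}
    return table, mean
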