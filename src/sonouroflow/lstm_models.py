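"""Sequence models for acoustic uroflowmetry.

Two small LSTM networks built from the same single-layer cell:

* a **sequence-to-sequence regressor** (hidden size 5, one-neuron dense
  head) that maps per-frame (loudness, roughness) features to flowrate in
  mL/s, trained with Adam on mean-squared error (batch 3, 40 epochs);
* a **sequence-to-label classifier** (hidden size 50, dense 3-class softmax
  head on the last hidden state) that maps a normalized length-246 flow
  curve to the bladder-emptying pattern {A, B, C}, trained with Adam on
  cross-entropy (batch 3, 500 epochs by default).

The cell follows the standard gated recurrence

    f_t = sigma(W_f [h_{t-1}, x_t] + b_f)
    i_t = sigma(W_i [h_{t-1}, x_t] + b_i)
    C~_t = tanh(W_c [h_{t-1}, x_t] + b_c)
    c_t = f_t * c_{t-1} + i_t * C~_t
    o_t = sigma(W_o [h_{t-1}, x_t] + b_o)
    h_t = o_t * tanh(c_t)

with backpropagation through time written out explicitly; the inner loops
are numba-compiled.  Everything is deterministic under a fixed seed
(single-threaded reference path).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .psychoacoustics import FeatureSeries
from .uroflow import LABELS, FlowrateCurve
from .dataset import NormalizedSequence, TrainingSet, RESAMPLE_LENGTH

# --------------------------------------------------------------------------
# Parameters and the single-cell step
# --------------------------------------------------------------------------


@dataclass
class LSTMParams:
    """Gate weights of one LSTM layer.

    Each ``W_*`` acts on the concatenation [h_{t-1}, x_t] and has shape
    (hidden_size, hidden_size + input_size); biases have shape
    (hidden_size,).
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        h, hi = self.W_f.shape
        for w in (self.W_i, self.W_c, self.W_o):
            if w.shape != (h, hi):
                raise ValueError("gate weight shapes inconsistent")
        for b in (self.b_f, self.b_i, self.b_c, self.b_o):
            if b.shape != (h,):
                raise ValueError("gate bias shapes inconsistent")
        for a in (self.W_f, self.W_i, self.W_c, self.W_o,
                  self.b_f, self.b_i, self.b_c, self.b_o):
            if not np.all(np.isfinite(a)):
                raise ValueError("parameters must be finite")

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]


@dataclass
class CellState:
    """Hidden output h_t and memory cell c_t of one LSTM step."""

    h: np.ndarray
    c: np.ndarray


def init_lstm_params(input_size: int, hidden_size: int, rng: np.random.Generator) -> LSTMParams:
    """Seeded uniform Glorot-style initialization.

    The forget-gate bias starts at 1 (the mainstream-framework default):
    with long sequences a zero forget bias lets early cell state decay so
    fast that gradients vanish and training stalls on some seeds.  Other
    biases start at zero.
    """
    fan_in = hidden_size + input_size
    lim = np.sqrt(6.0 / (fan_in + hidden_size))

    def w():
        return rng.uniform(-lim, lim, (hidden_size, fan_in))

    z = np.zeros(hidden_size)
    return LSTMParams(w(), w(), w(), w(), np.ones(hidden_size), z.copy(), z.copy(), z.copy())


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def lstm_cell_step(x_t: np.ndarray, prev: CellState, p: LSTMParams) -> CellState:
    """One step of the gated recurrence (reference, readable path)."""
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (p.input_size,):
        raise ValueError(f"expected input of shape ({p.input_size},)")
    if prev.h.shape != (p.hidden_size,) or prev.c.shape != (p.hidden_size,):
        raise ValueError("state dimensions inconsistent with parameters")
    hx = np.concatenate([prev.h, x_t])
    f = _sigmoid(p.W_f @ hx + p.b_f)
    i = _sigmoid(p.W_i @ hx + p.b_i)
    g = np.tanh(p.W_c @ hx + p.b_c)
    o = _sigmoid(p.W_o @ hx + p.b_o)
    c = f * prev.c + i * g
    h = o * np.tanh(c)
    return CellState(h=h, c=c)


# --------------------------------------------------------------------------
# Packed weights and numba kernels (gate order: f, i, g, o)
# --------------------------------------------------------------------------


def _pack(p: LSTMParams):
    """LSTMParams -> (Wx (I,4H), Wh (H,4H), b (4H,)) in gate order f,i,g,o."""
    h = p.hidden_size
    Wh = np.concatenate([p.W_f[:, :h].T, p.W_i[:, :h].T, p.W_c[:, :h].T, p.W_o[:, :h].T], axis=1)
    Wx = np.concatenate([p.W_f[:, h:].T, p.W_i[:, h:].T, p.W_c[:, h:].T, p.W_o[:, h:].T], axis=1)
    b = np.concatenate([p.b_f, p.b_i, p.b_c, p.b_o])
    return np.ascontiguousarray(Wx), np.ascontiguousarray(Wh), b


def _unpack(Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray) -> LSTMParams:
    h = Wh.shape[0]
    gates = [slice(0, h), slice(h, 2 * h), slice(2 * h, 3 * h), slice(3 * h, 4 * h)]
    Ws = [np.concatenate([Wh[:, g].T, Wx[:, g].T], axis=1) for g in gates]
    bs = [b[g].copy() for g in gates]
    return LSTMParams(Ws[0], Ws[1], Ws[2], Ws[3], bs[0], bs[1], bs[2], bs[3])


@njit(cache=False)
def _fwd_kernel(Zx, Wh, h0, c0):
    """Forward recurrence.  Zx (T,B,4H) holds X@Wx + b precomputed.

    Returns hidden states Hs (T+1,B,H), cell states Cs (T+1,B,H) and gate
    caches F, I, G, O (T,B,H)."""
    T, B, H4 = Zx.shape
    H = H4 // 4
    Hs = np.empty((T + 1, B, H))
    Cs = np.empty((T + 1, B, H))
    F = np.empty((T, B, H))
    Ig = np.empty((T, B, H))
    G = np.empty((T, B, H))
    O = np.empty((T, B, H))
    Hs[0] = h0
    Cs[0] = c0
    for t in range(T):
        Z = Zx[t] + np.dot(Hs[t], Wh)
        f = 1.0 / (1.0 + np.exp(-Z[:, 0:H]))
        i = 1.0 / (1.0 + np.exp(-Z[:, H : 2 * H]))
        g = np.tanh(Z[:, 2 * H : 3 * H])
        o = 1.0 / (1.0 + np.exp(-Z[:, 3 * H : 4 * H]))
        c = f * Cs[t] + i * g
        Hs[t + 1] = o * np.tanh(c)
        Cs[t + 1] = c
        F[t] = f
        Ig[t] = i
        G[t] = g
        O[t] = o
    return Hs, Cs, F, Ig, G, O


@njit(cache=False)
def _bwd_kernel(dH_out, Hs, Cs, F, Ig, G, O, WhT):
    """Backward recurrence: pre-activation gradients dA (T,B,4H) given the
    loss gradient w.r.t. every hidden output."""
    T, B, H = dH_out.shape
    dA = np.empty((T, B, 4 * H))
    dh = np.zeros((B, H))
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        dht = dh + dH_out[t]
        tc = np.tanh(Cs[t + 1])
        do = dht * tc
        dct = dc + dht * O[t] * (1.0 - tc * tc)
        df = dct * Cs[t]
        di = dct * G[t]
        dg = dct * Ig[t]
        dA[t, :, 0:H] = df * F[t] * (1.0 - F[t])
        dA[t, :, H : 2 * H] = di * Ig[t] * (1.0 - Ig[t])
        dA[t, :, 2 * H : 3 * H] = dg * (1.0 - G[t] * G[t])
        dA[t, :, 3 * H : 4 * H] = do * O[t] * (1.0 - O[t])
        dh = np.dot(np.ascontiguousarray(dA[t]), WhT)
        dc = dct * F[t]
    return dA


def _forward(X: np.ndarray, Wx, Wh, b):
    """Run the recurrence over a batch. X (T,B,I) -> caches."""
    T, B, _ = X.shape
    H = Wh.shape[0]
    Zx = (X.reshape(T * B, -1) @ Wx + b).reshape(T, B, 4 * H)
    h0 = np.zeros((B, H))
    return _fwd_kernel(np.ascontiguousarray(Zx), Wh, h0, h0.copy())


def _weight_grads(X, Hs, dA):
    T, B, I = X.shape
    H = Hs.shape[2]
    flatA = dA.reshape(T * B, 4 * H)
    dWx = X.reshape(T * B, I).T @ flatA
    dWh = Hs[:-1].reshape(T * B, H).T @ flatA
    db = flatA.sum(axis=0)
    return dWx, dWh, db


class _Adam:
    """Plain Adam over a list of parameter arrays."""

    def __init__(self, params: list, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# --------------------------------------------------------------------------
# Flowrate regressor
# --------------------------------------------------------------------------


@dataclass
class RegressorTrainConfig:
    """Training hyperparameters of the flowrate regressor.

    The learning rate defaults to 1e-2: with only 40 epochs over cohort-sized
    datasets (a few hundred optimizer steps) Adam's customary 1e-3 leaves the
    model visibly underfit, while 1e-2 converges well within the epoch budget.
    """

    hidden_size: int = 5
    batch_size: int = 3
    epochs: int = 40
    learning_rate: float = 1e-2
    seed: int = 0
    input_mode: str = "both"  # "both" (loudness+roughness) or "roughness"


@dataclass
class RegressorModel:
    """Trained sequence-to-sequence flowrate predictor."""

    params: LSTMParams
    head_w: np.ndarray  # (hidden,)
    head_b: float
    feature_mean: np.ndarray
    feature_std: np.ndarray
    target_mean: float
    target_std: float
    input_mode: str = "both"
    loss_history: np.ndarray = field(default=None, repr=False)

    def _feature_matrix(self, fs: FeatureSeries) -> np.ndarray:
        x = np.column_stack([fs.loudness, fs.roughness])
        return _select_inputs(x, self.input_mode)

    def predict(self, features: FeatureSeries) -> FlowrateCurve:
        """Predict flowrate (mL/s) on the feature time grid; clipped at 0."""
        if features.times.size == 0:
            raise ValueError("empty feature series")
        x = (self._feature_matrix(features) - self.feature_mean) / self.feature_std
        Hs, *_ = _forward(x[:, None, :], *_pack(self.params))
        y = Hs[1:, 0, :] @ self.head_w + self.head_b
        v = y * self.target_std + self.target_mean
        return FlowrateCurve(features.times.copy(), np.maximum(v, 0.0))


def _select_inputs(x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "both":
        return x
    if mode == "roughness":
        return x[:, 1:2]
    raise ValueError("input_mode must be 'both' or 'roughness'")


def predict_flowrate(features: FeatureSeries, model: RegressorModel) -> FlowrateCurve:
    """Functional alias of :meth:`RegressorModel.predict`."""
    return model.predict(features)


def train_regressor(ts: TrainingSet, cfg: RegressorTrainConfig | None = None) -> RegressorModel:
    """Train the flowrate regressor with Adam on masked mean-squared error.

    Sequences of unequal length are zero-padded per batch with the padded
    steps masked out of the loss.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or RegressorTrainConfig()
    if ts.task != "regression" or not ts.inputs_train:
        raise ValueError("nonempty regression training set required")
    rng = np.random.default_rng(cfg.seed)

    xs = [
        (_select_inputs(np.atleast_2d(x), cfg.input_mode) - _select_inputs(
            np.atleast_2d(ts.feature_mean), cfg.input_mode
        )) / _select_inputs(np.atleast_2d(ts.feature_std), cfg.input_mode)
        for x in ts.inputs_train
    ]
    ys = [(np.asarray(y) - ts.target_mean) / ts.target_std for y in ts.targets_train]
    input_size = xs[0].shape[1]

    p = init_lstm_params(input_size, cfg.hidden_size, rng)
    Wx, Wh, b = _pack(p)
    head_w = rng.uniform(-0.5, 0.5, cfg.hidden_size)
    head_b = np.zeros(1)
    opt = _Adam([Wx, Wh, b, head_w, head_b], lr=cfg.learning_rate)

    n = len(xs)
    losses = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            bx = [xs[j] for j in idx]
            by = [ys[j] for j in idx]
            T = max(x.shape[0] for x in bx)
            B = len(bx)
            X = np.zeros((T, B, input_size))
            Y = np.zeros((T, B))
            M = np.zeros((T, B))
            for j, (x, y) in enumerate(zip(bx, by)):
                X[: x.shape[0], j] = x
                Y[: y.size, j] = y
                M[: y.size, j] = 1.0
            Hs, Cs, F, Ig, G, O = _fwd_kernel(
                np.ascontiguousarray((X.reshape(T * B, -1) @ Wx + b).reshape(T, B, -1)),
                Wh,
                np.zeros((B, cfg.hidden_size)),
                np.zeros((B, cfg.hidden_size)),
            )
            pred = Hs[1:] @ head_w + head_b[0]  # (T,B)
            err = (pred - Y) * M
            m_sum = M.sum()
            loss = float((err ** 2).sum() / m_sum)
            dpred = 2.0 * err / m_sum
            dH_out = dpred[:, :, None] * head_w[None, None, :]
            dA = _bwd_kernel(dH_out, Hs, Cs, F, Ig, G, O, np.ascontiguousarray(Wh.T))
            dWx, dWh, db = _weight_grads(X, Hs, dA)
            d_head_w = np.einsum("tb,tbh->h", dpred, Hs[1:])
            d_head_b = np.array([dpred.sum()])
            opt.step([dWx, dWh, db, d_head_w, d_head_b])
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)

    return RegressorModel(
        params=_unpack(Wx, Wh, b),
        head_w=head_w,
        head_b=float(head_b[0]),
        feature_mean=_select_inputs(np.atleast_2d(ts.feature_mean), cfg.input_mode)[0],
        feature_std=_select_inputs(np.atleast_2d(ts.feature_std), cfg.input_mode)[0],
        target_mean=ts.target_mean,
        target_std=ts.target_std,
        input_mode=cfg.input_mode,
        loss_history=np.asarray(losses),
    )


# --------------------------------------------------------------------------
# Pattern classifier
# --------------------------------------------------------------------------


@dataclass
class ClassifierTrainConfig:
    """Training hyperparameters of the pattern classifier."""

    hidden_size: int = 50
    batch_size: int = 3
    epochs: int = 500
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class ClassifierModel:
    """Trained sequence-to-label pattern classifier.

    The last hidden state summarizes the whole normalized curve; a dense
    softmax head maps it to class probabilities y = softmax(W h_T + b).
    """

    params: LSTMParams
    head_W: np.ndarray  # (hidden, 3)
    head_b: np.ndarray  # (3,)
    classes: tuple = LABELS
    sequence_length: int = RESAMPLE_LENGTH
    loss_history: np.ndarray = field(default=None, repr=False)

    def classify(self, seq) -> np.ndarray:
        """Class probabilities over (A, B, C) for one normalized curve."""
        vals = seq.values if isinstance(seq, NormalizedSequence) else np.asarray(seq, dtype=float)
        if vals.size != self.sequence_length:
            raise ValueError(f"sequence length must be {self.sequence_length}")
        Hs, *_ = _forward(vals[:, None, None], *_pack(self.params))
        return _softmax(Hs[-1, 0] @ self.head_W + self.head_b)

    def predict_label(self, seq) -> str:
        return self.classes[int(np.argmax(self.classify(seq)))]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def classify_pattern(seq, model: ClassifierModel) -> np.ndarray:
    """Functional alias of :meth:`ClassifierModel.classify`."""
    return model.classify(seq)


def train_classifier(ts: TrainingSet, cfg: ClassifierTrainConfig | None = None) -> ClassifierModel:
    """Train the pattern classifier with Adam on cross-entropy.

    Requires all three classes in the training split; deterministic given
    ``cfg.seed``.
    """
    cfg = cfg or ClassifierTrainConfig()
    if ts.task != "classification" or not ts.inputs_train:
        raise ValueError("nonempty classification training set required")
    labels = sorted(set(ts.targets_train))
    if set(LABELS) - set(labels):
        raise ValueError(f"all classes {LABELS} must be present in training data")
    rng = np.random.default_rng(cfg.seed)

    X_all = np.stack([np.asarray(x, dtype=float).reshape(-1) for x in ts.inputs_train])
    T = X_all.shape[1]
    y_all = np.array([LABELS.index(lbl) for lbl in ts.targets_train])
    n = X_all.shape[0]
    n_cls = len(LABELS)

    p = init_lstm_params(1, cfg.hidden_size, rng)
    Wx, Wh, b = _pack(p)
    lim = np.sqrt(6.0 / (cfg.hidden_size + n_cls))
    head_W = rng.uniform(-lim, lim, (cfg.hidden_size, n_cls))
    head_b = np.zeros(n_cls)
    opt = _Adam([Wx, Wh, b, head_W, head_b], lr=cfg.learning_rate)

    losses = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            B = idx.size
            X = np.ascontiguousarray(X_all[idx].T[:, :, None])  # (T,B,1)
            Hs, Cs, F, Ig, G, O = _fwd_kernel(
                np.ascontiguousarray((X.reshape(T * B, 1) @ Wx + b).reshape(T, B, -1)),
                Wh,
                np.zeros((B, cfg.hidden_size)),
                np.zeros((B, cfg.hidden_size)),
            )
            logits = Hs[-1] @ head_W + head_b
            probs = _softmax(logits)
            onehot = np.eye(n_cls)[y_all[idx]]
            loss = float(-np.log(np.maximum((probs * onehot).sum(axis=1), 1e-12)).mean())
            dlogits = (probs - onehot) / B
            dH_out = np.zeros((T, B, cfg.hidden_size))
            dH_out[-1] = dlogits @ head_W.T
            dA = _bwd_kernel(dH_out, Hs, Cs, F, Ig, G, O, np.ascontiguousarray(Wh.T))
            dWx, dWh, db = _weight_grads(X, Hs, dA)
            d_head_W = Hs[-1].T @ dlogits
            d_head_b = dlogits.sum(axis=0)
            opt.step([dWx, dWh, db, d_head_W, d_head_b])
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)

    return ClassifierModel(
        params=_unpack(Wx, Wh, b),
        head_W=head_W,
        head_b=head_b,
        sequence_length=T,
        loss_history=np.asarray(losses),
    )


# --------------------------------------------------------------------------
# Evaluation and serialization
# --------------------------------------------------------------------------


def evaluate_error_rate(pred: FlowrateCurve, meas: FlowrateCurve) -> float:
    """Mean flowrate error rate in percent.

    mean_t |pred - meas| / max(meas) * 100 on a common time grid (align
    first when grids differ)."""
    if pred.times.size != meas.times.size or not np.allclose(pred.times, meas.times):
        raise ValueError("curves must share a common time grid; align first")
    vmax = float(meas.flowrate.max())
    if vmax <= 0:
        raise ValueError("measured curve has zero maximum")
    return float(np.mean(np.abs(pred.flowrate - meas.flowrate)) / vmax * 100.0)


_FORMAT_VERSION = 1


def save_model(model, path) -> None:
    """Serialize a regressor or classifier to one portable .npz file."""
    if isinstance(model, RegressorModel):
        manifest = {
            "format_version": _FORMAT_VERSION,
            "kind": "regressor",
            "input_mode": model.input_mode,
            "target_mean": model.target_mean,
            "target_std": model.target_std,
            "head_b": model.head_b,
        }
        np.savez(
            path,
            manifest=np.array(json.dumps(manifest)),
            W_f=model.params.W_f, W_i=model.params.W_i,
            W_c=model.params.W_c, W_o=model.params.W_o,
            b_f=model.params.b_f, b_i=model.params.b_i,
            b_c=model.params.b_c, b_o=model.params.b_o,
            head_w=model.head_w,
            feature_mean=model.feature_mean,
            feature_std=model.feature_std,
        )
    elif isinstance(model, ClassifierModel):
        manifest = {
            "format_version": _FORMAT_VERSION,
            "kind": "classifier",
            "classes": list(model.classes),
            "sequence_length": model.sequence_length,
        }
        np.savez(
            path,
            manifest=np.array(json.dumps(manifest)),
            W_f=model.params.W_f, W_i=model.params.W_i,
            W_c=model.params.W_c, W_o=model.params.W_o,
            b_f=model.params.b_f, b_i=model.params.b_i,
            b_c=model.params.b_c, b_o=model.params.b_o,
            head_W=model.head_W, head_b=model.head_b,
        )
    else:
        raise TypeError("model must be a RegressorModel or ClassifierModel")


def load_model(path):
    """Load a model written by :func:`save_model`."""
    with np.load(path) as z:
        manifest = json.loads(str(z["manifest"]))
        if manifest.get("format_version") != _FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        params = LSTMParams(
            z["W_f"], z["W_i"], z["W_c"], z["W_o"],
            z["b_f"], z["b_i"], z["b_c"], z["b_o"],
        )
        if manifest["kind"] == "regressor":
            return RegressorModel(
                params=params,
                head_w=z["head_w"],
                head_b=float(manifest["head_b"]),
                feature_mean=z["feature_mean"],
                feature_std=z["feature_std"],
                target_mean=float(manifest["target_mean"]),
                target_std=float(manifest["target_std"]),
                input_mode=manifest["input_mode"],
            )
        return ClassifierModel(
            params=params,
            head_W=z["head_W"],
            head_b=z["head_b"],
            classes=tuple(manifest["classes"]),
            sequence_length=int(manifest["sequence_length"]),
        )
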