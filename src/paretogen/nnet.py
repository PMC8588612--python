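"""NumPy recurrent language model and multitask MLP with manual backprop.

This module holds the numerical core used by the generator and the MT-DNN
QSAR model: batched LSTM/GRU layers with exact analytic gradients (checked
against finite differences in the test suite), a stable softmax
cross-entropy head supporting per-sequence weights (which makes the REINFORCE
policy gradient a weighted NLL gradient), and an Adam optimizer.

Everything is float64 and CPU-only; the architectures mirror the reference
design (embedding + stacked recurrent layers + linear head for the generator,
ReLU MLP with dropout for the multitask regressor) but layer sizes are plain
constructor arguments so tests can run scaled-down instances.
"""

from __future__ import annotations

import hashlib
from typing import Dict, List, Sequence, Tuple

import numpy as np

Params = Dict[str, np.ndarray]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    s = logits - m
    return s - np.log(np.exp(s).sum(axis=-1, keepdims=True))


def softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(logits))


def params_hash(params: Params) -> str:
    """Deterministic digest of a parameter set (used for frozen-net checks)."""
    h = hashlib.sha256()
    for k in sorted(params):
        h.update(k.encode())
        h.update(np.ascontiguousarray(params[k]).tobytes())
    return h.hexdigest()


def copy_params(params: Params) -> Params:
    return {k: v.copy() for k, v in params.items()}


class Adam:
    """Adam optimizer over a named parameter dict (in-place updates)."""

    def __init__(self, params: Params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: Params) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# recurrent cells
# ---------------------------------------------------------------------------

def _lstm_forward(X, Wx, Wh, b, h0=None, c0=None):
    """X: (B,T,Din) -> H: (B,T,Hd); gates cached for backward."""
    B, T, _ = X.shape
    H = Wh.shape[0]
    h = np.zeros((B, H)) if h0 is None else h0
    c = np.zeros((B, H)) if c0 is None else c0
    Hs = np.empty((B, T, H))
    cache = []
    for t in range(T):
        x = X[:, t]
        a = x @ Wx + h @ Wh + b
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H:2 * H])
        g = np.tanh(a[:, 2 * H:3 * H])
        o = _sigmoid(a[:, 3 * H:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache.append((x, h, c, i, f, g, o, c_new, tc))
        h, c = h_new, c_new
        Hs[:, t] = h
    return Hs, (h, c), cache


def _lstm_backward(dH, cache, Wx, Wh):
    B, T, H = dH.shape
    Din = Wx.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dX = np.empty((B, T, Din))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x, h_prev, c_prev, i, f, g, o, c_new, tc = cache[t]
        dh = dH[:, t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        da = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        dWx += x.T @ da
        dWh += h_prev.T @ da
        db += da.sum(axis=0)
        dX[:, t] = da @ Wx.T
        dh_next = da @ Wh.T
    return dX, dWx, dWh, db


def _gru_forward(X, Wx, Wh, b, bh, h0=None):
    """GRU with separate hidden-side bias for the candidate gate (PyTorch layout)."""
    B, T, _ = X.shape
    H = Wh.shape[0]
    h = np.zeros((B, H)) if h0 is None else h0
    Hs = np.empty((B, T, H))
    cache = []
    for t in range(T):
        x = X[:, t]
        ax = x @ Wx + b
        ah = h @ Wh + bh
        z = _sigmoid(ax[:, :H] + ah[:, :H])
        r = _sigmoid(ax[:, H:2 * H] + ah[:, H:2 * H])
        s = ah[:, 2 * H:]
        n = np.tanh(ax[:, 2 * H:] + r * s)
        h_new = (1 - z) * n + z * h
        cache.append((x, h, z, r, s, n))
        h = h_new
        Hs[:, t] = h
    return Hs, h, cache


def _gru_backward(dH, cache, Wx, Wh):
    B, T, H = dH.shape
    Din = Wx.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(3 * H)
    dbh = np.zeros(3 * H)
    dX = np.empty((B, T, Din))
    dh_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x, h_prev, z, r, s, n = cache[t]
        dh = dH[:, t] + dh_next
        dz = dh * (h_prev - n)
        dn = dh * (1 - z)
        dh_prev = dh * z
        dan = dn * (1 - n * n)          # grad wrt pre-tanh candidate
        dr = dan * s
        ds = dan * r
        daz = dz * z * (1 - z)
        dar = dr * r * (1 - r)
        da_x = np.concatenate([daz, dar, dan], axis=1)   # input-side pre-activations
        da_h = np.concatenate([daz, dar, ds], axis=1)    # hidden-side pre-activations
        dWx += x.T @ da_x
        db += da_x.sum(axis=0)
        dWh += h_prev.T @ da_h
        dbh += da_h.sum(axis=0)
        dX[:, t] = da_x @ Wx.T
        dh_next = dh_prev + da_h @ Wh.T
    return dX, dWx, dWh, db, dbh


# ---------------------------------------------------------------------------
# recurrent language model
# ---------------------------------------------------------------------------

class RecurrentLM:
    """Embedding + stacked LSTM/GRU layers + linear softmax head.

    Computes exact gradients of a per-sequence-weighted NLL, which covers both
    maximum-likelihood training (uniform weights) and the REINFORCE policy
    gradient (weights = -reward / batch for gradient ascent).
    """

    def __init__(self, vocab_size: int, emb_dim: int = 128, hidden_dim: int = 512,
                 n_layers: int = 3, cell: str = "lstm", seed: int = 0):
        if cell not in ("lstm", "gru"):
            raise ValueError(f"unknown cell {cell!r}")
        self.vocab_size = vocab_size
        self.emb_dim = emb_dim
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.cell = cell
        rng = np.random.default_rng(seed)
        G = 4 if cell == "lstm" else 3
        p: Params = {}
        p["E"] = rng.uniform(-0.1, 0.1, size=(vocab_size, emb_dim))
        din = emb_dim
        for l in range(n_layers):
            k = 1.0 / np.sqrt(hidden_dim)
            p[f"Wx{l}"] = rng.uniform(-k, k, size=(din, G * hidden_dim))
            p[f"Wh{l}"] = rng.uniform(-k, k, size=(hidden_dim, G * hidden_dim))
            p[f"b{l}"] = np.zeros(G * hidden_dim)
            if cell == "gru":
                p[f"bh{l}"] = np.zeros(G * hidden_dim)
            din = hidden_dim
        ko = 1.0 / np.sqrt(hidden_dim)
        p["Wo"] = rng.uniform(-ko, ko, size=(hidden_dim, vocab_size))
        p["bo"] = np.zeros(vocab_size)
        self.params = p

    # -- persistence / copying ------------------------------------------------

    def config(self) -> dict:
        return dict(vocab_size=self.vocab_size, emb_dim=self.emb_dim,
                    hidden_dim=self.hidden_dim, n_layers=self.n_layers, cell=self.cell)

    def clone(self) -> "RecurrentLM":
        other = RecurrentLM(**self.config())
        other.params = copy_params(self.params)
        return other

    def load_params_from(self, other: "RecurrentLM") -> None:
        if other.config() != self.config():
            raise ValueError("architecture mismatch")
        self.params = copy_params(other.params)

    def hash(self) -> str:
        return params_hash(self.params)

    # -- dense forward/backward ----------------------------------------------

    def _run_layers(self, emb: np.ndarray):
        caches = []
        h = emb
        for l in range(self.n_layers):
            if self.cell == "lstm":
                h, _, cache = _lstm_forward(
                    h, self.params[f"Wx{l}"], self.params[f"Wh{l}"], self.params[f"b{l}"])
            else:
                h, _, cache = _gru_forward(
                    h, self.params[f"Wx{l}"], self.params[f"Wh{l}"],
                    self.params[f"b{l}"], self.params[f"bh{l}"])
            caches.append(cache)
        return h, caches

    def logits(self, inputs: np.ndarray) -> np.ndarray:
        """inputs: (B,T) int token ids -> (B,T,V) unnormalized scores."""
        emb = self.params["E"][inputs]
        h, _ = self._run_layers(emb)
        return h @ self.params["Wo"] + self.params["bo"]

    def sequence_nll(self, inputs, targets, mask) -> np.ndarray:
        """Per-sequence negative log-likelihood, shape (B,)."""
        logp = log_softmax(self.logits(inputs))
        B, T = targets.shape
        tok_logp = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
        return -(tok_logp * mask).sum(axis=1)

    def loss_and_grads(self, inputs, targets, mask, seq_weights=None
                       ) -> Tuple[float, Params]:
        """Weighted NLL  sum_b w_b * nll_b  and its exact gradients."""
        B, T = inputs.shape
        w = np.full(B, 1.0 / B) if seq_weights is None else np.asarray(seq_weights, float)
        emb = self.params["E"][inputs]
        h, caches = self._run_layers(emb)
        logits = h @ self.params["Wo"] + self.params["bo"]
        logp = log_softmax(logits)
        tok_logp = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
        loss = float(-(tok_logp * mask * w[:, None]).sum())

        dlogits = np.exp(logp)
        np.subtract.at(dlogits.reshape(B * T, -1),
                       (np.arange(B * T), targets.reshape(-1)), 1.0)
        dlogits *= (mask * w[:, None])[..., None]

        grads: Params = {}
        grads["Wo"] = np.einsum("bth,btv->hv", h, dlogits)
        grads["bo"] = dlogits.sum(axis=(0, 1))
        dh = dlogits @ self.params["Wo"].T
        for l in range(self.n_layers - 1, -1, -1):
            if self.cell == "lstm":
                dh, dWx, dWh, db = _lstm_backward(
                    dh, caches[l], self.params[f"Wx{l}"], self.params[f"Wh{l}"])
            else:
                dh, dWx, dWh, db, dbh = _gru_backward(
                    dh, caches[l], self.params[f"Wx{l}"], self.params[f"Wh{l}"])
                grads[f"bh{l}"] = dbh
            grads[f"Wx{l}"], grads[f"Wh{l}"], grads[f"b{l}"] = dWx, dWh, db
        dE = np.zeros_like(self.params["E"])
        np.add.at(dE, inputs.reshape(-1), dh.reshape(B * T, -1))
        grads["E"] = dE
        return loss, grads

    # -- stepwise API for sampling -------------------------------------------

    def init_state(self, batch_size: int) -> List:
        H = self.hidden_dim
        if self.cell == "lstm":
            return [(np.zeros((batch_size, H)), np.zeros((batch_size, H)))
                    for _ in range(self.n_layers)]
        return [np.zeros((batch_size, H)) for _ in range(self.n_layers)]

    def step(self, token_ids: np.ndarray, state: List) -> Tuple[np.ndarray, List]:
        """One autoregressive step: (B,) token ids -> (B,V) probabilities."""
        x = self.params["E"][token_ids]
        new_state = []
        for l in range(self.n_layers):
            if self.cell == "lstm":
                h, c = state[l]
                _, (h, c), _ = _lstm_forward(
                    x[:, None, :], self.params[f"Wx{l}"], self.params[f"Wh{l}"],
                    self.params[f"b{l}"], h0=h, c0=c)
                new_state.append((h, c))
                x = h
            else:
                h = state[l]
                _, h, _ = _gru_forward(
                    x[:, None, :], self.params[f"Wx{l}"], self.params[f"Wh{l}"],
                    self.params[f"b{l}"], self.params[f"bh{l}"], h0=h)
                new_state.append(h)
                x = h
        probs = softmax(x @ self.params["Wo"] + self.params["bo"])
        return probs, new_state


# ---------------------------------------------------------------------------
# multitask MLP regressor (MT-DNN)
# ---------------------------------------------------------------------------

class MultiTaskMLP:
    """ReLU MLP with dropout trained by Adam on a masked, weighted MSE.

    One output unit per target; rows may have missing targets (NaN), which are
    masked out of the loss so each molecule only trains the tasks it was
    measured on.
    """

    def __init__(self, n_features: int, n_tasks: int,
                 hidden: Sequence[int] = (4000, 2000, 1000),
                 dropout: float = 0.2, lr: float = 1e-3, epochs: int = 100,
                 batch_size: int = 256, seed: int = 0):
        self.hidden = tuple(hidden)
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        rng = np.random.default_rng(seed)
        dims = [n_features, *hidden, n_tasks]
        self.params: Params = {}
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            k = np.sqrt(2.0 / a)
            self.params[f"W{i}"] = rng.normal(0, k, size=(a, b))
            self.params[f"b{i}"] = np.zeros(b)
        self.n_layers = len(dims) - 1

    def _forward(self, X, rng=None):
        h = X
        cache = []
        for i in range(self.n_layers):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if i < self.n_layers - 1:
                a = np.maximum(z, 0.0)
                if rng is not None and self.dropout > 0:
                    keep = (rng.random(a.shape) >= self.dropout)
                    a = a * keep / (1.0 - self.dropout)
                else:
                    keep = None
                cache.append((h, z, keep))
                h = a
            else:
                cache.append((h, z, None))
                h = z
        return h, cache

    def fit(self, X, Y, sample_weight=None):
        """Y: (n, n_tasks) with NaN marking unmeasured (molecule, task) pairs.

        ``sample_weight`` may be per-row (n,) or per-cell (n, n_tasks).
        """
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n = X.shape[0]
        sw = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        if sw.ndim == 1:
            sw = np.broadcast_to(sw[:, None], Y.shape if Y.ndim == 2 else (n, 1)).copy()
        task_mask = ~np.isnan(Y)
        Yf = np.where(task_mask, Y, 0.0)
        rng = np.random.default_rng(self.seed)
        opt = Adam(self.params, lr=self.lr)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], Yf[idx]
                mb = task_mask[idx] * sw[idx]
                out, cache = self._forward(xb, rng=rng)
                denom = max(mb.sum(), 1.0)
                dout = 2.0 * (out - yb) * mb / denom
                grads: Params = {}
                delta = dout
                for i in range(self.n_layers - 1, -1, -1):
                    h_in, z, keep = cache[i]
                    grads[f"W{i}"] = h_in.T @ delta
                    grads[f"b{i}"] = delta.sum(axis=0)
                    if i > 0:
                        delta = delta @ self.params[f"W{i}"].T
                        _, z_prev, keep_prev = cache[i - 1]
                        if keep_prev is not None:
                            delta = delta * keep_prev / (1.0 - self.dropout)
                        delta = delta * (z_prev > 0)
                opt.step(grads)
        return self

    def predict(self, X) -> np.ndarray:
        out, _ = self._forward(np.asarray(X, float), rng=None)
        return out
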