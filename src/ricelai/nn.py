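"""Minimal NumPy neural-network engine for the sequence regressors.

Implements exactly the layers the LAI models need -- dense, 1-D convolution
over time, max pooling, LSTM, additive (Bahdanau-style) attention with a
learned query, inverted dropout -- each with a hand-written backward pass,
plus an Adam optimizer and an early-stopping training loop.  Everything is
deterministic given a seed and runs comfortably on one CPU at the sample
sizes of a plot-trial campaign (hundreds of sequences).

Attention follows the additive form: for hidden states h_1..h_T and a query
s, the raw score of step i is ``v^T tanh(U h_i + W s)``; scores are
softmax-normalized over unmasked steps into weights alpha that form the
convex-combination context vector ``h* = sum_i alpha_i h_i``.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = [
    "attention_scores",
    "attention_normalize",
    "attention_context",
    "Dense",
    "Conv1D",
    "MaxPool1D",
    "LSTM",
    "AdditiveAttention",
    "Dropout",
    "Adam",
]

_NEG_INF = -1e30


# ---------------------------------------------------------------------------
# Functional attention primitives (also the public contract of the mechanism)
# ---------------------------------------------------------------------------

def attention_scores(
    hidden_states: np.ndarray,
    query_state: np.ndarray,
    U: np.ndarray,
    W: np.ndarray,
    v: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Raw additive-attention score per time step.

    ``hidden_states`` is (T, H) or (B, T, H); ``query_state`` is (S,);
    ``U`` is (H, A), ``W`` is (S, A), ``v`` is (A,).  Masked steps (mask
    False) are set to a large negative surrogate so the subsequent softmax
    assigns them zero weight.
    """
    h = np.asarray(hidden_states, dtype=float)
    single = h.ndim == 2
    h = h[None] if single else h
    U, W, v = (np.asarray(a, dtype=float) for a in (U, W, v))
    s = np.asarray(query_state, dtype=float)
    if h.shape[-1] != U.shape[0] or s.shape[-1] != W.shape[0] or U.shape[1] != v.shape[0]:
        raise ValueError("inconsistent attention dimensions")
    z = np.tanh(h @ U + (s @ W)[None, None, :])
    e = z @ v
    if mask is not None:
        e = np.where(np.asarray(mask, dtype=bool).reshape(e.shape), e, _NEG_INF)
    return e[0] if single else e


def attention_normalize(scores: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Softmax the raw scores over time into weights alpha.

    Weights are non-negative, sum to one over unmasked steps, and are
    invariant to adding a constant to all scores.  All-masked input is an
    error.
    """
    e = np.asarray(scores, dtype=float).copy()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).reshape(e.shape)
        if not m.any(axis=-1).all():
            raise ValueError("at least one unmasked step is required")
        e = np.where(m, e, _NEG_INF)
    e = e - e.max(axis=-1, keepdims=True)
    w = np.exp(e)
    if mask is not None:
        w = np.where(m, w, 0.0)
    total = w.sum(axis=-1, keepdims=True)
    if np.any(total == 0):
        raise ValueError("at least one unmasked step is required")
    return w / total


def attention_context(hidden_states: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Convex combination of hidden states: h* = sum_i alpha_i h_i."""
    h = np.asarray(hidden_states, dtype=float)
    w = np.asarray(weights, dtype=float)
    if h.shape[:-1] != w.shape:
        raise ValueError("weights and hidden states disagree in length")
    return np.einsum("...t,...th->...h", w, h)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base: holds params/grads dicts; subclasses cache what backward needs."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        #: parameter names subject to L2 weight regularization
        self.weight_keys: tuple[str, ...] = ()

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(p) for k, p in self.params.items()}


class Dense(Layer):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int) -> None:
        super().__init__()
        self.params = {"W": _glorot(rng, (n_in, n_out)), "b": np.zeros(n_out)}
        self.weight_keys = ("W",)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.grads["W"] += x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
        self.grads["b"] += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.params["W"].T


class Conv1D(Layer):
    """Same-padded 1-D convolution along the time axis of a (B, T, F) input."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_filters: int, kernel: int) -> None:
        super().__init__()
        self.kernel = kernel
        self.params = {
            "W": _glorot(rng, (kernel * n_in, n_filters)).reshape(kernel, n_in, n_filters),
            "b": np.zeros(n_filters),
        }
        self.weight_keys = ("W",)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        left = (k - 1) // 2
        right = k - 1 - left
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        self._xp, self._T = xp, x.shape[1]
        y = np.zeros((x.shape[0], x.shape[1], self.params["b"].shape[0]))
        for j in range(k):
            y += xp[:, j : j + self._T, :] @ self.params["W"][j]
        return y + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, T = self.kernel, self._T
        xp = self._xp
        dxp = np.zeros_like(xp)
        for j in range(k):
            self.grads["W"][j] += np.einsum("btf,btc->fc", xp[:, j : j + T, :], dy)
            dxp[:, j : j + T, :] += dy @ self.params["W"][j].T
        self.grads["b"] += dy.sum(axis=(0, 1))
        left = (k - 1) // 2
        return dxp[:, left : left + T, :]


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; pads with -inf if T % p != 0.

    ``pool_mask`` marks a pooled step valid when any constituent input step
    was valid.
    """

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pool
        B, T, C = x.shape
        Tp = -(-T // p) * p
        xpad = np.full((B, Tp, C), -np.inf)
        xpad[:, :T, :] = x
        xr = xpad.reshape(B, Tp // p, p, C)
        self._arg = xr.argmax(axis=2)
        self._shape = (B, T, C)
        return np.take_along_axis(xr, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def pool_mask(self, mask: np.ndarray) -> np.ndarray:
        p = self.pool
        B, T = mask.shape
        Tp = -(-T // p) * p
        mpad = np.zeros((B, Tp), dtype=bool)
        mpad[:, :T] = mask
        return mpad.reshape(B, Tp // p, p).any(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, T, C = self._shape
        p = self.pool
        Tp = -(-T // p) * p
        dxr = np.zeros((B, Tp // p, p, C))
        np.put_along_axis(dxr, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        return dxr.reshape(B, Tp, C)[:, :T, :]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTM(Layer):
    """Unidirectional LSTM returning the full hidden-state sequence.

    Gate order in the stacked weight matrices is (input, forget, cell,
    output); the forget-gate bias is initialized to one.
    """

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int) -> None:
        super().__init__()
        H = n_hidden
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0
        self.params = {
            "Wx": _glorot(rng, (n_in, 4 * H)),
            "Wh": _glorot(rng, (H, 4 * H)),
            "b": b,
        }
        self.weight_keys = ("Wx", "Wh")
        self.H = H

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        out = np.zeros((B, T, H))
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        for t in range(T):
            pre = x[:, t, :] @ Wx + h @ Wh + b
            i = _sigmoid(pre[:, :H])
            f = _sigmoid(pre[:, H : 2 * H])
            g = np.tanh(pre[:, 2 * H : 3 * H])
            o = _sigmoid(pre[:, 3 * H :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            out[:, t, :] = h
            self._cache.append((x[:, t, :], h_prev, c_prev, i, f, g, o, tc))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, H = dout.shape
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dx = np.zeros((B, T, Wx.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            xt, h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dout[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc**2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dpre = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            self.grads["Wx"] += xt.T @ dpre
            self.grads["Wh"] += h_prev.T @ dpre
            self.grads["b"] += dpre.sum(axis=0)
            dx[:, t, :] = dpre @ Wx.T
            dh_next = dpre @ Wh.T
            dc_next = dc * f
        return dx


class AdditiveAttention(Layer):
    """Additive attention over encoder states with a learned query vector.

    In a sequence-to-one encoder there is no decoder state to play the role
    of the query, so the query ``s`` is a trainable parameter; scores are
    ``v^T tanh(U h_i + W s)`` and the output is the softmax-weighted context
    vector.  The last normalized weights are kept on the instance for
    inspection.
    """

    def __init__(self, rng: np.random.Generator, n_hidden: int, n_attn: int) -> None:
        super().__init__()
        self.params = {
            "U": _glorot(rng, (n_hidden, n_attn)),
            "W": _glorot(rng, (n_attn, n_attn)),
            "s": rng.uniform(-0.1, 0.1, size=n_attn),
            "v": _glorot(rng, (n_attn, 1))[:, 0],
        }
        self.weight_keys = ("U", "W", "v", "s")
        self.last_weights: np.ndarray | None = None

    def forward(self, h: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        U, W, s, v = (self.params[k] for k in ("U", "W", "s", "v"))
        z = np.tanh(h @ U + (s @ W)[None, None, :])
        e = z @ v
        if mask is not None:
            e = np.where(mask, e, _NEG_INF)
        alpha = attention_normalize(e)
        ctx = attention_context(h, alpha)
        self._cache = (h, z, alpha, mask)
        self.last_weights = alpha
        return ctx

    def backward(self, dctx: np.ndarray) -> np.ndarray:
        h, z, alpha, mask = self._cache
        U, W, s, v = (self.params[k] for k in ("U", "W", "s", "v"))
        dalpha = np.einsum("bh,bth->bt", dctx, h)
        dh = alpha[:, :, None] * dctx[:, None, :]
        de = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        if mask is not None:
            de = np.where(mask, de, 0.0)
        dz = de[:, :, None] * v[None, None, :] * (1.0 - z**2)
        self.grads["v"] += np.einsum("bt,bta->a", de, z)
        self.grads["U"] += np.einsum("bth,bta->ha", h, dz)
        dsw = dz.sum(axis=(0, 1))
        self.grads["W"] += np.outer(s, dsw)
        self.grads["s"] += dsw @ W.T
        dh += dz @ U.T
        return dh


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Adam:
    """Adam optimizer over a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(p) for k, p in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(p) for k, p in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[li][k] = self.b1 * self.m[li][k] + (1 - self.b1) * g
                self.v[li][k] = self.b2 * self.v[li][k] + (1 - self.b2) * g**2
                mhat = self.m[li][k] / (1 - self.b1**self.t)
                vhat = self.v[li][k] / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Training loop shared by all deep models
# ---------------------------------------------------------------------------

class SequenceRegressor:
    """Base class: forward/backward composition is defined by subclasses.

    Subclasses must set ``self.layers`` and implement ``_forward(X, mask,
    rng)`` (rng enables dropout -> training mode) and ``_backward(dpred)``.
    """

    layers: list[Layer]

    def predict(self, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return self._forward(X, mask, rng=None)

    def _forward(self, X, mask, rng):  # pragma: no cover - abstract
        raise NotImplementedError

    def _backward(self, dpred):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- training ----------------------------------------------------------

    def _penalty(self, l2: float) -> float:
        return l2 * sum(
            float((layer.params[k] ** 2).sum())
            for layer in self.layers
            for k in layer.weight_keys
        )

    def _val_loss(self, X, mask, y) -> float:
        pred = self.predict(X, mask)
        return float(np.mean((pred - y) ** 2))

    def fit(
        self,
        X: np.ndarray,
        mask: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        mask_val: np.ndarray,
        y_val: np.ndarray,
        *,
        l2: float = 0.01,
        lr: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 300,
        patience: int = 10,
        seed: int = 0,
    ) -> dict:
        """Minimize MSE + L2 penalty with Adam and patience-based early stopping.

        Returns the training history; the parameters of the best validation
        epoch are restored before returning.
        """
        rng = np.random.default_rng(seed)
        opt = Adam(self.layers, lr=lr)
        n = len(y)
        best_val = np.inf
        best_epoch = 0
        best_params = None
        history = {"train_loss": [], "val_loss": [], "stopped_epoch": None, "best_epoch": None}
        for epoch in range(1, max_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                Xb, mb, yb = X[idx], mask[idx], y[idx]
                pred = self._forward(Xb, mb, rng)
                err = pred - yb
                mse = float(np.mean(err**2))
                epoch_loss += mse * len(idx)
                for layer in self.layers:
                    layer.zero_grad()
                self._backward(2.0 * err / len(idx))
                for layer in self.layers:
                    for k in layer.weight_keys:
                        layer.grads[k] += 2.0 * l2 * layer.params[k]
                opt.step()
            history["train_loss"].append(epoch_loss / n + self._penalty(l2))
            val = self._val_loss(X_val, mask_val, y_val)
            history["val_loss"].append(val)
            if val < best_val:
                best_val, best_epoch = val, epoch
                best_params = [copy.deepcopy(layer.params) for layer in self.layers]
            if epoch - best_epoch >= patience:
                break
        if best_params is not None:
            for layer, saved in zip(self.layers, best_params):
                layer.params = saved
        history["stopped_epoch"] = epoch
        history["best_epoch"] = best_epoch
        return history
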