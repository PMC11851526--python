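"""Minimal feed-forward / attention / recurrent building blocks with
hand-written backprop, sized for landmark-scale problems.

All arrays are float64 numpy. Every layer caches what its backward pass
needs during ``forward`` and exposes its trainable tensors as
:class:`Parameter` objects, which the :class:`Adam` optimizer updates in
place. Analytic gradients are verified against central finite differences
in the test suite, so the implementations here are deliberately plain.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Dense",
    "ReLU",
    "Dropout",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
    "LSTMLayer",
    "sinusoidal_positional_encoding",
    "sigmoid",
    "bce_with_logits",
    "mse_loss",
    "Adam",
]


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Dense:
    """Affine map over the last axis."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Parameter(glorot(rng, n_in, n_out))
        self.b = Parameter(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Dropout:
    """Inverted dropout; identity when ``train=False`` or rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = float(rate)
        self.rng = rng

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class LayerNorm:
    def __init__(self, d: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        axes = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return (dxhat - m1 - xhat * m2) / std


def _masked_softmax(scores: np.ndarray, key_mask: np.ndarray | None) -> np.ndarray:
    # scores: (B, H, T, T); key_mask: (B, T) True where the key is valid
    if key_mask is not None:
        scores = np.where(key_mask[:, None, None, :], scores, -1e30)
    scores = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention:
    """Scaled dot-product self-attention with an optional key padding mask.

    Padded key positions receive exactly zero attention weight (enforced by
    a large negative score before the softmax).
    """

    def __init__(self, d_model: int, num_heads: int, rng: np.random.Generator):
        if d_model % num_heads != 0:
            raise ValueError("d_model must be divisible by num_heads")
        self.d = d_model
        self.h = num_heads
        self.dh = d_model // num_heads
        self.Wq = Dense(d_model, d_model, rng)
        self.Wk = Dense(d_model, d_model, rng)
        self.Wv = Dense(d_model, d_model, rng)
        self.Wo = Dense(d_model, d_model, rng)

    def params(self):
        return self.Wq.params() + self.Wk.params() + self.Wv.params() + self.Wo.params()

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        return x.reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)

    def forward(self, x: np.ndarray, key_mask: np.ndarray | None = None) -> np.ndarray:
        B, T, _ = x.shape
        q = self._split(self.Wq.forward(x))
        k = self._split(self.Wk.forward(x))
        v = self._split(self.Wv.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        attn = _masked_softmax(scores, key_mask)
        heads = attn @ v
        self._cache = (q, k, v, attn)
        concat = heads.transpose(0, 2, 1, 3).reshape(B, T, self.d)
        self.last_attention = attn  # exposed for inspection / oracle tests
        return self.Wo.forward(concat)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, attn = self._cache
        B, T, _ = dy.shape
        dconcat = self.Wo.backward(dy)
        dheads = dconcat.reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)
        dattn = dheads @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dheads
        # softmax Jacobian-vector product, row-wise
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.dh)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q

        def merge(a):
            return a.transpose(0, 2, 1, 3).reshape(B, T, self.d)

        dx = self.Wq.backward(merge(dq))
        dx = dx + self.Wk.backward(merge(dk))
        dx = dx + self.Wv.backward(merge(dv))
        return dx


class TransformerEncoderLayer:
    """Post-norm encoder block: self-attention and a position-wise
    feed-forward network, each wrapped in residual + layer norm."""

    def __init__(self, d_model: int, num_heads: int, ffn_dim: int,
                 rng: np.random.Generator, dropout: float = 0.0):
        self.attn = MultiHeadSelfAttention(d_model, num_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ff1 = Dense(d_model, ffn_dim, rng)
        self.relu = ReLU()
        self.ff2 = Dense(ffn_dim, d_model, rng)
        self.ln2 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def params(self):
        return (self.attn.params() + self.ln1.params() + self.ff1.params()
                + self.ff2.params() + self.ln2.params())

    def forward(self, x: np.ndarray, key_mask: np.ndarray | None = None,
                train: bool = True) -> np.ndarray:
        a = self.drop1.forward(self.attn.forward(x, key_mask), train)
        h = self.ln1.forward(x + a)
        f = self.drop2.forward(self.ff2.forward(self.relu.forward(self.ff1.forward(h))), train)
        return self.ln2.forward(h + f)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.ln2.backward(dy)
        df = self.drop2.backward(d)
        dh = d + self.ff1.backward(self.relu.backward(self.ff2.backward(df)))
        d = self.ln1.backward(dh)
        da = self.drop1.backward(d)
        return d + self.attn.backward(da)


def sinusoidal_positional_encoding(T: int, d: int) -> np.ndarray:
    """Fixed sin/cos positional table of shape (T, d)."""
    pos = np.arange(T)[:, None].astype(np.float64)
    i = np.arange(d // 2)[None, :].astype(np.float64)
    angle = pos / np.power(10000.0, 2.0 * i / d)
    pe = np.zeros((T, d))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : d - d // 2])
    return pe


class LSTMLayer:
    """Single LSTM layer unrolled over time with full BPTT.

    Gate layout in the packed weight matrices is (input, forget, cell,
    output). Initial hidden and cell states are zero.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in = n_in
        self.nh = n_hidden
        self.Wx = Parameter(glorot(rng, n_in, 4 * n_hidden))
        self.Wh = Parameter(glorot(rng, n_hidden, 4 * n_hidden))
        b = np.zeros(4 * n_hidden)
        b[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias init
        self.b = Parameter(b)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        nh = self.nh
        h = np.zeros((B, nh))
        c = np.zeros((B, nh))
        self._cache = []
        self._x = x
        out = np.zeros((B, T, nh))
        for t in range(T):
            z = x[:, t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = sigmoid(z[:, :nh])
            f = sigmoid(z[:, nh:2 * nh])
            g = np.tanh(z[:, 2 * nh:3 * nh])
            o = sigmoid(z[:, 3 * nh:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            out[:, t] = h
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, _ = x.shape
        nh = self.nh
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, nh))
        dc_next = np.zeros((B, nh))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            dh = dout[:, t] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            self.Wx.grad += x[:, t].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
            dc_next = dc * f
        return dx


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy over all elements, numerically stable.

    Returns ``(loss, dlogits)``.
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    # softplus(z) - y*z, computed stably
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz


def mse_loss(pred: np.ndarray, targets: np.ndarray):
    diff = np.asarray(pred, dtype=np.float64) - np.asarray(targets, dtype=np.float64)
    loss = np.mean(diff ** 2)
    return loss, 2.0 * diff / diff.size


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
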