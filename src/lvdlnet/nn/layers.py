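"""Layers with explicit forward/backward passes.

Conventions: ``forward(x, train)`` caches whatever ``backward(dout)`` needs;
``backward`` writes parameter gradients into ``self.grads`` (accumulating
nothing — each backward overwrites) and returns the gradient w.r.t. its
input. Parameters live in ``self.params`` as plain float64 arrays so the
optimizer can update them in place; non-trainable state (batch-norm running
moments) lives in ``self.state``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = [
    "Layer",
    "Dense",
    "BatchNorm1d",
    "Dropout",
    "ReLU",
    "Tanh",
    "LineConv",
    "BiLSTM",
    "softmax",
    "cross_entropy",
]


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map with He-scaled Gaussian initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


class BatchNorm1d(Layer):
    """Batch normalization over the batch axis with running moments for eval."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(n_features), "beta": np.zeros(n_features)}
        self.state = {
            "running_mean": np.zeros(n_features),
            "running_var": np.ones(n_features),
        }

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.state["running_mean"] = m * self.state["running_mean"] + (1 - m) * mu
            self.state["running_var"] = m * self.state["running_var"] + (1 - m) * var
        else:
            mu = self.state["running_mean"]
            var = self.state["running_var"]
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * invstd
        self._cache = (xhat, invstd, train)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, invstd, was_train = self._cache
        self.grads = {
            "gamma": (dout * xhat).sum(axis=0),
            "beta": dout.sum(axis=0),
        }
        dxhat = dout * self.params["gamma"]
        if not was_train:
            return dxhat * invstd
        n = dout.shape[0]
        return (
            invstd
            / n
            * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class LineConv(Layer):
    """One shared width-K inner product applied to each of L line intervals.

    Input (B, L, K) -> output (B, L): ``out[b, l] = x[b, l] . w + bias``.
    Equivalent to a stride-K width-K convolution over the flattened L*K
    vector with a single output channel.
    """

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / kernel), size=kernel),
            "b": np.zeros(1),
        }

    def forward(self, x, train=False):
        if x.ndim != 3 or x.shape[2] != self.kernel:
            raise ValueError(
                f"expected input (B, L, {self.kernel}), got {x.shape}"
            )
        self._x = x
        return x @ self.params["w"] + self.params["b"][0]

    def backward(self, dout):
        self.grads = {
            "w": np.einsum("blk,bl->k", self._x, dout),
            "b": np.array([dout.sum()]),
        }
        return dout[:, :, None] * self.params["w"][None, None, :]


class BiLSTM(Layer):
    """Bidirectional LSTM over (B, T, n_in); returns the concatenated final
    hidden states of both directions, shape (B, 2H).

    Both directions are evaluated in one pass: the leading axis of every
    weight array indexes the direction (0 = forward in wavelength order,
    1 = reversed) and the per-timestep recurrence uses batched matmuls, so
    the Python-level loop runs T times, not 2T. Gate order in the packed
    weights is [i, f, o, g] — the three sigmoid gates occupy one contiguous
    block. The forget-gate bias starts at 1 (standard trick for gradient
    flow at initialization).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.n_in = n_in
        self.n_hidden = n_hidden
        s = 1.0 / np.sqrt(n_hidden)
        self.params = {
            "Wx": rng.uniform(-s, s, size=(2, n_in, 4 * n_hidden)),
            "Wh": rng.uniform(-s, s, size=(2, n_hidden, 4 * n_hidden)),
            "b": np.zeros((2, 4 * n_hidden)),
        }
        self.params["b"][:, n_hidden : 2 * n_hidden] = 1.0  # forget gate

    def forward(self, x, train=False):
        if x.ndim != 3 or x.shape[2] != self.n_in:
            raise ValueError(f"expected input (B, T, {self.n_in}), got {x.shape}")
        B, T, _ = x.shape
        H = self.n_hidden
        Wh = self.params["Wh"]
        xs = np.stack([x, x[:, ::-1, :]])  # (2, B, T, n_in)
        # input contribution for every direction and timestep in one matmul
        zx = np.matmul(xs.reshape(2, B * T, self.n_in), self.params["Wx"])
        zx = zx.reshape(2, B, T, 4 * H) + self.params["b"][:, None, None, :]
        h = np.zeros((2, B, H))
        c = np.zeros((2, B, H))
        cache = []
        for t in range(T):
            z = zx[:, :, t, :] + np.matmul(h, Wh)
            gates = np.empty_like(z)
            gates[..., : 3 * H] = _sigmoid(z[..., : 3 * H])
            gates[..., 3 * H :] = np.tanh(z[..., 3 * H :])
            i = gates[..., :H]
            f = gates[..., H : 2 * H]
            o = gates[..., 2 * H : 3 * H]
            g = gates[..., 3 * H :]
            c_next = f * c + i * g
            tanh_c = np.tanh(c_next)
            cache.append((h, c, gates, tanh_c))
            h = o * tanh_c
            c = c_next
        self._cache = (xs, cache)
        return np.concatenate([h[0], h[1]], axis=1)

    def backward(self, dout):
        xs, cache = self._cache
        _, B, T, _ = xs.shape
        H = self.n_hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dxs = np.zeros_like(xs)
        dh = np.stack([dout[:, :H], dout[:, H:]])
        dc = np.zeros((2, B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, gates, tanh_c = cache[t]
            i = gates[..., :H]
            f = gates[..., H : 2 * H]
            o = gates[..., 2 * H : 3 * H]
            g = gates[..., 3 * H :]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            dz = np.empty((2, B, 4 * H))
            dz[..., :H] = (dc * g) * i * (1.0 - i)
            dz[..., H : 2 * H] = (dc * c_prev) * f * (1.0 - f)
            dz[..., 2 * H : 3 * H] = do * o * (1.0 - o)
            dz[..., 3 * H :] = (dc * i) * (1.0 - g**2)
            dWx += np.matmul(xs[:, :, t, :].transpose(0, 2, 1), dz)
            dWh += np.matmul(h_prev.transpose(0, 2, 1), dz)
            db += dz.sum(axis=1)
            dxs[:, :, t, :] = np.matmul(dz, Wx.transpose(0, 2, 1))
            dh = np.matmul(dz, Wh.transpose(0, 2, 1))
            dc = dc * f
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dxs[0] + dxs[1][:, ::-1, :]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    B = logits.shape[0]
    p = softmax(logits)
    loss = -float(np.mean(np.log(p[np.arange(B), y] + 1e-300)))
    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    return loss, dlogits / B
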