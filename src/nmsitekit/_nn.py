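"""Minimal feed-forward layers with explicit backpropagation.

Dense/convolution/normalization/attention building blocks on numpy,
each exposing ``forward(x, train=...)`` and ``backward(grad_out)`` and
holding its parameters in ``self.params`` (name -> Param). Gradients are
accumulated in ``Param.grad`` and verified against central finite
differences in the test suite. float64 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Linear",
    "Conv1d",
    "Conv2d",
    "BatchNorm",
    "AvgPool1d",
    "AvgPool2d",
    "PReLU",
    "Dropout",
    "MultiHeadSelfAttention",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base layer; subclasses fill self.params and the two passes."""

    def __init__(self):
        self.params: dict[str, Param] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad[...] = 0.0


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.params = {
            "W": Param(_he_init(rng, (n_in, n_out), n_in)),
            "b": Param(np.zeros(n_out)),
        }

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"].value + self.params["b"].value

    def backward(self, grad_out):
        x2 = self._x.reshape(-1, self.n_in)
        g2 = grad_out.reshape(-1, self.n_out)
        self.params["W"].grad += x2.T @ g2
        self.params["b"].grad += g2.sum(axis=0)
        return grad_out @ self.params["W"].value.T


class Conv1d(Layer):
    """Same-padded 1D convolution over (batch, channels, length)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.params = {
            "W": Param(_he_init(rng, (c_in * kernel, c_out), c_in * kernel)),
            "b": Param(np.zeros(c_out)),
        }

    def forward(self, x, train=False):
        B, C, L = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # (B, C, L, k) windows -> (B, L, C*k)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = win.transpose(0, 2, 1, 3).reshape(B, L, C * self.k)
        self._cols, self._shape = cols, (B, C, L)
        out = cols @ self.params["W"].value + self.params["b"].value  # (B, L, c_out)
        return out.transpose(0, 2, 1)

    def backward(self, grad_out):
        B, C, L = self._shape
        g = grad_out.transpose(0, 2, 1)  # (B, L, c_out)
        self.params["W"].grad += self._cols.reshape(-1, C * self.k).T @ g.reshape(-1, self.c_out)
        self.params["b"].grad += g.sum(axis=(0, 1))
        gcols = (g @ self.params["W"].value.T).reshape(B, L, C, self.k)
        pad = self.k // 2
        gxp = np.zeros((B, C, L + 2 * pad))
        for t in range(self.k):
            gxp[:, :, t : t + L] += gcols[:, :, :, t].transpose(0, 2, 1)
        return gxp[:, :, pad : pad + L]


class Conv2d(Layer):
    """Same-padded 2D convolution over (batch, channels, height, width)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan = c_in * kernel * kernel
        self.params = {
            "W": Param(_he_init(rng, (fan, c_out), fan)),
            "b": Param(np.zeros(c_out)),
        }

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        k, pad = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * k * k)
        self._cols, self._shape = cols, (B, C, H, W)
        out = cols @ self.params["W"].value + self.params["b"].value
        return out.reshape(B, H, W, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad_out):
        B, C, H, W = self._shape
        k, pad = self.k, self.k // 2
        g = grad_out.transpose(0, 2, 3, 1).reshape(B, H * W, self.c_out)
        self.params["W"].grad += self._cols.reshape(-1, C * k * k).T @ g.reshape(-1, self.c_out)
        self.params["b"].grad += g.sum(axis=(0, 1))
        gcols = (g @ self.params["W"].value.T).reshape(B, H, W, C, k, k)
        gxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad))
        for ti in range(k):
            for tj in range(k):
                gxp[:, :, ti : ti + H, tj : tj + W] += gcols[:, :, :, :, ti, tj].transpose(
                    0, 3, 1, 2
                )
        return gxp[:, :, pad : pad + H, pad : pad + W]


class BatchNorm(Layer):
    """Per-channel normalization; channel axis is axis 1.

    Training uses batch statistics and updates exponential running
    statistics; inference uses the running statistics.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.c = channels
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": Param(np.ones(channels)),
            "beta": Param(np.zeros(channels)),
        }
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def _bshape(self, ndim: int):
        return (1, self.c) + (1,) * (ndim - 2)

    def forward(self, x, train=False):
        axes = tuple(i for i in range(x.ndim) if i != 1)
        shp = self._bshape(x.ndim)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv.reshape(shp)
        self._xhat, self._inv, self._axes, self._train = xhat, inv, axes, train
        self._m = x.size // self.c
        return self.params["gamma"].value.reshape(shp) * xhat + self.params["beta"].value.reshape(shp)

    def backward(self, grad_out):
        shp = self._bshape(grad_out.ndim)
        axes = self._axes
        self.params["gamma"].grad += (grad_out * self._xhat).sum(axis=axes)
        self.params["beta"].grad += grad_out.sum(axis=axes)
        gxhat = grad_out * self.params["gamma"].value.reshape(shp)
        if not self._train:
            return gxhat * self._inv.reshape(shp)
        m = self._m
        term = (
            gxhat
            - gxhat.mean(axis=axes).reshape(shp)
            - self._xhat * (gxhat * self._xhat).sum(axis=axes).reshape(shp) / m
        )
        return term * self._inv.reshape(shp)


class PReLU(Layer):
    """Parametric ReLU with one learned slope per channel (axis 1), or a
    single slope when channels=1 is used on flat activations."""

    def __init__(self, channels: int, init: float = 0.25, channel_axis: int = 1):
        super().__init__()
        self.c = channels
        self.axis = channel_axis
        self.params = {"a": Param(np.full(channels, init))}

    def _shape(self, ndim: int):
        shp = [1] * ndim
        shp[self.axis] = self.c
        return tuple(shp)

    def forward(self, x, train=False):
        self._x = x
        a = self.params["a"].value.reshape(self._shape(x.ndim))
        return np.where(x > 0, x, a * x)

    def backward(self, grad_out):
        x = self._x
        shp = self._shape(x.ndim)
        a = self.params["a"].value.reshape(shp)
        axes = tuple(i for i in range(x.ndim) if i != self.axis)
        self.params["a"].grad += (grad_out * np.where(x > 0, 0.0, x)).sum(axis=axes)
        return grad_out * np.where(x > 0, 1.0, a)


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        assert self.rng is not None, "Dropout needs an rng for training"
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad_out):
        return grad_out if self._mask is None else grad_out * self._mask


class AvgPool1d(Layer):
    """Non-overlapping window-mean pooling over the trailing axis of (B, C, L)."""

    def __init__(self, size: int):
        super().__init__()
        if size < 1:
            raise ValueError("pool size must be >= 1")
        self.s = size

    def forward(self, x, train=False):
        s = self.s
        if s == 1:
            self._shape = None
            return x
        B, C, L = x.shape
        Ls = L // s
        self._shape = (B, C, L, Ls)
        return x[:, :, : Ls * s].reshape(B, C, Ls, s).mean(axis=3)

    def backward(self, grad_out):
        if self._shape is None:
            return grad_out
        B, C, L, Ls = self._shape
        s = self.s
        g = np.zeros((B, C, L))
        g[:, :, : Ls * s] = np.repeat(grad_out, s, axis=2) / s
        return g


class AvgPool2d(Layer):
    """Non-overlapping window-mean pooling over the two trailing axes.

    Trailing rows/columns that do not fill a window are dropped.
    """

    def __init__(self, size: int):
        super().__init__()
        if size < 1:
            raise ValueError("pool size must be >= 1")
        self.s = size

    def forward(self, x, train=False):
        s = self.s
        if s == 1:
            self._shape = None
            return x
        B, C, H, W = x.shape
        Hs, Ws = H // s, W // s
        self._shape = (B, C, H, W, Hs, Ws)
        xv = x[:, :, : Hs * s, : Ws * s].reshape(B, C, Hs, s, Ws, s)
        return xv.mean(axis=(3, 5))

    def backward(self, grad_out):
        if self._shape is None:
            return grad_out
        B, C, H, W, Hs, Ws = self._shape
        s = self.s
        g = np.zeros((B, C, H, W))
        gexp = np.broadcast_to(
            grad_out[:, :, :, None, :, None], (B, C, Hs, s, Ws, s)
        ) / (s * s)
        g[:, :, : Hs * s, : Ws * s] = gexp.reshape(B, C, Hs * s, Ws * s)
        return g


def _softmax_last(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Layer):
    """Multi-head scaled-dot-product self-attention with a residual add.

    Input and output are (batch, tokens, d_model). Per head i the layer
    computes Q_i = X W_i^Q, K_i = X W_i^K, V_i = X W_i^V, then
    softmax(Q_i K_i^T / sqrt(d_k)) V_i; the concatenated heads pass
    through W^O and are added back to X. No bias terms.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.d, self.h = d_model, n_heads
        self.dk = d_model // n_heads
        self.params = {}
        for i in range(n_heads):
            for nm in ("Q", "K", "V"):
                self.params[f"W{nm}_{i}"] = Param(_he_init(rng, (d_model, self.dk), d_model))
        self.params["WO"] = Param(_he_init(rng, (d_model, d_model), d_model))

    def _packed(self, nm: str) -> np.ndarray:
        """Concatenate the per-head (d, d_k) projections into one (d, d) matrix."""
        return np.concatenate([self.params[f"W{nm}_{i}"].value for i in range(self.h)], axis=1)

    def _split_heads(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        return x.reshape(B, T, self.h, self.dk).transpose(0, 2, 1, 3)  # (B, h, T, dk)

    def forward(self, x, train=False):
        B, T, d = x.shape
        self._x = x
        Q = self._split_heads(x @ self._packed("Q"))
        K = self._split_heads(x @ self._packed("K"))
        V = self._split_heads(x @ self._packed("V"))
        S = Q @ K.transpose(0, 1, 3, 2) / np.sqrt(self.dk)
        A = _softmax_last(S)
        H = A @ V  # (B, h, T, dk)
        self._QKVA = (Q, K, V, A)
        concat = H.transpose(0, 2, 1, 3).reshape(B, T, d)
        self._concat = concat
        return x + concat @ self.params["WO"].value

    @property
    def attention_weights(self) -> list[np.ndarray]:
        """Per-head softmax attention matrices from the last forward pass."""
        A = self._QKVA[3]
        return [A[:, i] for i in range(self.h)]

    def backward(self, grad_out):
        x = self._x
        B, T, d = x.shape
        Q, K, V, A = self._QKVA
        gx = grad_out.copy()  # residual path
        g_concat = grad_out @ self.params["WO"].value.T
        x2 = x.reshape(B * T, d)
        self.params["WO"].grad += self._concat.reshape(B * T, d).T @ grad_out.reshape(B * T, d)
        gH = self._split_heads(g_concat)
        gA = gH @ V.transpose(0, 1, 3, 2)
        gV = A.transpose(0, 1, 3, 2) @ gH
        gS = A * (gA - (gA * A).sum(axis=-1, keepdims=True)) / np.sqrt(self.dk)
        gQ = gS @ K
        gK = gS.transpose(0, 1, 3, 2) @ Q
        for nm, gM in (("Q", gQ), ("K", gK), ("V", gV)):
            gflat = gM.transpose(0, 2, 1, 3).reshape(B * T, d)  # heads back to features
            gW = x2.T @ gflat  # (d, d) across all heads
            Wpacked = self._packed(nm)
            for i in range(self.h):
                self.params[f"W{nm}_{i}"].grad += gW[:, i * self.dk : (i + 1) * self.dk]
            gx += (gflat @ Wpacked.T).reshape(B, T, d)
        return gx
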