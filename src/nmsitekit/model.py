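"""The hybrid Nm-site classifier.

Architecture, per window: two two-layer 1D-convolution branches process
the one-hot (L x 4) and Z-curve (L x 3) encodings; a two-layer 2D
convolution branch processes the L x L pairing matrix and is collapsed to
a per-position vector by row-wise mean pooling. Each branch is projected
to d_model channels, the three token maps are concatenated along the
token axis, passed through multi-head self-attention with a residual
connection, read out position-preservingly (the token matrix is
flattened; mean/max pooling are selectable alternatives), and classified
by an MLP with progressively decreasing hidden sizes ending in a sigmoid
probability. Since site context is position-specific relative to the
window center, the flattened readout matters: global pooling would make
the sequence branches translation-invariant and blind to where a motif
sits. Batch normalization follows every convolution;
PReLU is the activation throughout; dropout sits between MLP layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from nmsitekit._nn import (
    AvgPool1d,
    AvgPool2d,
    BatchNorm,
    Conv1d,
    Conv2d,
    Dropout,
    Layer,
    Linear,
    MultiHeadSelfAttention,
    Param,
    PReLU,
)
from nmsitekit.errors import InvalidConfigError, NumericalFailureError

__all__ = ["ModelConfig", "NmSiteModel", "build_model", "attend", "save_model", "load_model"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``default()`` is the full-width architecture (wide convolutions, 64-d
    attention, seven-layer MLP from 128 down to 2). ``small()`` is the
    CPU-scale preset used by the end-to-end pipeline: same topology,
    narrower channels and 2x pooling, so a full five-fold run trains in
    minutes on one core.
    """

    conv1d_channels: tuple[int, int] = (32, 64)
    conv1d_kernel: int = 5
    conv1d_pool: int = 1  # window-mean pooling factor after each 1D conv layer
    conv2d_channels: tuple[int, int] = (16, 32)
    conv2d_kernel: int = 3
    conv2d_pool: int = 1  # window-mean pooling factor after each 2D conv layer
    conv2d_input_pool: int = 1  # coarsen the pairing matrix before the first 2D conv
    attention_heads: int = 4
    d_model: int = 64
    mlp_hidden_sizes: tuple[int, ...] = (128, 64, 32, 16, 8, 4, 2)
    dropout: float = 0.05
    token_pool: str = "flatten"  # attention-output readout: flatten | mean | max
    window_length: int = 41  # production window size; fixes the flattened width
    z_scale: bool = False  # scale Z-curve coordinates by 1/L on input

    def __post_init__(self):
        if self.d_model % self.attention_heads != 0:
            raise InvalidConfigError(
                f"invalid config: d_model ({self.d_model}) not divisible by "
                f"attention_heads ({self.attention_heads})"
            )
        if any(a <= b for a, b in zip(self.mlp_hidden_sizes, self.mlp_hidden_sizes[1:])):
            raise InvalidConfigError("invalid config: mlp_hidden_sizes must be strictly decreasing")
        if not 0.0 <= self.dropout < 1.0:
            raise InvalidConfigError("invalid config: dropout must be in [0, 1)")
        if self.conv1d_kernel % 2 == 0 or self.conv2d_kernel % 2 == 0:
            raise InvalidConfigError("invalid config: kernel sizes must be odd")
        if self.token_pool not in ("flatten", "mean", "max"):
            raise InvalidConfigError("invalid config: token_pool must be flatten, mean or max")

    @property
    def d_k(self) -> int:
        return self.d_model // self.attention_heads

    @property
    def n_tokens(self) -> int:
        """Token count entering attention for a window of `window_length`."""
        l1 = self.window_length
        for _ in range(2):
            l1 //= self.conv1d_pool
        l2 = self.window_length // self.conv2d_input_pool
        for _ in range(2):
            l2 //= self.conv2d_pool
        return 2 * l1 + l2

    @property
    def mlp_input_size(self) -> int:
        if self.token_pool == "flatten":
            return self.n_tokens * self.d_model
        return self.d_model

    @classmethod
    def default(cls) -> "ModelConfig":
        return cls()

    @classmethod
    def small(cls) -> "ModelConfig":
        return cls(
            conv1d_channels=(8, 16),
            conv1d_pool=2,
            conv2d_channels=(4, 8),
            conv2d_pool=2,
            conv2d_input_pool=2,
            d_model=32,
            mlp_hidden_sizes=(32, 16, 8, 4, 2),
        )


class _ConvBranch1d:
    def __init__(self, c_in: int, cfg: ModelConfig, rng):
        c1, c2 = cfg.conv1d_channels
        k = cfg.conv1d_kernel
        self.layers: list[Layer] = [
            Conv1d(c_in, c1, k, rng), AvgPool1d(cfg.conv1d_pool), BatchNorm(c1), PReLU(c1),
            Conv1d(c1, c2, k, rng), AvgPool1d(cfg.conv1d_pool), BatchNorm(c2), PReLU(c2),
            Conv1d(c2, cfg.d_model, 1, rng),
        ]

    def forward(self, x, train):
        for lyr in self.layers:
            x = lyr.forward(x, train)
        return x

    def backward(self, g):
        for lyr in reversed(self.layers):
            g = lyr.backward(g)
        return g


class _ConvBranch2d:
    """2D branch; collapses columns by mean pooling into per-row tokens.

    An optional window-mean pool after each conv layer (conv2d_pool > 1)
    coarsens the pairing map; the resulting tokens then summarize groups
    of adjacent positions instead of single positions.
    """

    def __init__(self, cfg: ModelConfig, rng):
        c1, c2 = cfg.conv2d_channels
        k = cfg.conv2d_kernel
        self.conv_layers: list[Layer] = [
            AvgPool2d(cfg.conv2d_input_pool),
            Conv2d(1, c1, k, rng), AvgPool2d(cfg.conv2d_pool), BatchNorm(c1), PReLU(c1),
            Conv2d(c1, c2, k, rng), AvgPool2d(cfg.conv2d_pool), BatchNorm(c2), PReLU(c2),
        ]
        self.proj = Conv1d(c2, cfg.d_model, 1, rng)

    def forward(self, x, train):
        for lyr in self.conv_layers:
            x = lyr.forward(x, train)
        self._w = x.shape[3]
        pooled = x.mean(axis=3)  # (B, C, L): row-wise pooling over partners
        return self.proj.forward(pooled, train)

    def backward(self, g):
        g = self.proj.backward(g)
        g = np.repeat(g[:, :, :, None], self._w, axis=3) / self._w
        for lyr in reversed(self.conv_layers):
            g = lyr.backward(g)
        return g


class NmSiteModel:
    """Assembled classifier; ``forward`` maps feature arrays to probabilities."""

    def __init__(self, config: ModelConfig, rng_seed: int = 0):
        self.config = config
        rng = np.random.default_rng(rng_seed)
        self.branch_onehot = _ConvBranch1d(4, config, rng)
        self.branch_zcurve = _ConvBranch1d(3, config, rng)
        self.branch_pair = _ConvBranch2d(config, rng)
        self.attention = MultiHeadSelfAttention(config.d_model, config.attention_heads, rng)
        sizes = (config.mlp_input_size,) + tuple(config.mlp_hidden_sizes) + (1,)
        self.mlp: list[Layer] = []
        for i, (a, b) in enumerate(zip(sizes, sizes[1:])):
            self.mlp.append(Linear(a, b, rng))
            if i < len(sizes) - 2:  # activation + dropout between layers only
                self.mlp.append(PReLU(b, channel_axis=1))
                self.mlp.append(Dropout(config.dropout))
        self._dropout_rng = np.random.default_rng(rng_seed + 1)
        for lyr in self.mlp:
            if isinstance(lyr, Dropout):
                lyr.rng = self._dropout_rng

    # -- plumbing ----------------------------------------------------------
    def _modules(self):
        yield from self.branch_onehot.layers
        yield from self.branch_zcurve.layers
        yield from self.branch_pair.conv_layers
        yield self.branch_pair.proj
        yield self.attention
        yield from self.mlp

    def named_params(self) -> dict[str, Param]:
        out: dict[str, Param] = {}
        for i, mod in enumerate(self._modules()):
            for name, p in mod.params.items():
                out[f"m{i}.{type(mod).__name__}.{name}"] = p
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.named_params().values())

    def zero_grad(self) -> None:
        for mod in self._modules():
            mod.zero_grad()

    # -- passes ------------------------------------------------------------
    def forward(self, one_hot, z_curve, pairing, train: bool = False) -> np.ndarray:
        """Probabilities for a batch: inputs (B,L,4), (B,L,3), (B,L,L)."""
        B, L = one_hot.shape[0], one_hot.shape[1]
        xo = np.asarray(one_hot, dtype=np.float64).transpose(0, 2, 1)
        xz = np.asarray(z_curve, dtype=np.float64).transpose(0, 2, 1)
        if self.config.z_scale:
            xz = xz / L
        xp = np.asarray(pairing, dtype=np.float64)[:, None, :, :]

        to = self.branch_onehot.forward(xo, train)  # (B, d, L)
        tz = self.branch_zcurve.forward(xz, train)
        tp = self.branch_pair.forward(xp, train)  # (B, d, L') with L' = L // pool^2
        self._branch_lengths = (to.shape[2], tz.shape[2], tp.shape[2])
        tokens = np.concatenate([to, tz, tp], axis=2).transpose(0, 2, 1)  # (B, T, d)

        y = self.attention.forward(tokens, train)
        self._n_tokens = y.shape[1]
        if self.config.token_pool == "flatten":
            if self.config.window_length != L:
                raise ValueError(
                    f"model built for {self.config.window_length}-nt windows, got {L}"
                )
            h = y.reshape(B, -1)  # position-preserving readout
        elif self.config.token_pool == "max":
            self._argmax = y.argmax(axis=1)  # (B, d)
            h = np.take_along_axis(y, self._argmax[:, None, :], axis=1)[:, 0, :]
        else:
            h = y.mean(axis=1)  # (B, d)
        for lyr in self.mlp:
            h = lyr.forward(h, train)
        logit = h[:, 0]
        self._logit = logit
        p = 1.0 / (1.0 + np.exp(-logit))
        if not np.all(np.isfinite(p)):
            raise NumericalFailureError("non-finite activation in forward pass")
        self._p = p
        self._L = L
        return p

    def backward(self, dloss_dp: np.ndarray) -> None:
        """Backpropagate from the gradient of the loss w.r.t. probabilities."""
        p = self._p
        g = (dloss_dp * p * (1.0 - p))[:, None]  # through the sigmoid
        for lyr in reversed(self.mlp):
            g = lyr.backward(g)
        if self.config.token_pool == "flatten":
            g = g.reshape(g.shape[0], self._n_tokens, -1)
        elif self.config.token_pool == "max":
            gt = np.zeros((g.shape[0], self._n_tokens, g.shape[1]))
            np.put_along_axis(gt, self._argmax[:, None, :], g[:, None, :], axis=1)
            g = gt
        else:
            g = np.repeat(g[:, None, :], self._n_tokens, axis=1) / self._n_tokens
        g = self.attention.backward(g)
        g = g.transpose(0, 2, 1)  # (B, d, T)
        lo, lz, lp = self._branch_lengths
        go, gz, gp = g[:, :, :lo], g[:, :, lo : lo + lz], g[:, :, lo + lz :]
        self.branch_onehot.backward(go)
        self.branch_zcurve.backward(gz)
        self.branch_pair.backward(gp)

    def predict(self, dataset, batch_size: int = 256) -> np.ndarray:
        """Inference-mode probabilities for an EncodedDataset."""
        out = np.empty(len(dataset))
        for s in range(0, len(dataset), batch_size):
            sl = slice(s, s + batch_size)
            out[sl] = self.forward(dataset.one_hot[sl], dataset.z_curve[sl], dataset.pairing[sl])
        return out

    # -- state -------------------------------------------------------------
    def get_state(self) -> dict[str, np.ndarray]:
        state = {name: p.value.copy() for name, p in self.named_params().items()}
        for i, mod in enumerate(self._modules()):
            if isinstance(mod, BatchNorm):
                state[f"m{i}.BatchNorm.running_mean"] = mod.running_mean.copy()
                state[f"m{i}.BatchNorm.running_var"] = mod.running_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_params()
        for name, p in params.items():
            p.value[...] = state[name]
        for i, mod in enumerate(self._modules()):
            if isinstance(mod, BatchNorm):
                mod.running_mean[...] = state[f"m{i}.BatchNorm.running_mean"]
                mod.running_var[...] = state[f"m{i}.BatchNorm.running_var"]


def build_model(config: ModelConfig | None = None, rng_seed: int = 0) -> NmSiteModel:
    """Deterministically initialized model."""
    return NmSiteModel(config or ModelConfig(), rng_seed=rng_seed)


def attend(X: np.ndarray, attention: MultiHeadSelfAttention):
    """Apply one self-attention + residual block to a single token matrix.

    Returns (Y, trace) where Y = X + MultiHead(X) has X's shape and trace
    is the list of per-head attention weight matrices (rows sum to 1).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != attention.d:
        raise ValueError(f"expected (tokens, {attention.d}) input, got {X.shape}")
    Y = attention.forward(X[None], train=False)[0]
    trace = [A[0] for A in attention.attention_weights]
    return Y, trace


def save_model(path, model: NmSiteModel) -> None:
    """Checkpoint: config (json) + all tensors, reloadable bit-exactly."""
    state = model.get_state()
    np.savez_compressed(
        path,
        __config__=np.frombuffer(json.dumps(asdict(model.config)).encode(), dtype=np.uint8),
        **state,
    )


def load_model(path) -> NmSiteModel:
    with np.load(path, allow_pickle=False) as z:
        cfg_raw = json.loads(bytes(z["__config__"]).decode())
        for key in ("conv1d_channels", "conv2d_channels", "mlp_hidden_sizes"):
            cfg_raw[key] = tuple(cfg_raw[key])
        model = NmSiteModel(ModelConfig(**cfg_raw))
        model.set_state({k: z[k] for k in z.files if k != "__config__"})
    return model
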