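"""Training protocol: asymmetric loss, AdamW, cosine annealing, 5-fold CV.

The loss is a focal modulation of a weighted binary cross-entropy: with
p_t = p*y + (1-p)*(1-y) the per-sample loss is

    (1 - p_t)^gamma * ( -[ w*y*log(p) + (1-y)*log(1-p) ] )

averaged over the batch. gamma (default 2) down-weights well-classified
samples; w re-weights the positive class (typically scanned over
0.1..2.0 and selected on validation data when tuning for imbalance). Optimization uses AdamW (lr 1e-3, weight decay 1e-6),
a cosine-annealed learning rate, global gradient-norm clipping at 10,
batch size 64, and early stopping on validation MCC with patience 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from nmsitekit.errors import NumericalFailureError, SingleClassError
from nmsitekit.features import EncodedDataset
from nmsitekit.metrics import confusion, mcc_from_counts
from nmsitekit.model import ModelConfig, NmSiteModel, build_model

__all__ = [
    "LossConfig",
    "TrainConfig",
    "TrainHistory",
    "FoldResult",
    "asymmetric_loss",
    "asymmetric_loss_grad",
    "AdamW",
    "cosine_lr",
    "train_fold",
    "cross_validate",
]

_EPS = 1e-7  # probability clipping inside the loss


@dataclass(frozen=True)
class LossConfig:
    gamma: float = 2.0
    pos_weight: float = 1.0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.pos_weight <= 0:
            raise ValueError("pos_weight must be > 0")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-6
    batch_size: int = 64
    max_grad_norm: float = 10.0
    patience: int = 10
    max_epochs: int = 200
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("lr", "weight_decay", "batch_size", "max_grad_norm", "patience", "max_epochs", "folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_mcc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    @property
    def best_val_mcc(self) -> float:
        return self.val_mcc[self.best_epoch]


@dataclass
class FoldResult:
    model: NmSiteModel
    history: TrainHistory
    val_probs: np.ndarray | None = None  # predictions on the unified validation set


def _check_batch(p, y):
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if p.size == 0:
        raise ValueError("empty batch")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("label out of domain {0, 1}")
    return np.clip(p, _EPS, 1.0 - _EPS), y.astype(float)


def asymmetric_loss(probabilities, labels, config: LossConfig | None = None) -> float:
    """Batch-mean focal weighted binary cross-entropy."""
    cfg = config or LossConfig()
    p, y = _check_batch(probabilities, labels)
    p_t = p * y + (1.0 - p) * (1.0 - y)
    wbce = -(cfg.pos_weight * y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(np.mean((1.0 - p_t) ** cfg.gamma * wbce))


def asymmetric_loss_grad(probabilities, labels, config: LossConfig | None = None) -> np.ndarray:
    """d(loss)/d(p_i), batch-mean convention (verified by finite differences)."""
    cfg = config or LossConfig()
    p, y = _check_batch(probabilities, labels)
    g, w = cfg.gamma, cfg.pos_weight
    n = p.size
    grad = np.empty_like(p)
    pos = y == 1
    pp, pn = p[pos], p[~pos]
    # y=1: L = (1-p)^g * (-w log p)
    grad[pos] = g * (1 - pp) ** (g - 1) * w * np.log(pp) - (1 - pp) ** g * w / pp if g > 0 else -w / pp
    # y=0: L = p^g * (-log(1-p))
    grad[~pos] = (
        -g * pn ** (g - 1) * np.log(1 - pn) + pn ** g / (1 - pn) if g > 0 else 1.0 / (1 - pn)
    )
    # clipped region has zero gradient
    raw = np.asarray(probabilities, dtype=float)
    grad[(raw < _EPS) | (raw > 1 - _EPS)] = 0.0
    return grad / n


class AdamW:
    """Adam with decoupled weight decay over a named parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, weight_decay: float = 1e-6,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, p in self.params.items():
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p.value -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.value)


def cosine_lr(epoch: int, base_lr: float, period: int, min_lr: float = 0.0) -> float:
    """Cosine-annealed learning rate over `period` epochs (no warm restarts)."""
    frac = min(epoch, period) / period
    return min_lr + 0.5 * (base_lr - min_lr) * (1.0 + math.cos(math.pi * frac))


def _clip_grad_norm(params: dict, max_norm: float) -> float:
    total = math.sqrt(sum(float(np.sum(p.grad ** 2)) for p in params.values()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params.values():
            p.grad *= scale
    return total


def _val_mcc(model: NmSiteModel, val: EncodedDataset) -> float:
    probs = model.predict(val)
    return mcc_from_counts(confusion(val.labels, probs))


def train_fold(
    train: EncodedDataset,
    val: EncodedDataset,
    model_config: ModelConfig | None = None,
    loss_config: LossConfig | None = None,
    train_config: TrainConfig | None = None,
    rng_seed: int | None = None,
) -> tuple[NmSiteModel, TrainHistory]:
    """Train one model; return the parameters of the best-validation-MCC epoch.

    Early stopping: training ends when validation MCC has not improved for
    `patience` consecutive epochs, or at max_epochs.
    """
    mcfg = model_config or ModelConfig()
    lcfg = loss_config or LossConfig()
    tcfg = train_config or TrainConfig()
    seed = tcfg.seed if rng_seed is None else rng_seed

    classes = set(np.unique(val.labels).tolist())
    if classes != {0, 1}:
        raise SingleClassError("single-class validation set")

    model = build_model(mcfg, rng_seed=seed)
    # start the output at the class prior so the first epochs are not spent
    # learning the base rate (standard for rare-positive detection)
    prior = float(np.clip(np.mean(train.labels), 1e-3, 1 - 1e-3))
    model.mlp[-1].params["b"].value[0] = math.log(prior / (1.0 - prior))
    params = model.named_params()
    opt = AdamW(params, lr=tcfg.lr, weight_decay=tcfg.weight_decay)
    shuffle_rng = np.random.default_rng(seed + 10_000)

    history = TrainHistory()
    best_state = model.get_state()
    best_mcc = -np.inf
    since_improve = 0

    n = len(train)
    for epoch in range(tcfg.max_epochs):
        lr = cosine_lr(epoch, tcfg.lr, tcfg.max_epochs)
        opt.lr = lr
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for s in range(0, n, tcfg.batch_size):
            idx = order[s : s + tcfg.batch_size]
            probs = model.forward(
                train.one_hot[idx], train.z_curve[idx], train.pairing[idx], train=True
            )
            y = train.labels[idx]
            loss = asymmetric_loss(probs, y, lcfg)
            if not math.isfinite(loss):
                raise NumericalFailureError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}"
                )
            model.zero_grad()
            model.backward(asymmetric_loss_grad(probs, y, lcfg))
            _clip_grad_norm(params, tcfg.max_grad_norm)
            opt.step()
            epoch_loss += loss
            n_batches += 1

        mcc = _val_mcc(model, val)
        history.train_loss.append(epoch_loss / max(n_batches, 1))
        history.val_mcc.append(mcc)
        history.lr.append(lr)

        if mcc > best_mcc:
            best_mcc = mcc
            best_state = model.get_state()
            history.best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= tcfg.patience:
                history.stop_reason = "early_stop"
                break
    if not history.stop_reason:
        history.stop_reason = "max_epochs"

    model.set_state(best_state)
    return model, history


def make_folds(labels: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic class-stratified k-fold index pairs (train_idx, val_idx)."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(labels)), labels)]


def cross_validate(
    train_set: EncodedDataset,
    unified_val_set: EncodedDataset | None = None,
    model_config: ModelConfig | None = None,
    loss_config: LossConfig | None = None,
    train_config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> list[FoldResult]:
    """Five-fold cross-validation producing k models.

    Each model trains on k-1 folds with early stopping on its own held-out
    fold; the unified validation set (when given) is only scored, feeding
    the ensemble-weight optimization downstream.
    """
    if len(train_set) < k:
        raise ValueError(f"need at least {k} samples for {k}-fold CV")
    results: list[FoldResult] = []
    for fold_i, (tr_idx, va_idx) in enumerate(make_folds(train_set.labels, k, seed)):
        model, hist = train_fold(
            train_set.subset(tr_idx),
            train_set.subset(va_idx),
            model_config=model_config,
            loss_config=loss_config,
            train_config=train_config,
            rng_seed=seed + fold_i,
        )
        probs = model.predict(unified_val_set) if unified_val_set is not None else None
        results.append(FoldResult(model=model, history=hist, val_probs=probs))
    return results
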