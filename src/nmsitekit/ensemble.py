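"""Combining the five cross-validation models.

Three combiners are provided: hard voting (majority of thresholded
labels), soft voting (unweighted mean probability), and a weighted
average  y_hat = sum_i w_i f_i(x)  with nonnegative weights summing to 1,
where the weights are found by Bayesian optimization of the Matthews
correlation coefficient on a validation set. The Gaussian-process
surrogate (Matern 5/2) models MCC as a function of a point in the unit
box [0, 1]^m which is normalized onto the simplex before evaluation;
candidates are proposed by maximizing expected improvement. The initial
design always contains the equal-weight vector and every one-model
vertex, so the optimized ensemble can never score below soft voting or
any single model on the optimization set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from nmsitekit.errors import SingleClassError
from nmsitekit.metrics import confusion, mcc_from_counts

__all__ = [
    "EnsembleWeights",
    "BOConfig",
    "hard_vote",
    "soft_vote",
    "weighted_predict",
    "optimize_weights",
]


@dataclass(frozen=True)
class EnsembleWeights:
    """Nonnegative model weights on the simplex (sum to 1 within 1e-9)."""

    weights: tuple[float, ...]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < -1e-12):
            raise ValueError("invalid weights: negative entry")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise ValueError(f"invalid weights: sum {w.sum()} != 1")

    @classmethod
    def uniform(cls, m: int = 5) -> "EnsembleWeights":
        return cls(weights=tuple([1.0 / m] * m))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


@dataclass(frozen=True)
class BOConfig:
    """Bayesian-optimization settings for the weight search."""

    n_initial: int = 10  # always includes equal weights + the m vertices
    n_iterations: int = 50
    n_candidates: int = 2000  # random acquisition-maximization pool per step
    xi: float = 0.01  # EI exploration margin
    seed: int = 0

    def __post_init__(self):
        if self.n_initial < 6:
            raise ValueError("n_initial must be >= 6")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def hard_vote(per_model_labels: np.ndarray) -> np.ndarray:
    """Majority label per sample from an (m, n) binary vote matrix; m must be odd."""
    votes = np.asarray(per_model_labels)
    m = votes.shape[0]
    if m % 2 == 0:
        raise ValueError("even model count: ties possible, configure a tie rule")
    return (votes.sum(axis=0) > m / 2).astype(int)


def soft_vote(per_model_probs: np.ndarray) -> np.ndarray:
    """Unweighted mean probability per sample (equal-weight special case)."""
    return np.asarray(per_model_probs, dtype=float).mean(axis=0)


def weighted_predict(per_model_probs: np.ndarray, weights: EnsembleWeights) -> np.ndarray:
    """y_hat = sum_i w_i f_i(x) per sample."""
    probs = np.asarray(per_model_probs, dtype=float)
    w = weights.as_array()
    if w.shape[0] != probs.shape[0]:
        raise ValueError(f"{w.shape[0]} weights for {probs.shape[0]} models")
    return w @ probs


def _simplex_normalize(points: np.ndarray) -> np.ndarray:
    """Map box points onto the simplex; the all-zero point is rejected upstream."""
    s = points.sum(axis=-1, keepdims=True)
    return points / s


def _mcc_of(weights_row: np.ndarray, probs: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    yhat = weights_row @ probs
    return mcc_from_counts(confusion(labels, yhat, threshold=threshold))


def optimize_weights(
    per_model_probs: np.ndarray,
    labels: np.ndarray,
    config: BOConfig | None = None,
    threshold: float = 0.5,
) -> tuple[EnsembleWeights, float]:
    """Search the weight simplex for maximal MCC on a validation set.

    Returns the best weights actually evaluated and the MCC they achieve.
    Deterministic given the BOConfig seed.
    """
    cfg = config or BOConfig()
    probs = np.asarray(per_model_probs, dtype=float)
    y = np.asarray(labels)
    m = probs.shape[0]
    if len(set(np.unique(y).tolist()) & {0, 1}) < 2:
        raise SingleClassError("degenerate labels: both classes required")

    rng = np.random.default_rng(cfg.seed)

    # initial design: equal weights, the m vertices, then random box points
    X: list[np.ndarray] = [np.full(m, 1.0 / m)]
    X.extend(np.eye(m))
    while len(X) < cfg.n_initial:
        pt = rng.random(m)
        if pt.sum() > 1e-9:
            X.append(pt)
    X_arr = np.array(X)
    Y = np.array([_mcc_of(w, probs, y, threshold) for w in _simplex_normalize(X_arr)])

    kernel = Matern(nu=2.5, length_scale=np.ones(m))
    for _ in range(cfg.n_iterations):
        gp = GaussianProcessRegressor(
            kernel=kernel, alpha=1e-6, normalize_y=True, random_state=int(rng.integers(2**31))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            gp.fit(X_arr, Y)
        best = Y.max()
        cand = rng.random((cfg.n_candidates, m))
        cand = cand[cand.sum(axis=1) > 1e-9]
        mu, sigma = gp.predict(cand, return_std=True)
        sigma = np.maximum(sigma, 1e-12)
        imp = mu - best - cfg.xi
        zscore = imp / sigma
        ei = imp * norm.cdf(zscore) + sigma * norm.pdf(zscore)
        x_next = cand[int(np.argmax(ei))]
        y_next = _mcc_of(_simplex_normalize(x_next[None])[0], probs, y, threshold)
        X_arr = np.vstack([X_arr, x_next])
        Y = np.append(Y, y_next)

    best_i = int(np.argmax(Y))
    w_best = _simplex_normalize(X_arr[best_i][None])[0]
    return EnsembleWeights(weights=tuple(float(v) for v in w_best)), float(Y[best_i])
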