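"""Asymmetric loss closed forms and the training/cross-validation protocol."""

import math

import numpy as np
import pytest

from nmsitekit.errors import SingleClassError
from nmsitekit.features import encode_windows
from nmsitekit.model import ModelConfig
from nmsitekit.synthetic import SyntheticSpec, generate
from nmsitekit.training import (
    LossConfig,
    TrainConfig,
    asymmetric_loss,
    asymmetric_loss_grad,
    cosine_lr,
    cross_validate,
    make_folds,
    train_fold,
)

FAST_MODEL = ModelConfig(
    conv1d_channels=(4, 6),
    conv1d_pool=2,
    conv2d_channels=(2, 3),
    conv2d_pool=2,
    conv2d_input_pool=2,
    d_model=8,
    attention_heads=2,
    mlp_hidden_sizes=(8, 2),
    dropout=0.05,
)


class TestLoss:
    def test_perfect_confidence_vanishes(self):
        assert asymmetric_loss([1 - 1e-9], [1]) < 1e-10

    def test_gamma_zero_is_bce(self):
        cfg = LossConfig(gamma=0.0, pos_weight=1.0)
        assert asymmetric_loss([0.5], [1], cfg) == pytest.approx(math.log(2), abs=1e-10)
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, 500)
        y = rng.integers(0, 2, 500)
        bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert asymmetric_loss(p, y, cfg) == pytest.approx(bce, abs=1e-10)

    def test_gamma_two_closed_form(self):
        cfg = LossConfig(gamma=2.0, pos_weight=1.0)
        assert asymmetric_loss([0.5], [1], cfg) == pytest.approx(0.25 * math.log(2), abs=1e-10)

    def test_focal_factor_never_increases_loss(self):
        p = np.linspace(0.01, 0.99, 99)
        for y in (0, 1):
            labels = np.full_like(p, y)
            l2 = np.array([asymmetric_loss([pi], [y], LossConfig(gamma=2.0)) for pi in p])
            l0 = np.array([asymmetric_loss([pi], [y], LossConfig(gamma=0.0)) for pi in p])
            assert np.all(l2 <= l0 + 1e-12)

    def test_monotonicity_grid(self):
        p = np.linspace(0.01, 0.99, 99)
        pos = [asymmetric_loss([pi], [1]) for pi in p]
        neg = [asymmetric_loss([pi], [0]) for pi in p]
        assert all(a > b for a, b in zip(pos, pos[1:]))  # decreasing in p for y=1
        assert all(a < b for a, b in zip(neg, neg[1:]))  # increasing in p for y=0

    def test_pos_weight_scales_positives_only(self):
        p = [0.3, 0.7]
        for w in (0.5, 1.5, 2.0):
            lw = LossConfig(pos_weight=w)
            l1 = LossConfig(pos_weight=1.0)
            assert asymmetric_loss(p, [1, 1], lw) == pytest.approx(
                w * asymmetric_loss(p, [1, 1], l1), abs=1e-12
            )
            assert asymmetric_loss(p, [0, 0], lw) == asymmetric_loss(p, [0, 0], l1)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, 40)
        y = rng.integers(0, 2, 40)
        for cfg in (LossConfig(), LossConfig(gamma=0), LossConfig(gamma=1.5, pos_weight=0.7)):
            g = asymmetric_loss_grad(p, y, cfg)
            h = 1e-7
            for i in range(0, 40, 7):
                pp = p.copy()
                pp[i] += h
                num = (asymmetric_loss(pp, y, cfg) - asymmetric_loss(p, y, cfg)) / h
                assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_error_modes(self):
        with pytest.raises(ValueError, match="empty"):
            asymmetric_loss([], [])
        with pytest.raises(ValueError, match="label"):
            asymmetric_loss([0.5], [2])


def test_cosine_schedule_endpoints():
    assert cosine_lr(0, 1e-3, 100) == pytest.approx(1e-3)
    assert cosine_lr(100, 1e-3, 100) == pytest.approx(0.0, abs=1e-12)
    assert cosine_lr(50, 1e-3, 100) == pytest.approx(5e-4)


class TestFolds:
    def test_partition_and_determinism(self):
        y = np.array([0] * 80 + [1] * 20)
        folds = make_folds(y, 5, seed=3)
        seen = np.concatenate([va for _, va in folds])
        assert sorted(seen) == list(range(100))
        folds2 = make_folds(y, 5, seed=3)
        for (_, a), (_, b) in zip(folds, folds2):
            assert np.array_equal(a, b)

    def test_stratification_within_one_sample(self):
        y = np.array([0] * 110 + [1] * 11)
        global_frac = y.mean()
        for _, va in make_folds(y, 5, seed=1):
            n_pos = y[va].sum()
            assert abs(n_pos - global_frac * len(va)) <= 1


@pytest.fixture(scope="module")
def tiny_sets():
    ws = generate(SyntheticSpec(n_pos=24, n_neg=48, motif_fidelity=1.0, seed=12))
    enc = encode_windows(ws)
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(enc))
    return enc.subset(idx[:48]), enc.subset(idx[48:])


class TestTrainFold:
    def test_single_epoch_history(self, tiny_sets):
        train, val = tiny_sets
        _, hist = train_fold(
            train, val, model_config=FAST_MODEL,
            train_config=TrainConfig(seed=1, max_epochs=1),
        )
        assert len(hist.train_loss) == 1
        assert hist.stop_reason == "max_epochs"

    def test_single_class_validation_rejected(self, tiny_sets):
        train, val = tiny_sets
        pos_only = val.subset(np.nonzero(val.labels == 1)[0])
        with pytest.raises(SingleClassError):
            train_fold(train, pos_only, model_config=FAST_MODEL,
                       train_config=TrainConfig(seed=1, max_epochs=1))

    def test_early_stop_after_patience(self, tiny_sets):
        """With lr forced to ~0 nothing improves after epoch 0, so training
        must stop after exactly patience+1 epochs."""
        train, val = tiny_sets
        cfg = TrainConfig(seed=1, lr=1e-12, max_epochs=50, patience=3)
        _, hist = train_fold(train, val, model_config=FAST_MODEL, train_config=cfg)
        assert hist.stop_reason == "early_stop"
        assert len(hist.val_mcc) == 1 + cfg.patience

    def test_best_params_reproduce_recorded_mcc(self, tiny_sets):
        from nmsitekit.metrics import confusion, mcc_from_counts

        train, val = tiny_sets
        model, hist = train_fold(
            train, val, model_config=FAST_MODEL,
            train_config=TrainConfig(seed=2, max_epochs=6, patience=6),
        )
        re_mcc = mcc_from_counts(confusion(val.labels, model.predict(val)))
        assert re_mcc == pytest.approx(hist.best_val_mcc, abs=1e-12)

    def test_learns_separable_motif(self):
        """A noise-free planted motif must be learnable to validation MCC
        >= 0.95 (fixed seed; balanced 1000-window set)."""
        ws = generate(SyntheticSpec(n_pos=500, n_neg=500, motif_fidelity=1.0, seed=12))
        enc = encode_windows(ws)
        idx = np.random.default_rng(0).permutation(len(enc))
        train, val = enc.subset(idx[:700]), enc.subset(idx[700:])
        model, hist = train_fold(
            train, val, model_config=ModelConfig.small(),
            train_config=TrainConfig(seed=3, max_epochs=50, patience=16, batch_size=32),
        )
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert hist.best_val_mcc >= 0.95


class TestCrossValidate:
    def test_five_models_and_val_probs(self, tiny_sets):
        train, val = tiny_sets
        results = cross_validate(
            train, val, model_config=FAST_MODEL,
            train_config=TrainConfig(seed=4, max_epochs=2), k=5, seed=4,
        )
        assert len(results) == 5
        for fr in results:
            assert fr.val_probs.shape == (len(val),)
            assert np.all((fr.val_probs > 0) & (fr.val_probs < 1))

    def test_deterministic_given_seed(self, tiny_sets):
        train, val = tiny_sets
        a = cross_validate(train, val, model_config=FAST_MODEL,
                           train_config=TrainConfig(seed=5, max_epochs=2), seed=5)
        b = cross_validate(train, val, model_config=FAST_MODEL,
                           train_config=TrainConfig(seed=5, max_epochs=2), seed=5)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.val_probs, fb.val_probs)
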