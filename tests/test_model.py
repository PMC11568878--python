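"""Hybrid network: initialization, attention oracle, gradients, serialization."""

import numpy as np
import pytest

from nmsitekit._nn import MultiHeadSelfAttention
from nmsitekit.errors import InvalidConfigError
from nmsitekit.features import encode_windows
from nmsitekit.model import ModelConfig, attend, build_model, load_model, save_model
from nmsitekit.training import LossConfig, asymmetric_loss, asymmetric_loss_grad

TINY = ModelConfig(
    conv1d_channels=(3, 4),
    conv1d_pool=2,
    conv2d_channels=(2, 3),
    conv2d_pool=2,
    d_model=8,
    attention_heads=2,
    mlp_hidden_sizes=(6, 2),
    dropout=0.0,
    window_length=9,
)


def naive_multihead_attention(X, params, n_heads, dk):
    """Straightforward loop reference: per-head scaled dot-product, concat, W^O, residual."""
    T, d = X.shape
    heads = []
    for i in range(n_heads):
        Q = X @ params[f"WQ_{i}"]
        K = X @ params[f"WK_{i}"]
        V = X @ params[f"WV_{i}"]
        H = np.zeros((T, dk))
        for t in range(T):
            scores = np.array([Q[t] @ K[s] / np.sqrt(dk) for s in range(T)])
            w = np.exp(scores - scores.max())
            w /= w.sum()
            for s in range(T):
                H[t] += w[s] * V[s]
        heads.append(H)
    return X + np.concatenate(heads, axis=1) @ params["WO"]


class TestConfig:
    def test_divisibility_enforced(self):
        with pytest.raises(InvalidConfigError, match="divisible"):
            ModelConfig(attention_heads=3, d_model=64)

    def test_mlp_must_decrease(self):
        with pytest.raises(InvalidConfigError, match="decreasing"):
            ModelConfig(mlp_hidden_sizes=(64, 64, 2))

    def test_dk(self):
        assert ModelConfig().d_k == 16


class TestBuild:
    def test_seeded_init_bit_identical(self):
        a = build_model(TINY, rng_seed=0).get_state()
        b = build_model(TINY, rng_seed=0).get_state()
        assert a.keys() == b.keys()
        for k in a:
            assert np.array_equal(a[k], b[k])

    def test_parameter_count_matches_shape_audit(self):
        cfg = TINY
        model = build_model(cfg)

        def conv1d_branch(c_in):
            c1, c2 = cfg.conv1d_channels
            k = cfg.conv1d_kernel
            n = (c_in * k * c1 + c1) + (c1 * k * c2 + c2)  # convs
            n += 2 * (c1 + c2)  # batch-norm gamma/beta
            n += c1 + c2  # prelu slopes
            n += c2 * cfg.d_model + cfg.d_model  # 1x1 projection
            return n

        c1, c2 = cfg.conv2d_channels
        k2 = cfg.conv2d_kernel
        conv2d_branch = (
            (1 * k2 * k2 * c1 + c1) + (c1 * k2 * k2 * c2 + c2)
            + 2 * (c1 + c2) + (c1 + c2)
            + c2 * cfg.d_model + cfg.d_model
        )
        attention = 3 * cfg.attention_heads * cfg.d_model * cfg.d_k + cfg.d_model**2
        sizes = (cfg.mlp_input_size,) + cfg.mlp_hidden_sizes + (1,)
        mlp = sum(a * b + b for a, b in zip(sizes, sizes[1:]))
        mlp += sum(cfg.mlp_hidden_sizes)  # prelu slopes between layers
        expected = conv1d_branch(4) + conv1d_branch(3) + conv2d_branch + attention + mlp
        assert model.n_parameters() == expected


class TestAttend:
    def test_zero_projection_gives_exact_identity(self, rng):
        att = MultiHeadSelfAttention(8, 2, rng)
        att.params["WO"].value[...] = 0.0
        X = rng.normal(size=(5, 8))
        Y, _ = attend(X, att)
        assert np.array_equal(Y, X)

    def test_identical_rows_give_uniform_attention(self, rng):
        att = MultiHeadSelfAttention(8, 2, rng)
        X = np.tile(rng.normal(size=(1, 8)), (6, 1))
        _, trace = attend(X, att)
        for A in trace:
            assert A == pytest.approx(np.full((6, 6), 1 / 6), abs=1e-12)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_naive_loop_oracle(self, trial):
        rng = np.random.default_rng(trial)
        att = MultiHeadSelfAttention(8, 4, rng)
        X = rng.normal(size=(7, 8))
        Y, trace = attend(X, att)
        params = {k: p.value for k, p in att.params.items()}
        expected = naive_multihead_attention(X, params, n_heads=4, dk=2)
        assert Y == pytest.approx(expected, abs=1e-10)
        for A in trace:
            assert A.sum(axis=1) == pytest.approx(np.ones(7), abs=1e-9)


@pytest.fixture(scope="module")
def encoded():
    from nmsitekit.synthetic import SyntheticSpec, generate

    return encode_windows(generate(SyntheticSpec(n_pos=4, n_neg=4, seed=8)))


class TestForward:
    def test_output_in_open_interval(self, encoded):
        model = build_model(ModelConfig.small(), rng_seed=1)
        p = model.predict(encoded)
        assert np.all((p > 0) & (p < 1))

    def test_inference_deterministic(self, encoded):
        model = build_model(ModelConfig.small(), rng_seed=1)
        assert np.array_equal(model.predict(encoded), model.predict(encoded))

    def test_batching_consistency(self, encoded):
        model = build_model(ModelConfig.small(), rng_seed=1)
        batched = model.predict(encoded, batch_size=8)
        singles = np.concatenate(
            [model.predict(encoded.subset([i]), batch_size=1) for i in range(len(encoded))]
        )
        assert batched == pytest.approx(singles, abs=1e-12)


class TestGradients:
    def test_full_model_gradient_matches_finite_differences(self, rng):
        L = 9
        model = build_model(TINY, rng_seed=0)
        oh = rng.random((3, L, 4))
        zc = rng.normal(size=(3, L, 3))
        pr = (rng.random((3, L, L)) < 0.2).astype(float)
        y = np.array([1, 0, 1])
        cfg = LossConfig()
        p = model.forward(oh, zc, pr, train=True)
        model.zero_grad()
        model.backward(asymmetric_loss_grad(p, y, cfg))
        h = 1e-6
        for name, par in model.named_params().items():
            flat = par.value.ravel()
            for k in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                orig = flat[k]
                flat[k] = orig + h
                lo = asymmetric_loss(model.forward(oh, zc, pr, train=True), y, cfg)
                flat[k] = orig - h
                hi = asymmetric_loss(model.forward(oh, zc, pr, train=True), y, cfg)
                flat[k] = orig
                num = (lo - hi) / (2 * h)
                ana = par.grad.ravel()[k]
                assert ana == pytest.approx(num, abs=1e-5 * max(1.0, abs(num))), name

    def test_no_dead_branch(self, rng):
        """Every parameter tensor receives gradient from some sample."""
        L = 9
        model = build_model(TINY, rng_seed=3)
        oh = rng.random((8, L, 4))
        zc = rng.normal(size=(8, L, 3))
        pr = (rng.random((8, L, L)) < 0.3).astype(float)
        y = rng.integers(0, 2, 8)
        p = model.forward(oh, zc, pr, train=True)
        model.zero_grad()
        model.backward(asymmetric_loss_grad(p, y, LossConfig()))
        for name, par in model.named_params().items():
            assert np.any(par.grad != 0), f"dead parameter tensor: {name}"


def test_serialization_round_trip(tmp_path, rng):
    from nmsitekit.synthetic import SyntheticSpec, generate

    enc = encode_windows(generate(SyntheticSpec(n_pos=3, n_neg=3, seed=9)))
    model = build_model(ModelConfig.small(), rng_seed=4)
    # perturb running stats so they are exercised by the round trip
    model.forward(enc.one_hot, enc.z_curve, enc.pairing, train=True)
    before = model.predict(enc)
    path = tmp_path / "ckpt.npz"
    save_model(path, model)
    restored = load_model(path)
    assert restored.config == model.config
    assert np.array_equal(restored.predict(enc), before)
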