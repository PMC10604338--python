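"""Network building blocks: MFM, Swish, residual paths, attention, wiring."""

import numpy as np
import pytest
from scipy.special import expit

from mcheart._nn import (
    Conv2d,
    MFM,
    MultiHeadSelfAttention,
    ResidualBlock,
    Sequential,
    weighted_cross_entropy,
)
from mcheart.relcnn_model import (
    DEFAULT_BLOCK_FILTERS,
    LcnnBlock,
    LcnnBlockSpec,
    RelcnnConfig,
    build_relcnn,
    lcnn_block,
    mfm,
    multi_head_self_attention,
    residual_add,
    swish,
)

TINY_FILTERS = (2, 2, 3, 3, 4, 4, 2, 2, 2)


def tiny_model(**overrides):
    kwargs = dict(
        block_filters=TINY_FILTERS, d_model=8, mha_heads=2,
        scalar_feature_names=("s0",),
    )
    kwargs.update(overrides)
    return build_relcnn(RelcnnConfig(**kwargs), (2, 16, 48), seed=0)


class TestMfm:
    def test_identical_halves_pass_through(self, rng):
        x = rng.normal(size=(4, 10, 12))
        assert np.array_equal(mfm(np.concatenate([x, x])), x)

    def test_constant_halves(self):
        x = np.concatenate([np.full((3, 4, 4), 5.0), np.full((3, 4, 4), 1.0)])
        assert np.all(mfm(x) == 5.0)

    def test_matches_bruteforce_max_oracle(self, rng):
        for _ in range(100):
            c = 2 * int(rng.integers(1, 5))
            x = rng.normal(size=(c, 5, 6))
            out = mfm(x)
            oracle = np.maximum(x[: c // 2], x[c // 2 :])
            assert np.array_equal(out, oracle)
            assert np.all(out >= x[: c // 2]) and np.all(out >= x[c // 2 :])

    def test_odd_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            mfm(rng.normal(size=(3, 4, 4)))


class TestSwish:
    def test_zero_maps_to_zero(self):
        assert swish(np.array([0.0]))[0] == 0.0

    def test_unit_value(self):
        assert swish(np.array([1.0]), 1.0)[0] == pytest.approx(expit(1.0))

    def test_approaches_identity_at_large_beta(self):
        x = np.array([0.5])
        assert abs(swish(x, 40.0)[0] - 0.5) < 1e-3  # beta*x = 20


class TestLcnnBlock:
    def test_identity_path_with_duplicating_conv(self, rng):
        f = 3
        block = LcnnBlock(f, LcnnBlockSpec(f=f, k=1), rng)
        w = np.zeros((2 * f, f, 1, 1))
        for o in range(2 * f):
            w[o, o % f, 0, 0] = 1.0  # duplicate channels: conv out = [x; x]
        block.conv.w.value = w
        block.conv.b.value = np.zeros(2 * f)
        x = rng.normal(size=(2, f, 8, 8))
        assert np.allclose(block.forward(x), x)

    def test_maxpool_halves_spatial_dims(self, rng):
        out = lcnn_block(
            rng.normal(size=(1, 140, 782)), LcnnBlockSpec(f=4, k=3, m=1), seed=0
        )
        assert out.shape == (4, 70, 391)

    @pytest.mark.parametrize("spec", [LcnnBlockSpec(4, 3), LcnnBlockSpec(7, 5, 1, 1, 1)])
    def test_output_channels_equal_f(self, rng, spec):
        out = lcnn_block(rng.normal(size=(2, 3, 12, 12)), spec, seed=1)
        assert out.shape[1] == spec.f

    def test_kernel_size_validated(self):
        with pytest.raises(ValueError):
            LcnnBlockSpec(f=4, k=2)


class TestResidual:
    def test_zero_main_path_is_identity(self, rng):
        conv = Conv2d(3, 3, 3, rng)
        conv.w.value[:] = 0.0
        conv.b.value[:] = 0.0
        block = ResidualBlock(Sequential(conv))
        x = rng.normal(size=(2, 3, 8, 8))
        assert np.array_equal(block.forward(x), x)

    def test_matching_shapes_additive(self, rng):
        x = rng.normal(size=(3, 5, 6))
        fx = rng.normal(size=(3, 5, 6))
        assert np.allclose(residual_add(x, fx) - fx, x)
        assert np.array_equal(residual_add(x, np.zeros_like(x)), x)

    def test_channel_mismatch_projected(self, rng):
        x = rng.normal(size=(48, 4, 4))
        fx = rng.normal(size=(64, 4, 4))
        out = residual_add(x, fx)
        assert out.shape == (64, 4, 4)

    def test_spatial_mismatch_pooled(self, rng):
        x = rng.normal(size=(4, 8, 8))
        fx = np.zeros((4, 4, 4))
        out = residual_add(x, fx)
        assert out.shape == (4, 4, 4)

    def test_irreconcilable_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            residual_add(rng.normal(size=(4, 5, 5)), rng.normal(size=(4, 3, 5)))


class TestMultiHeadSelfAttention:
    def test_constant_sequence_gives_constant_output(self):
        x = np.tile(np.arange(8.0), (5, 1))[None]  # all frames identical
        out = multi_head_self_attention(x, heads=2, seed=0)
        assert np.allclose(out - out[:, :1], 0.0)

    def test_permutation_equivariance(self, rng):
        x = rng.normal(size=(1, 7, 8))
        perm = rng.permutation(7)
        layer = MultiHeadSelfAttention(8, 2, np.random.default_rng(0))
        assert np.allclose(layer.forward(x)[:, perm], layer.forward(x[:, perm]))

    def test_head_dimension(self):
        layer = MultiHeadSelfAttention(64, 8, np.random.default_rng(0))
        assert layer.dh == 8

    def test_divisibility_enforced(self):
        with pytest.raises(ValueError):
            MultiHeadSelfAttention(64, 10, np.random.default_rng(0))


class TestBuildRelcnn:
    def test_forward_softmax_rows(self, rng):
        model = tiny_model()
        probs = model.predict_proba(rng.normal(size=(4, 2, 16, 48)), rng.normal(size=(4, 1)))
        assert probs.shape == (4, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_block_filters_introspection(self):
        model = build_relcnn(RelcnnConfig(), (2, 140, 782), seed=0)
        assert model.block_filters == list(DEFAULT_BLOCK_FILTERS)

    @pytest.mark.parametrize(
        "overrides",
        [dict(use_mha=False), dict(mha_heads=4), dict(activation="relu"),
         dict(activation="none"), dict(mha_heads=10, d_model=40)],
    )
    def test_ablation_variants_build_and_run(self, rng, overrides):
        model = tiny_model(**overrides)
        probs = model.predict_proba(rng.normal(size=(2, 2, 16, 48)))
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_heads_must_divide_embedding(self):
        with pytest.raises(ValueError):
            RelcnnConfig(mha_heads=10, d_model=64)

    def test_gradient_reaches_every_parameter(self, rng):
        model = tiny_model()
        x = rng.normal(size=(3, 2, 16, 48))
        s = rng.normal(size=(3, 1))
        y = np.eye(2)[rng.integers(0, 2, 3)]
        opt = model.make_optimizer()
        opt.zero_grad()
        logits = model.forward_logits(x, s, train=True)
        _, dlogits = weighted_cross_entropy(logits, y, np.array([1.0, 3.0]))
        model.backward(dlogits)
        for name, p in model.parameters().items():
            assert np.abs(p.grad).max() > 0, f"zero gradient reaching {name}"

    def test_one_optimizer_step_changes_every_parameter(self, rng):
        model = tiny_model()
        x = rng.normal(size=(3, 2, 16, 48))
        s = rng.normal(size=(3, 1))
        y = np.eye(2)[rng.integers(0, 2, 3)]
        before = {k: p.value.copy() for k, p in model.parameters().items()}
        opt = model.make_optimizer()
        opt.zero_grad()
        logits = model.forward_logits(x, s, train=True)
        _, dlogits = weighted_cross_entropy(logits, y, np.array([1.0, 3.0]))
        model.backward(dlogits)
        opt.step()
        for name, p in model.parameters().items():
            assert not np.array_equal(before[name], p.value), f"{name} unchanged"

    def test_checkpoint_round_trip_preserves_norm_statistics(self, tmp_path, rng):
        model = tiny_model()
        x = rng.normal(size=(4, 2, 16, 48))
        # move the batch-norm running statistics away from their defaults
        model.forward_logits(x, rng.normal(size=(4, 1)), train=True)
        ref = model.predict_proba(x)
        model.save(tmp_path / "ckpt.npz")
        other = tiny_model()
        other.load(tmp_path / "ckpt.npz")
        assert np.allclose(other.predict_proba(x), ref)


class TestGradientsAgainstFiniteDifferences:
    def test_sampled_entries_match_numeric_gradient(self, rng):
        """Analytic backprop through the full stack (conv, MFM, pool, BN,
        Swish, attention, dense) agrees with central differences."""
        model = build_relcnn(
            RelcnnConfig(block_filters=TINY_FILTERS, d_model=8, mha_heads=2,
                         scalar_feature_names=("s0",)),
            (2, 16, 32), seed=0,
        )
        x = rng.normal(size=(2, 2, 16, 32))
        s = rng.normal(size=(2, 1))
        y = np.eye(2)[rng.integers(0, 2, 2)]
        w = np.array([1.0, 3.0])

        def loss():
            return weighted_cross_entropy(model.forward_logits(x, s, train=True), y, w)[0]

        params = model.parameters()
        for p in params.values():
            p.grad = np.zeros_like(p.value)
        _, dlogits = weighted_cross_entropy(
            model.forward_logits(x, s, train=True), y, w
        )
        model.backward(dlogits)
        check_rng = np.random.default_rng(0)
        for name, p in params.items():
            flat = p.value.ravel()
            for idx in check_rng.choice(flat.size, size=min(2, flat.size), replace=False):
                eps = 1e-6
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = p.grad.ravel()[idx]
                assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-7), name
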