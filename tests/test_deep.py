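"""Unit and property tests for the deep residual model."""

import numpy as np
import pytest

from drrbm.deep import (
    VARIANTS,
    AttentionGate,
    DeepModel,
    DeepTrainConfig,
    LayerNormParams,
    ResidualBlock,
    attention_forward,
    block_forward,
    finetune,
    forward,
    hinge_head_loss,
    layer_norm,
    predict,
    pretrain_deep,
    softmax_head,
    _loss_and_grads,
    _params,
)
from drrbm.rbm import RBMTrainConfig


def make_model(d=6, k=3, seed=0, head_kind="hinge", attention=True, scale=0.3):
    rng = np.random.default_rng(seed)
    h = d // 2

    def block():
        return ResidualBlock(rng.normal(0, scale, (d, h)),
                             rng.normal(0, scale, (h, d)),
                             LayerNormParams(rng.normal(1, 0.1, d), rng.normal(0, 0.1, d)))

    gate = (AttentionGate(rng.normal(0, scale, (d, 4)), rng.normal(0, scale, 4))
            if attention else AttentionGate.disabled_gate(d))
    return DeepModel(block(), block(), gate, head_kind,
                     rng.normal(0, scale, (d, k)), rng.normal(0, scale, k))


class TestLayerNorm:
    def test_reference_vector(self):
        out = layer_norm(np.array([1.0, 2.0, 3.0]), LayerNormParams.identity(3))
        np.testing.assert_allclose(out, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_input_maps_to_bias(self):
        p = LayerNormParams(np.full(4, 2.0), np.full(4, 0.5))
        np.testing.assert_allclose(layer_norm(np.full(4, 7.0), p), 0.5)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 8))
        p = LayerNormParams.identity(8)
        base = layer_norm(x, p)
        # epsilon makes the invariance approximate at moderate scales
        np.testing.assert_allclose(layer_norm(3.0 * x + 11.0, p), base, atol=1e-4)

    def test_output_moments(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 16))
        out = layer_norm(x, LayerNormParams.identity(16))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.var(axis=1), 1.0, atol=1e-4)


class TestResidualBlock:
    def test_zero_weights_identity(self):
        d = 6
        block = ResidualBlock(np.zeros((d, 3)), np.zeros((3, d)),
                              LayerNormParams.identity(d))
        x = np.random.default_rng(0).normal(size=(4, d))
        np.testing.assert_array_equal(block_forward(block, x), x)

    def test_hand_computed_small(self):
        # d=2: LN of (1, 3) -> (-1, 1) (up to eps); W_in sends it to ReLU(1*1 + ...)
        block = ResidualBlock(np.array([[0.0], [1.0]]), np.array([[1.0, 2.0]]),
                              LayerNormParams.identity(2))
        out = block_forward(block, np.array([1.0, 3.0]))
        # LN ~ (-1, 1), z = 1, relu = 1, out = (1, 3) + (1, 2)
        np.testing.assert_allclose(out, [2.0, 5.0], atol=1e-4)

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            ResidualBlock(np.zeros((5, 2)), np.zeros((2, 5)), LayerNormParams.identity(5))


class TestAttention:
    def test_zero_scores_identity(self):
        d = 5
        gate = AttentionGate(np.zeros((d, 3)), np.zeros(3))
        x = np.random.default_rng(2).normal(size=(4, d))
        out, alpha = attention_forward(gate, x)
        np.testing.assert_allclose(out, x, atol=1e-12)
        np.testing.assert_allclose(alpha, 1.0 / d)

    def test_disabled_gate_identity(self):
        x = np.random.default_rng(3).normal(size=(2, 7))
        out, alpha = attention_forward(AttentionGate.disabled_gate(7), x)
        np.testing.assert_array_equal(out, x)
        np.testing.assert_allclose(alpha.sum(axis=-1), 1.0)

    def test_alpha_is_distribution(self):
        rng = np.random.default_rng(4)
        gate = AttentionGate(rng.normal(size=(6, 4)), rng.normal(size=4))
        _, alpha = attention_forward(gate, rng.normal(size=(8, 6)))
        assert (alpha >= 0).all()
        np.testing.assert_allclose(alpha.sum(axis=-1), 1.0, atol=1e-12)

    def test_scale_preserving_on_average(self):
        # sum of d * alpha is d, so uniform alpha leaves totals unchanged
        rng = np.random.default_rng(5)
        gate = AttentionGate(rng.normal(0, 0.01, (6, 4)), rng.normal(0, 0.01, 4))
        x = np.abs(rng.normal(size=(3, 6)))
        out, _ = attention_forward(gate, x)
        np.testing.assert_allclose(out.sum(), x.sum(), rtol=0.05)


class TestHeads:
    def test_softmax_rows_sum_to_one(self):
        model = make_model(head_kind="softmax")
        x2 = np.random.default_rng(0).normal(size=(5, 6))
        p = softmax_head(x2, model)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-12)
        assert (p > 0).all()

    def test_predict_one_based_first_max(self):
        assert predict(np.array([0.2, 0.5, 0.3])) == 2
        assert predict(np.array([0.4, 0.4, 0.2])) == 1
        np.testing.assert_array_equal(predict(np.array([[1.0, 0.0], [0.0, 1.0]])), [1, 2])

    @pytest.mark.parametrize(
        "scores, y, expected",
        [
            ([2.0, -2.0, -2.0], 1, 0.0),          # all margins satisfied
            ([0.0, 0.0, 0.0], 1, 3.0),            # three unit violations
            ([-1.0, 1.0], 1, 4.0 + 4.0),          # (1-(-1))^2 + (1-(-1))^2
        ],
    )
    def test_hinge_hand_values(self, scores, y, expected):
        assert hinge_head_loss(scores, y, C=1.0) == pytest.approx(expected)

    def test_hinge_scales_with_C(self):
        assert hinge_head_loss([0.0, 0.0], 1, C=3.0) == pytest.approx(6.0)

    def test_hinge_rejects_bad_label(self):
        with pytest.raises(ValueError):
            hinge_head_loss([0.0, 0.0], 3, C=1.0)


class TestGradients:
    @pytest.mark.parametrize("head_kind", ["softmax", "hinge"])
    @pytest.mark.parametrize("attention", [True, False])
    def test_matches_finite_differences(self, head_kind, attention):
        rng = np.random.default_rng(0)
        model = make_model(d=6, k=3, head_kind=head_kind, attention=attention)
        X = rng.normal(size=(5, 6))
        y = rng.integers(1, 4, size=5)
        _, grads = _loss_and_grads(model, X, y, C=1.5, l2=0.01)
        eps = 1e-6
        for name, p in _params(model).items():
            flat = p.ravel()
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = _loss_and_grads(model, X, y, C=1.5, l2=0.01)
                flat[idx] = orig - eps
                lm, _ = _loss_and_grads(model, X, y, C=1.5, l2=0.01)
                flat[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert grads[name].ravel()[idx] == pytest.approx(fd, abs=1e-5), (
                    f"{name}[{idx}] analytic {grads[name].ravel()[idx]} vs fd {fd}")

    def test_l2_term_adds_weight_gradient(self):
        model = make_model()
        X = np.random.default_rng(1).normal(size=(4, 6))
        y = np.array([1, 2, 3, 1])
        _, g0 = _loss_and_grads(model, X, y, C=1.0, l2=0.0)
        _, g1 = _loss_and_grads(model, X, y, C=1.0, l2=0.5)
        np.testing.assert_allclose(g1["W_head"] - g0["W_head"], 0.5 * model.W_head)
        np.testing.assert_allclose(g1["b_head"], g0["b_head"])  # biases exempt


class TestPretrain:
    def test_shapes_and_attention_flag(self):
        rng = np.random.default_rng(0)
        data = rng.random((30, 8))
        cfg = DeepTrainConfig(pretrain=RBMTrainConfig(epochs=2), seed=0)
        for variant, (head, att) in VARIANTS.items():
            model = pretrain_deep(data, cfg, n_classes=4, head_kind=head, attention=att)
            assert model.d == 8 and model.k == 4
            assert model.block1.W_in.shape == (8, 4)
            assert model.block2.W_out.shape == (4, 8)
            assert model.attention.enabled is att
            assert model.head_kind == head

    def test_reproducible(self):
        rng = np.random.default_rng(1)
        data = rng.random((20, 6))
        cfg = DeepTrainConfig(pretrain=RBMTrainConfig(epochs=2), seed=7)
        m1 = pretrain_deep(data, cfg, n_classes=3)
        m2 = pretrain_deep(data, cfg, n_classes=3)
        np.testing.assert_array_equal(m1.block1.W_in, m2.block1.W_in)
        np.testing.assert_array_equal(m1.block2.W_out, m2.block2.W_out)

    def test_initial_attention_is_identity(self):
        rng = np.random.default_rng(2)
        data = rng.random((20, 6))
        model = pretrain_deep(data, DeepTrainConfig(pretrain=RBMTrainConfig(epochs=1)),
                              n_classes=3, attention=True)
        out, alpha = attention_forward(model.attention, rng.normal(size=(4, 6)))
        np.testing.assert_allclose(alpha, 1.0 / 6)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            pretrain_deep(np.zeros((5, 7)), DeepTrainConfig())


def separable_problem(n=120, d=10, k=3, seed=0, gap=4.0):
    rng = np.random.default_rng(seed)
    y = rng.integers(1, k + 1, size=n)
    means = np.zeros((k, d))
    means[:, 0] = (np.arange(k) - (k - 1) / 2) * gap
    means[:, 1] = ((np.arange(k) % 2) * 2 - 1) * gap / 2
    X = means[y - 1] + rng.normal(0, 1.0, (n, d))
    return X, y


class TestFinetune:
    def test_zero_epochs_returns_copy(self):
        model = make_model()
        X, y = separable_problem(d=6)
        out, trace = finetune(model, X, y, DeepTrainConfig(finetune_epochs=0))
        assert trace.size == 0
        np.testing.assert_array_equal(out.W_head, model.W_head)
        assert out is not model

    def test_loss_decreases(self):
        X, y = separable_problem(d=6, seed=3)
        cfg = DeepTrainConfig(pretrain=RBMTrainConfig(epochs=2),
                              finetune_epochs=40, finetune_lr=5e-3,
                              weight_decay=1e-3, batch_size=40, seed=0)
        model = pretrain_deep(X, cfg, n_classes=3)
        _, trace = finetune(model, X, y, cfg)
        assert trace[-5:].mean() < 0.5 * trace[:5].mean()

    @pytest.mark.parametrize("variant", sorted(VARIANTS))
    def test_learns_separable_toy(self, variant):
        head, att = VARIANTS[variant]
        X, y = separable_problem(n=150, d=10, k=3, seed=4, gap=5.0)
        cfg = DeepTrainConfig(pretrain=RBMTrainConfig(epochs=3),
                              finetune_epochs=120, finetune_lr=5e-3,
                              weight_decay=1e-3, batch_size=50, seed=0)
        model = pretrain_deep(np.clip(X / 10 + 0.5, 0, 1), cfg,
                              n_classes=3, head_kind=head, attention=att)
        model, _ = finetune(model, X, y, cfg)
        _, pred = forward(model, X)
        assert np.mean(pred == y) >= 0.95

    def test_reproducible(self):
        X, y = separable_problem(d=6)
        cfg = DeepTrainConfig(pretrain=RBMTrainConfig(epochs=1),
                              finetune_epochs=5, seed=11)
        m1, t1 = finetune(pretrain_deep(X, cfg, n_classes=3), X, y, cfg)
        m2, t2 = finetune(pretrain_deep(X, cfg, n_classes=3), X, y, cfg)
        np.testing.assert_array_equal(m1.W_head, m2.W_head)
        np.testing.assert_array_equal(t1, t2)

    def test_rejects_out_of_range_labels(self):
        model = make_model(k=3)
        with pytest.raises(ValueError):
            finetune(model, np.zeros((2, 6)), np.array([0, 1]), DeepTrainConfig())


class TestSerialization:
    @pytest.mark.parametrize("attention", [True, False])
    def test_round_trip_preserves_predictions(self, attention):
        model = make_model(attention=attention)
        back = DeepModel.from_dict(model.to_dict())
        x = np.random.default_rng(0).normal(size=(5, 6))
        s1, p1 = forward(model, x)
        s2, p2 = forward(back, x)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(p1, p2)

    def test_version_check(self):
        d = make_model().to_dict()
        d["format_version"] = 0
        with pytest.raises(ValueError, match="version"):
            DeepModel.from_dict(d)
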