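"""Gradient correctness of every layer, attention-gate properties, model audit."""

from dataclasses import replace

import numpy as np
import pytest

from eegadhd.nnet import (
    BatchNorm,
    Conv1d,
    Dense,
    ResidualBlock,
    SpatialAttention,
    TemporalAttention,
    numeric_gradient,
    softmax_cross_entropy,
)
from eegadhd.resnet import REDUCED_CONFIG, ModelConfig, build_model, predict, train

RNG = np.random.default_rng(0)


def assert_grads_match(layer, x, tol=1e-4):
    """Backward vs central finite differences, for the input and every parameter.

    Comparison is absolute, scaled by the overall gradient magnitude, so
    parameters with an exactly-zero true gradient (e.g. a conv bias feeding a
    batch-norm) do not produce spurious 0/0 failures.
    """
    y = layer(x)
    dy = RNG.standard_normal(y.shape)
    dx = layer.backward(dy)

    def loss():
        return float((layer(x) * dy).sum())

    gx = numeric_gradient(loss, x)
    scale = max(np.abs(gx).max(), 1.0)
    assert np.abs(gx - dx).max() <= tol * scale
    layer(x)
    layer.backward(dy)
    for name, p in layer.all_params().items():
        g = layer.all_grads()[name].copy()
        gnum = numeric_gradient(loss, p)
        scale = max(np.abs(gnum).max(), 1.0)
        assert np.abs(gnum - g).max() <= tol * scale, name


class TestLayerGradients:
    def test_dense(self):
        assert_grads_match(Dense(6, 4, RNG), RNG.standard_normal((5, 6)))

    @pytest.mark.parametrize("kernel,stride", [(3, 1), (3, 2), (5, 2), (7, 1), (1, 2)])
    def test_conv1d(self, kernel, stride):
        assert_grads_match(Conv1d(2, 3, kernel, stride, RNG),
                           RNG.standard_normal((4, 2, 13)))

    def test_batchnorm_conv(self):
        assert_grads_match(BatchNorm(3, conv=True), RNG.standard_normal((4, 3, 7)))

    def test_batchnorm_dense(self):
        assert_grads_match(BatchNorm(5, conv=False), RNG.standard_normal((6, 5)))

    def test_spatial_attention(self):
        layer = SpatialAttention(4, RNG)
        layer.fc2._params["W"][:] = 0.3 * RNG.standard_normal(layer.fc2._params["W"].shape)
        assert_grads_match(layer, RNG.standard_normal((3, 4, 9)))

    def test_temporal_attention(self):
        layer = TemporalAttention(3, RNG)
        layer._params["v"][:] = 0.3 * RNG.standard_normal(3)
        assert_grads_match(layer, RNG.standard_normal((3, 3, 8)))

    @pytest.mark.parametrize("c_out,stride", [(3, 1), (5, 2)])
    def test_residual_block(self, c_out, stride):
        assert_grads_match(ResidualBlock(3, c_out, 3, stride, RNG),
                           RNG.standard_normal((4, 3, 11)))

    def test_zeroed_residual_path_gradient_is_identity_path(self):
        """With F(x) forced to zero, the loss gradient w.r.t. the block input
        must match the finite-difference gradient through relu(x)."""
        block = ResidualBlock(3, 3, 3, 1, RNG)
        for conv in (block.conv1, block.conv2):
            conv._params["W"][:] = 0
            conv._params["b"][:] = 0
        x = RNG.standard_normal((4, 3, 11)) + 0.1
        assert_grads_match(block, x)
        y = block(x)
        np.testing.assert_allclose(y, np.maximum(x, 0), atol=1e-12)


class TestAttentionProperties:
    def test_spatial_weights_simplex(self):
        layer = SpatialAttention(7, RNG)
        layer.fc2._params["W"][:] = RNG.standard_normal(layer.fc2._params["W"].shape)
        layer(RNG.standard_normal((11, 7, 5)))
        w = layer.last_weights
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_spatial_uniform_at_symmetric_init(self):
        layer = SpatialAttention(5, RNG)       # scoring layer zero-initialized
        layer(RNG.standard_normal((4, 5, 6)))
        np.testing.assert_allclose(layer.last_weights, 0.2, atol=1e-12)

    def test_spatial_single_channel_degenerate(self):
        layer = SpatialAttention(1, RNG)
        x = RNG.standard_normal((3, 1, 6))
        layer(x)
        np.testing.assert_array_equal(layer.last_weights, np.ones((3, 1)))

    def test_temporal_weights_simplex(self):
        layer = TemporalAttention(4, RNG)
        layer._params["v"][:] = RNG.standard_normal(4)
        layer(RNG.standard_normal((9, 4, 12)))
        w = layer.last_weights
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_temporal_identity_at_length_one(self):
        layer = TemporalAttention(6, RNG)
        layer._params["v"][:] = RNG.standard_normal(6)
        x = RNG.standard_normal((5, 6, 1))
        assert np.array_equal(layer(x), x)


class TestBuildModel:
    def test_default_has_18_block_convs(self):
        m = build_model(ModelConfig(), 89)
        assert m.count_block_convs() == 18

    def test_kernel_validation(self):
        with pytest.raises(ValueError, match="kernel"):
            ModelConfig(stage_kernels=(7, 5, 4, 3))

    def test_input_width_contract(self):
        with pytest.raises(ValueError):
            build_model(ModelConfig(), 4)

    def test_zero_batch_forward_finite(self):
        m = build_model(REDUCED_CONFIG, 32)
        m.set_train(False)
        out = m(np.zeros((3, 1, 32)))
        assert out.shape == (3, 2)
        assert np.isfinite(out).all()

    def test_stride_halves_width(self):
        rng = np.random.default_rng(1)
        block = ResidualBlock(2, 4, 3, 2, rng)
        y = block(rng.standard_normal((2, 2, 16)))
        assert y.shape[-1] == 8

    def test_attention_ablation_is_plain_resnet(self):
        cfg = replace(REDUCED_CONFIG, spatial_attention=False, temporal_attention=False)
        m = build_model(cfg, 32)
        assert m.attention_layers() == []
        assert m.count_block_convs() == 8


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(1)
    n = 600
    y = np.repeat([0, 1], n // 2)
    x = rng.standard_normal((n, 89))
    x[y == 1, :10] += 2.0
    return x, y


class TestTrainPredict:
    def test_zero_epochs_returns_initialization(self, separable):
        x, y = separable
        cfg = replace(REDUCED_CONFIG, epochs=0, seed=0)
        model = train(x, y, cfg)
        assert model.history == []

    def test_separable_training_accuracy(self, separable):
        x, y = separable
        cfg = replace(REDUCED_CONFIG, epochs=20, batch_size=64, seed=0)
        model = train(x, y, cfg)
        _, pred = predict(model, x)
        assert np.mean(pred == y) >= 0.98
        # held-out generalization on fresh draws from the same construction
        rng = np.random.default_rng(99)
        y2 = np.repeat([0, 1], 100)
        x2 = rng.standard_normal((200, 89))
        x2[y2 == 1, :10] += 2.0
        _, pred2 = predict(model, x2)
        assert np.mean(pred2 == y2) >= 0.95

    def test_seed_determinism(self, separable):
        x, y = separable
        cfg = replace(REDUCED_CONFIG, epochs=3, seed=4)
        a = train(x, y, cfg)
        b = train(x, y, cfg)
        assert a.history == b.history

    def test_probabilities_simplex_and_tie_rule(self, separable):
        x, y = separable
        cfg = replace(REDUCED_CONFIG, epochs=2, seed=0)
        model = train(x, y, cfg)
        p, labels = predict(model, x[:50])
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        # exact tie -> class 0: an identically-zero head yields p = [0.5, 0.5]
        zeroed = train(x, y, replace(REDUCED_CONFIG, epochs=0, seed=0))
        for param in zeroed.network.head._params.values():
            param[:] = 0
        p_tie, label_tie = predict(zeroed, x[:5])
        np.testing.assert_array_equal(p_tie, 0.5)
        np.testing.assert_array_equal(label_tie, 0)

    def test_single_class_rejected(self):
        x = np.zeros((20, 16))
        with pytest.raises(ValueError):
            train(x, np.zeros(20, int), REDUCED_CONFIG)

    def test_width_mismatch_at_predict(self, separable):
        x, y = separable
        model = train(x, y, replace(REDUCED_CONFIG, epochs=1, seed=0))
        with pytest.raises(ValueError):
            predict(model, x[:, :40])


class TestSoftmaxCrossEntropy:
    def test_gradient_matches_finite_difference(self):
        logits = RNG.standard_normal((6, 2))
        labels = np.array([0, 1, 1, 0, 1, 0])
        _, grad = softmax_cross_entropy(logits, labels)
        gnum = numeric_gradient(
            lambda: softmax_cross_entropy(logits, labels)[0], logits)
        np.testing.assert_allclose(grad, gnum, atol=1e-7)


class TestLearnedAttentionConcentration:
    """Trained gates must concentrate on where the class signal actually lives."""

    def test_spatial_attention_finds_planted_channels(self):
        small = ModelConfig(
            blocks_per_stage=(1,), stage_kernels=(3,), stage_channels=(8,),
            input_spatial_attention=True, epochs=15, batch_size=32,
            learning_rate=3e-3)
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            n, length = 240, 32
            y = np.repeat([0, 1], n // 2)
            x = rng.standard_normal((n, 19, length))
            sig = 2.0 * np.sin(2 * np.pi * 8 * np.arange(length) / 128.0)
            for i in np.flatnonzero(y == 1):
                x[i, 3] += sig
                x[i, 7] += sig
            model = train(x, y, replace(small, seed=seed), input_channels=19)
            model.network.set_train(False)
            model.network(x)
            w = model.network.body.layers[0].last_weights.mean(axis=0)
            wins += w[[3, 7]].mean() > np.delete(w, [3, 7]).mean()
        assert wins >= 3

    def test_temporal_attention_finds_planted_interval(self):
        from eegadhd.nnet import TemporalAttention
        small = ModelConfig(
            blocks_per_stage=(1,), stage_kernels=(3,), stage_channels=(8,),
            epochs=20, batch_size=32, learning_rate=3e-3)
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            n, length = 240, 64
            y = np.repeat([0, 1], n // 2)
            x = rng.standard_normal((n, 1, length))
            x[y == 1, 0, :length // 2] += 1.5   # burst occupies the first half
            model = train(x, y, replace(small, seed=seed), input_channels=1)
            model.network.set_train(False)
            model.network(x)
            gate = [l for l in model.network.body.layers
                    if isinstance(l, TemporalAttention)][-1]
            wins += gate.last_weights[:, :length // 2].sum(axis=1).mean() > 0.5
        assert wins >= 3
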