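import numpy as np
import pytest

from dhsnet.errors import BatchError, ModelConfigError
from dhsnet.nn import (
    GatedConv1d,
    InceptionBlock,
    LeakyReLU,
    ModelConfig,
    SpatialPyramidPool,
    build_model,
    count_parameters,
    cross_entropy,
    load_checkpoint,
    predict,
    save_checkpoint,
)


def brute_force_conv_same(x, W, b):
    """Sliding-dot-product oracle for same-padding 1-D convolution."""
    n, cin, length = x.shape
    cout, _, k = W.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    y = np.zeros((n, cout, length))
    for i in range(n):
        for o in range(cout):
            for l in range(length):
                y[i, o, l] = (xp[i, :, l : l + k] * W[o]).sum() + b[o]
    return y


class TestLeakyRelu:
    @pytest.mark.parametrize("x,expected", [(5.0, 5.0), (0.0, 0.0), (-100.0, -1.0)])
    def test_pointwise_values(self, x, expected):
        layer = LeakyReLU(100.0)
        assert layer.forward(np.array([[x]])) == pytest.approx(expected)

    def test_monotone_and_continuous_at_zero(self):
        layer = LeakyReLU(100.0)
        xs = np.linspace(-2, 2, 2001)
        ys = layer.forward(xs[None])[0]
        assert (np.diff(ys) > 0).all()
        assert abs(layer.forward(np.array([[1e-9]]))[0, 0]) < 1e-8


class TestGatedConv:
    def test_zero_gate_halves_linear_conv(self, rng):
        gc = GatedConv1d(2, 3, 3, rng)
        gc.gate.W[...] = 0.0
        gc.gate.b[...] = 0.0
        x = rng.random((2, 2, 8)).astype(np.float32)
        lin = gc.linear.forward(x)
        assert np.allclose(gc.forward(x), 0.5 * lin, atol=1e-6)

    def test_zero_linear_conv_gives_zero(self, rng):
        gc = GatedConv1d(2, 3, 3, rng)
        gc.linear.W[...] = 0.0
        gc.linear.b[...] = 0.0
        x = rng.random((1, 2, 8)).astype(np.float32)
        assert np.allclose(gc.forward(x), 0.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            cin, cout = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            k = int(rng.choice([1, 3, 5, 7]))
            length = int(rng.integers(max(2, k), 11))
            gc = GatedConv1d(cin, cout, k, rng)
            x = rng.standard_normal((2, cin, length)).astype(np.float32)
            lin = brute_force_conv_same(x, gc.linear.W, gc.linear.b)
            gate = brute_force_conv_same(x, gc.gate.W, gc.gate.b)
            expected = lin * (1.0 / (1.0 + np.exp(-gate)))
            assert np.allclose(gc.forward(x), expected, atol=1e-6)

    def test_length_preserved(self, rng):
        gc = GatedConv1d(4, 8, 7, rng)
        assert gc.forward(rng.random((1, 4, 33)).astype(np.float32)).shape == (1, 8, 33)

    def test_channel_mismatch_rejected(self, rng):
        gc = GatedConv1d(4, 8, 3, rng)
        with pytest.raises(ModelConfigError):
            gc.forward(rng.random((1, 3, 10)).astype(np.float32))

    def test_single_gated_conv_parameter_count(self, rng):
        # 1->1 channels, kernel 3, biases: two kernels of 3 + two biases = 8
        gc = GatedConv1d(1, 1, 3, rng)
        assert count_parameters(gc) == 8


class TestInceptionBlock:
    def test_channel_concatenation_arithmetic(self, rng):
        block = InceptionBlock(*[GatedConv1d(4, 8, k, rng) for k in (1, 3, 5, 7)])
        y = block.forward(rng.random((2, 4, 16)).astype(np.float32))
        assert y.shape == (2, 32, 16)

    def test_branches_equal_standalone_calls(self, rng):
        branches = [GatedConv1d(4, 8, k, rng) for k in (1, 3, 5, 7)]
        block = InceptionBlock(*branches)
        x = rng.random((2, 4, 16)).astype(np.float32)
        y = block.forward(x)
        for i, branch in enumerate(branches):
            assert np.allclose(y[:, 8 * i : 8 * (i + 1)], branch.forward(x))


class TestSpp:
    def test_seven_bins_per_channel_for_any_length(self, rng):
        spp = SpatialPyramidPool((1, 2, 4))
        for length in (4, 5, 7, 12, 50, 333):
            y = spp.forward(rng.random((2, 3, length)))
            assert y.shape == (2, 21)

    def test_constant_input_gives_constant_bins(self):
        spp = SpatialPyramidPool((1, 2, 4))
        y = spp.forward(np.full((1, 2, 10), 3.25))
        assert np.allclose(y, 3.25)

    def test_worked_example_length_four(self):
        spp = SpatialPyramidPool((1, 2, 4))
        y = spp.forward(np.array([[[1.0, 2.0, 3.0, 4.0]]]))
        assert np.allclose(y[0], [2.5, 1.5, 3.5, 1.0, 2.0, 3.0, 4.0])

    def test_level_one_is_global_mean(self, rng):
        spp = SpatialPyramidPool((1, 2, 4))
        x = rng.standard_normal((3, 5, 17))
        y = spp.forward(x).reshape(3, 5, 7)
        assert np.allclose(y[:, :, 0], x.mean(axis=2))

    def test_part_sizes_differ_by_at_most_one(self):
        for length in range(4, 60):
            for k in (1, 2, 4):
                cuts = SpatialPyramidPool._boundaries(length, k)
                sizes = np.diff(cuts)
                assert sizes.sum() == length and sizes.max() - sizes.min() <= 1

    def test_too_short_input_rejected(self):
        with pytest.raises(ModelConfigError):
            SpatialPyramidPool((1, 2, 4)).forward(np.zeros((1, 1, 3)))

    def test_invalid_levels_rejected(self):
        with pytest.raises(ModelConfigError):
            SpatialPyramidPool((2, 4))


SMALL = ModelConfig(branch_widths=(2, 2, 2, 2, 2), fc_widths=(16, 8),
                    dropout_rate=0.0, init_seed=0)


class TestModel:
    def test_output_shape_invariant_to_length(self):
        m = build_model(SMALL)
        for length in (200, 317, 555, 800):
            x = np.random.rand(2, 4, length).astype(np.float32)
            assert m.forward(x).shape == (2, 2)

    def test_fc_input_width_is_channels_times_bins(self):
        cfg = ModelConfig()
        assert cfg.final_conv_channels * sum(cfg.spp_levels) == 2688

    def test_default_parameter_count_matches_reference(self):
        assert count_parameters(build_model()) == 3_077_382

    def test_frozen_layers_not_counted(self):
        m = build_model(SMALL)
        for layer in m.layers:
            layer.trainable = False
        # containers hold no params themselves; freeze recursively
        stack = list(m.layers)
        while stack:
            l = stack.pop()
            l.trainable = False
            stack.extend(l.children())
        assert count_parameters(m) == 0

    def test_predict_probabilities_sum_to_one(self, rng):
        m = build_model(SMALL)
        batch = [rng.random((300, 4)) for _ in range(3)]
        probs = predict(m, batch)
        assert probs.shape == (3, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_final_layer_gives_uniform_probabilities(self, rng):
        m = build_model(SMALL)
        m.layers[-1].W[...] = 0.0
        m.layers[-1].b[...] = 0.0
        probs = predict(m, [rng.random((256, 4))])
        assert np.allclose(probs, 0.5, atol=1e-7)

    def test_eval_mode_deterministic(self, rng):
        m = build_model(ModelConfig(branch_widths=(2, 2, 2, 2, 2),
                                    fc_widths=(16, 8), dropout_rate=0.3,
                                    init_seed=0))
        x = rng.random((2, 4, 220)).astype(np.float32)
        a = m.predict_proba(x)
        b = m.predict_proba(x)
        assert np.array_equal(a, b)

    def test_mixed_lengths_in_batch_rejected(self, rng):
        m = build_model(SMALL)
        with pytest.raises(BatchError):
            predict(m, [rng.random((300, 4)), rng.random((400, 4))])

    def test_out_of_range_length_rejected(self, rng):
        m = build_model(SMALL)
        with pytest.raises(BatchError):
            predict(m, [rng.random((150, 4))])

    def test_checkpoint_round_trip(self, tmp_path, rng):
        m = build_model(SMALL)
        x = rng.random((2, 4, 300)).astype(np.float32)
        expected = m.predict_proba(x)
        path = tmp_path / "model.npz"
        save_checkpoint(path, m)
        back = load_checkpoint(path)
        assert np.allclose(back.predict_proba(x), expected, atol=0)
        assert back.config == m.config


class TestGradients:
    def test_full_model_backward_matches_finite_differences(self):
        # float64 end-to-end check on a tiny config (kinks avoided by
        # keeping perturbations small and retrying a fixed parameter set)
        cfg = ModelConfig(branch_widths=(2, 2, 2, 2, 2), fc_widths=(8, 6),
                          dropout_rate=0.0, init_seed=3)
        m = build_model(cfg)
        stack = [m]
        while stack:
            layer = stack.pop()
            for i, p in enumerate(layer.params):
                layer.params[i] = p.astype(np.float64)
                layer.grads[i] = np.zeros_like(layer.params[i])
            if hasattr(layer, "W"):
                layer.W, layer.b = layer.params
            if hasattr(layer, "gamma"):
                layer.gamma, layer.beta = layer.params
            stack.extend(layer.children())
        rng = np.random.default_rng(0)
        x = rng.random((3, 4, 210))
        y = np.array([0, 1, 1])
        m.zero_grad()
        loss, dl = cross_entropy(m.forward(x, train=True), y)
        m.backward(dl)
        params = dict(m.named_parameters())
        grads = dict(m.named_gradients())
        names = list(params)
        eps = 1e-6
        for name in [names[i] for i in rng.choice(len(names), 15, replace=False)]:
            p, g = params[name], grads[name]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            old = p[idx]
            p[idx] = old + eps
            lp, _ = cross_entropy(m.forward(x, train=True), y)
            p[idx] = old - eps
            lm, _ = cross_entropy(m.forward(x, train=True), y)
            p[idx] = old
            numeric = (lp - lm) / (2 * eps)
            assert numeric == pytest.approx(float(g[idx]), rel=1e-4, abs=1e-7), name
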