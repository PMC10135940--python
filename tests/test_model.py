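"""Architecture contracts: shapes, SE behaviour, parameter accounting."""

import math

import numpy as np
import pytest

from ppgbp.fixtures import se_toy_example
from ppgbp.model import (
    MSFEConfig, SEConfig, ModelConfig, MSFE, SEResidualBlock, MSAResNet,
    build_model, count_parameters, predict, save_checkpoint, load_checkpoint,
)
from ppgbp.nn.layers import Conv1d, SEBlock


def _sigmoid(v):
    return 1.0 / (1.0 + math.exp(-v))


class TestMSFE:
    def test_default_output_shape_64x188(self, rng):
        stem = MSFE(3, MSFEConfig(), rng=rng)
        y = stem.forward(rng.standard_normal((2, 3, 375)), training=True)
        assert y.shape == (2, 64, 188)

    @pytest.mark.parametrize("kernels", [(3, 5, 7), (3, 9, 11), (5, 7, 15)])
    def test_branch_lengths_equal_for_any_odd_kernels(self, rng, kernels):
        stem = MSFE(3, MSFEConfig(regular_kernels=kernels), rng=rng)
        outs = stem.branch_outputs(rng.standard_normal((1, 3, 375)), training=True)
        lengths = {o.shape[2] for o in outs}
        assert len(outs) == 4 and lengths == {188}

    def test_zero_input_zero_output(self, rng):
        stem = MSFE(3, MSFEConfig(), rng=rng)
        y = stem.forward(np.zeros((2, 3, 375)), training=True)
        np.testing.assert_allclose(y, 0.0, atol=1e-7)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            MSFEConfig(large_kernel=12).validate()

    def test_depthwise_separable_parameter_economy(self, rng):
        """Depthwise(13) + pointwise uses far fewer weights than a full
        kernel-13 convolution at the same channel widths."""
        stem = MSFE(3, MSFEConfig(), rng=rng)
        large_branch = stem.dw.n_params() + stem.pw.n_params()
        regular_13 = Conv1d(3, 16, 13, bias=False, rng=rng).n_params()
        # closed form: 3*13 + 3*16 = 87 vs 3*16*13 = 624
        assert large_branch == 3 * 13 + 3 * 16 == 87
        assert regular_13 == 3 * 16 * 13 == 624
        assert large_branch < regular_13

    def test_economy_holds_generally(self, rng):
        for cin, cout, k in [(2, 2, 3), (4, 8, 5), (8, 8, 13)]:
            sep = cin * k + cin * cout
            full = cin * cout * k
            assert sep < full


class TestSEBlock:
    def test_shape_preserved_and_weights_in_unit_interval(self, rng):
        se = SEBlock(8, reduction=4, rng=rng, dtype=np.float64)
        x = rng.standard_normal((3, 8, 20))
        y = se.forward(x)
        assert y.shape == x.shape
        s = se.attention(x)
        assert np.all(s > 0.0) and np.all(s < 1.0)

    def test_contraction_on_magnitudes(self, rng):
        se = SEBlock(8, reduction=4, rng=rng, dtype=np.float64)
        x = rng.standard_normal((3, 8, 20))
        y = se.forward(x)
        assert np.all(np.abs(y) <= np.abs(x) + 1e-12)

    def test_identity_limit_when_logits_large(self, rng):
        se = SEBlock(4, reduction=2, rng=rng, dtype=np.float64)
        se.fc2.w.data[...] = 0.0
        se.fc2.b.data[...] = 50.0  # sigmoid -> 1
        x = rng.standard_normal((2, 4, 10))
        np.testing.assert_allclose(se.forward(x), x, rtol=1e-9)

    def test_hand_computed_toy_example(self):
        """Squeeze/excite/scale reproduced with scalar arithmetic."""
        toy = se_toy_example()
        se = SEBlock(2, reduction=2, dtype=np.float64)
        se.fc1.w.data[...] = np.array(toy["fc1_w"])
        se.fc1.b.data[...] = np.array(toy["fc1_b"])
        se.fc2.w.data[...] = np.array(toy["fc2_w"])
        se.fc2.b.data[...] = np.array(toy["fc2_b"])
        x = np.array([toy["x"]])
        # by hand: z = [1, 0]; hidden = relu(1*1 + (-1)*0 + 0.5) = 1.5
        # logits = [2*1.5, -1*1.5]; s = [sigmoid(3), sigmoid(-1.5)]
        s0, s1 = _sigmoid(3.0), _sigmoid(-1.5)
        expected = np.array([[[s0, s0, s0], [0.0, 0.0, 0.0]]])
        np.testing.assert_allclose(se.forward(x), expected, rtol=1e-12)


class TestResidualBlock:
    def test_zero_residual_reduces_to_relu_identity(self, rng):
        blk = SEResidualBlock(4, 4, stride=1, se_reduction=2, rng=rng,
                              dtype=np.float64)
        blk.conv1.w.data[...] = 0.0
        blk.conv2.w.data[...] = 0.0
        x = rng.standard_normal((2, 4, 10))
        np.testing.assert_allclose(blk.forward(x, training=True), np.maximum(x, 0.0),
                                   atol=1e-12)

    def test_stride_two_halves_length(self, rng):
        blk = SEResidualBlock(4, 8, stride=2, se_reduction=2, rng=rng)
        for L in (10, 11, 64, 375):
            y = blk.forward(rng.standard_normal((1, 4, L)).astype(np.float32),
                            training=True)
            assert y.shape == (1, 8, -(-L // 2))

    def test_shortcut_carries_gradient_when_residual_zeroed(self, rng):
        blk = SEResidualBlock(4, 4, stride=1, se_reduction=2, rng=rng,
                              dtype=np.float64)
        blk.conv1.w.data[...] = 0.0
        blk.conv2.w.data[...] = 0.0
        x = np.abs(rng.standard_normal((2, 4, 10))) + 0.1  # all positive
        blk.forward(x, training=True)
        gx = blk.backward(np.ones((2, 4, 10)))
        assert np.abs(gx).max() > 0.0


class TestModel:
    def test_forward_shape_and_finiteness(self, rng):
        model = build_model(ModelConfig(width_multiplier=0.25), seed=0)
        y = model.forward(rng.standard_normal((4, 3, 375)).astype(np.float32))
        assert y.shape == (4, 2)
        assert np.all(np.isfinite(y))

    @pytest.mark.parametrize("length", [64, 100, 375])
    def test_stage_length_arithmetic(self, rng, length):
        cfg = ModelConfig(width_multiplier=0.125, input_length=length)
        model = build_model(cfg, seed=0)
        L = -(-length // 2)              # stem stride 2
        L = (L + 2 - 3) // 2 + 1         # max pool k3 s2 pad1
        for blk in model.blocks:
            L = -(-L // blk.stride)
        x = rng.standard_normal((1, 3, length)).astype(np.float32)
        h = model.stem.forward(x)
        h = model.pool.forward(h)
        for blk in model.blocks:
            h = blk.forward(h)
        assert h.shape[2] == L

    def test_width_multiplier_monotone_in_parameters(self):
        full = build_model(ModelConfig(width_multiplier=1.0))
        quarter = build_model(ModelConfig(width_multiplier=0.25))
        assert count_parameters(quarter) < count_parameters(full)

    def test_parameter_count_matches_closed_form(self):
        """Layer-by-layer sum computed independently of the implementation."""

        def se_params(c, r):
            h = max(1, c // r)
            return (c * h + h) + (h * c + c)

        def block_params(cin, cout, stride, r):
            n = 3 * cin * cout + 2 * cout      # conv1 (k3, no bias) + bn1
            n += 3 * cout * cout + 2 * cout    # conv2 + bn2
            n += se_params(cout, r)
            if stride != 1 or cin != cout:
                n += cin * cout + 2 * cout     # projection conv (k1) + bn
            return n

        for wm in (1.0, 0.25):
            cfg = ModelConfig(width_multiplier=wm)
            model = build_model(cfg, seed=1)
            sc = cfg.scaled
            bc, oc = sc(16), sc(64)
            expected = 0
            for k in (3, 5, 7):
                expected += 3 * bc * k + 2 * bc          # regular branches + bn
            expected += 3 * 13 + 3 * bc + 2 * bc         # depthwise + pointwise + bn
            expected += 4 * bc * oc + 2 * oc             # reshape conv + bn
            cin = oc
            for stage, (nb, ch) in enumerate(zip(cfg.blocks_per_stage, cfg.stage_channels)):
                cout = sc(ch)
                for b in range(nb):
                    stride = 2 if (stage > 0 and b == 0) else 1
                    expected += block_params(cin, cout, stride, cfg.se.reduction)
                    cin = cout
            expected += cin * 2 + 2                      # fc head
            assert count_parameters(model) == expected

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            ModelConfig(blocks_per_stage=(2, 2), stage_channels=(64,)).validate()
        with pytest.raises(ValueError, match="stage width"):
            ModelConfig(msfe=MSFEConfig(out_channels=32)).validate()


class TestPredict:
    @pytest.fixture(scope="class")
    def tiny_model(self):
        cfg = ModelConfig(blocks_per_stage=(1, 1), stage_channels=(8, 16),
                          msfe=MSFEConfig(branch_channels=2, out_channels=8),
                          se=SEConfig(reduction=4))
        return build_model(cfg, seed=3)

    def test_inference_deterministic(self, tiny_model, rng):
        x = rng.standard_normal((5, 3, 375)).astype(np.float32)
        np.testing.assert_array_equal(predict(tiny_model, x), predict(tiny_model, x))

    def test_batch_independence(self, tiny_model, rng):
        x = rng.standard_normal((8, 3, 375)).astype(np.float32)
        batched = predict(tiny_model, x)
        single = predict(tiny_model, x[3])
        np.testing.assert_allclose(single[0], batched[3], atol=1e-5)

    def test_seeded_init_reproducible(self, rng):
        cfg = ModelConfig(blocks_per_stage=(1, 1), stage_channels=(8, 16),
                          msfe=MSFEConfig(branch_channels=2, out_channels=8))
        x = rng.standard_normal((2, 3, 375)).astype(np.float32)
        a = predict(build_model(cfg, seed=9), x)
        b = predict(build_model(cfg, seed=9), x)
        np.testing.assert_array_equal(a, b)

    def test_wrong_channel_count_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError, match="expected input"):
            tiny_model.forward(rng.standard_normal((2, 5, 375)))

    def test_checkpoint_round_trip(self, tiny_model, rng, tmp_path):
        x = rng.standard_normal((4, 3, 375)).astype(np.float32)
        before = predict(tiny_model, x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, tiny_model, extra={"note": "round-trip"})
        loaded, extra = load_checkpoint(path)
        assert extra == {"note": "round-trip"}
        np.testing.assert_array_equal(predict(loaded, x), before)
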