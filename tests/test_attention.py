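"""GCSA stages against loop-based oracles, invariants, and bookkeeping."""

import numpy as np
import pytest

from gcsaseg.attention import (GCSA, BatchNormState, ChannelAttentionParams,
                               SpatialAttentionParams, channel_attention,
                               channel_shuffle, channel_unshuffle, gcsa_apply,
                               gcsa_param_count, init_channel_attention_params,
                               init_spatial_attention_params, spatial_attention)
from gcsaseg.exceptions import ConfigurationError, ShapeError
from gcsaseg.nn.tensor import Tensor, no_grad
from oracle_utils import (channel_attention_loops, channel_shuffle_loops,
                          sigmoid, spatial_attention_loops)


# ---------------------------------------------------------------------------
# channel attention
# ---------------------------------------------------------------------------

class TestChannelAttention:
    def test_zero_input_stays_zero(self, ca_params4):
        x = np.zeros((2, 4, 3, 3))
        assert not channel_attention(x, ca_params4).any()

    def test_zero_weights_halve_the_input(self, rng):
        p = ChannelAttentionParams(np.zeros((1, 4)), np.zeros(1),
                                   np.zeros((4, 1)), np.zeros(4))
        x = rng.standard_normal((1, 4, 2, 2))
        np.testing.assert_allclose(channel_attention(x, p), 0.5 * x, rtol=1e-6)

    def test_straight_line_example(self):
        # C=4, single pixel [1,2,3,4]; gate = sigmoid(relu(0.1 * 10)) = sigmoid(1)
        p = ChannelAttentionParams(0.1 * np.ones((1, 4)), np.zeros(1),
                                   np.ones((4, 1)), np.zeros(4))
        x = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 4, 1, 1)
        expected = sigmoid(1.0) * x
        np.testing.assert_allclose(channel_attention(x, p), expected, rtol=1e-6)

    @pytest.mark.parametrize("shape", [(1, 4, 2, 2), (2, 8, 1, 2), (1, 16, 2, 2)])
    def test_matches_loop_oracle(self, rng, shape):
        p = init_channel_attention_params(shape[1], rng)
        x = rng.standard_normal(shape)
        np.testing.assert_allclose(channel_attention(x, p),
                                   channel_attention_loops(x, p), rtol=1e-6)

    def test_channel_mismatch_raises(self, ca_params4, rng):
        with pytest.raises(ShapeError):
            channel_attention(rng.standard_normal((1, 8, 2, 2)), ca_params4)

    def test_indivisible_width_raises(self, rng):
        p = init_channel_attention_params(4, rng)
        with pytest.raises(ConfigurationError):
            channel_attention(rng.standard_normal((1, 6, 2, 2)), p)


# ---------------------------------------------------------------------------
# channel shuffle
# ---------------------------------------------------------------------------

class TestChannelShuffle:
    def test_c4_is_identity(self, rng):
        x = rng.standard_normal((2, 4, 3, 3))
        np.testing.assert_array_equal(channel_shuffle(x, 4), x)

    def test_c8_order(self):
        x = np.arange(8, dtype=np.float32).reshape(1, 8, 1, 1)
        np.testing.assert_array_equal(channel_shuffle(x, 4).ravel(),
                                      [0, 2, 4, 6, 1, 3, 5, 7])

    @pytest.mark.parametrize("c,groups", [(8, 4), (16, 4), (12, 4), (8, 2)])
    def test_matches_brute_force_index_map(self, rng, c, groups):
        x = rng.standard_normal((2, c, 2, 3))
        np.testing.assert_array_equal(channel_shuffle(x, groups),
                                      channel_shuffle_loops(x, groups))

    @pytest.mark.parametrize("c", [8, 16, 20])
    def test_roundtrip_is_bitwise_identity(self, rng, c):
        x = rng.standard_normal((1, c, 2, 2)).astype(np.float32)
        np.testing.assert_array_equal(channel_unshuffle(channel_shuffle(x, 4), 4), x)

    def test_values_are_permuted_not_altered(self, rng):
        x = rng.standard_normal((3, 8, 2, 2))
        y = channel_shuffle(x, 4)
        np.testing.assert_array_equal(np.sort(y, axis=1), np.sort(x, axis=1))

    def test_indivisible_raises(self, rng):
        with pytest.raises(ConfigurationError):
            channel_shuffle(rng.standard_normal((1, 6, 2, 2)), 4)


# ---------------------------------------------------------------------------
# spatial attention
# ---------------------------------------------------------------------------

class TestSpatialAttention:
    def test_zero_input_stays_zero(self, sa_params4):
        x = np.zeros((1, 4, 3, 3))
        assert not spatial_attention(x, sa_params4, mode="eval").any()

    def test_single_pixel_keeps_shape(self, rng, sa_params4):
        x = rng.standard_normal((2, 4, 1, 1))
        assert spatial_attention(x, sa_params4, mode="eval").shape == (2, 4, 1, 1)

    def test_center_tap_straight_line_example(self):
        # H=W=1 so only the center tap of each 7x7 kernel touches the pixel.
        c1 = np.zeros((1, 4, 7, 7))
        c1[0, :, 3, 3] = [0.1, 0.2, 0.3, 0.4]
        c2 = np.zeros((4, 1, 7, 7))
        c2[:, 0, 3, 3] = [1.0, -1.0, 0.5, 0.25]
        bn1 = BatchNormState(np.ones(1), np.zeros(1), np.zeros(1), np.ones(1), eps=0.0)
        bn2 = BatchNormState(np.ones(4), np.zeros(4), np.zeros(4), np.ones(4), eps=0.0)
        p = SpatialAttentionParams(c1, np.zeros(1), bn1, c2, np.zeros(4), bn2)
        x = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 4, 1, 1)
        hidden = 0.1 * 1 + 0.2 * 2 + 0.3 * 3 + 0.4 * 4      # = 3.0, relu keeps it
        gate = sigmoid(3.0 * np.array([1.0, -1.0, 0.5, 0.25]))
        np.testing.assert_allclose(
            spatial_attention(x, p, mode="eval").ravel(),
            gate * np.array([1.0, 2.0, 3.0, 4.0]), rtol=1e-6)
        assert hidden == 3.0

    @pytest.mark.parametrize("shape,mode", [((1, 4, 2, 2), "eval"),
                                            ((2, 4, 2, 2), "train"),
                                            ((1, 8, 2, 2), "eval")])
    def test_matches_loop_oracle(self, rng, shape, mode):
        p = init_spatial_attention_params(shape[1], rng)
        p.bn1.running_mean[:] = rng.standard_normal(p.bn1.running_mean.size) * 0.1
        p.bn2.running_var[:] = 1.0 + rng.random(p.bn2.running_var.size)
        x = rng.standard_normal(shape)
        np.testing.assert_allclose(spatial_attention(x, p, mode=mode),
                                   spatial_attention_loops(x, p, mode=mode),
                                   rtol=1e-6, atol=1e-9)

    def test_channel_mismatch_raises(self, rng, sa_params4):
        with pytest.raises(ShapeError):
            spatial_attention(rng.standard_normal((1, 8, 2, 2)), sa_params4)


# ---------------------------------------------------------------------------
# composition, gating bound, differentiability, bookkeeping
# ---------------------------------------------------------------------------

class TestGcsaComposition:
    def test_zero_input_stays_zero(self, ca_params4, sa_params4):
        out = gcsa_apply(np.zeros((1, 4, 2, 2)), ca_params4, sa_params4)
        assert not out.any()

    def test_equals_manual_stage_composition(self, rng):
        ca = init_channel_attention_params(8, rng)
        sa = init_spatial_attention_params(8, rng)
        x = rng.standard_normal((2, 8, 3, 3))
        manual = spatial_attention(channel_shuffle(channel_attention(x, ca)), sa)
        np.testing.assert_array_equal(gcsa_apply(x, ca, sa), manual)

    @pytest.mark.parametrize("c", [32, 64, 160, 256])
    def test_shape_preserved_at_backbone_widths(self, rng, c):
        ca = init_channel_attention_params(c, rng)
        sa = init_spatial_attention_params(c, rng)
        x = rng.standard_normal((1, c, 4, 4)).astype(np.float32)
        assert gcsa_apply(x, ca, sa).shape == x.shape

    def test_module_equals_functional_with_exported_params(self, rng):
        blk = GCSA(8, np.random.default_rng(5))
        blk.eval()
        x = rng.standard_normal((2, 8, 4, 4)).astype(np.float32)
        with no_grad():
            y_mod = blk(Tensor(x)).data
        ca, sa = blk.export_params()
        np.testing.assert_allclose(y_mod, gcsa_apply(x, ca, sa, mode="eval"),
                                   rtol=1e-5, atol=1e-6)

    def test_gating_bound_both_attention_stages(self, rng):
        ca = init_channel_attention_params(8, rng)
        sa = init_spatial_attention_params(8, rng)
        for _ in range(50):
            x = rng.standard_normal((1, 8, 2, 2)) * rng.uniform(0.1, 10)
            assert (np.abs(channel_attention(x, ca)) <= np.abs(x)).all()
            assert (np.abs(spatial_attention(x, sa)) <= np.abs(x)).all()

    def test_gradient_flows_and_matches_finite_differences(self):
        blk = GCSA(4, np.random.default_rng(3))
        blk.train()
        x = np.random.default_rng(9).standard_normal((2, 4, 3, 3)).astype(np.float32)

        def run():
            t = Tensor(x, requires_grad=True)
            out = blk(t)
            return t, (out * out).sum()

        t, loss = run()
        loss.backward()
        assert np.isfinite(t.grad).all() and np.abs(t.grad).max() > 0
        # spot-check <= 32 scalars of the input gradient by central differences
        flat_idx = np.random.default_rng(0).choice(x.size, size=16, replace=False)
        eps = 1e-2
        for i in flat_idx:
            xp, xm = x.copy().ravel(), x.copy().ravel()
            xp[i] += eps
            xm[i] -= eps
            blk.train()
            with no_grad():
                lp = (blk(Tensor(xp.reshape(x.shape))) ** 2.0).sum().item()
                lm = (blk(Tensor(xm.reshape(x.shape))) ** 2.0).sum().item()
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(float(t.grad.ravel()[i]), rel=0.08, abs=2e-2)


class TestParamCount:
    @pytest.mark.parametrize("c", [4, 8, 32, 160])
    def test_matches_module_parameter_enumeration(self, c):
        blk = GCSA(c, np.random.default_rng(0))
        enumerated = sum(p.data.size for p in blk.parameters())
        assert gcsa_param_count(c) == enumerated

    def test_c32_breakdown(self):
        # MLP 552 + spatial path 25,208 under the stated conventions
        assert gcsa_param_count(32) == 552 + 25208 == 25760

    def test_quadratic_growth(self):
        for c in (8, 16, 32, 64):
            ratio = gcsa_param_count(2 * c) / gcsa_param_count(c)
            assert 3.4 < ratio < 4.2

    def test_indivisible_raises(self):
        with pytest.raises(ConfigurationError):
            gcsa_param_count(6)
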