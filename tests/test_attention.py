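"""Attention block unit tests: pooling, gating, closed forms, loop oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sran.attention import (
    BlockParams,
    attention_block_forward,
    channel_attention_apply,
    channel_attention_weights,
    global_average_pool,
    global_max_pool,
    reverse_attention_forward,
    spatial_attention_apply,
    spatial_attention_weights,
    srab_forward,
)

from _oracles import (
    attention_block_oracle,
    channel_attention_oracle,
    gap_oracle,
    gmp_oracle,
    randomize_block,
    reverse_attention_oracle,
    spatial_attention_oracle,
    srab_oracle,
)

LN2 = math.log(2.0)


class TestGlobalPooling:
    def test_hand_examples(self):
        x = np.array([[1.0, 3.0], [5.0, 7.0]])[:, :, None]
        assert global_average_pool(x) == pytest.approx([4.0])
        assert global_max_pool(x) == pytest.approx([7.0])

    def test_constant_map_pools_to_constant(self):
        x = np.full((5, 7, 3), 2.5)
        assert global_average_pool(x) == pytest.approx([2.5] * 3)
        assert global_max_pool(x) == pytest.approx([2.5] * 3)

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=(4, 4, 3))
        assert global_average_pool(x) == pytest.approx(gap_oracle(x), abs=1e-6)
        np.testing.assert_array_equal(global_max_pool(x), gmp_oracle(x))

    def test_batch_axis_accepted(self, rng):
        x = rng.normal(size=(2, 4, 4, 3))
        out = global_average_pool(x)
        assert out.shape == (2, 3)
        assert out[1] == pytest.approx(gap_oracle(x[1]), abs=1e-6)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            global_average_pool(np.zeros((0, 3, 2)))
        with pytest.raises(ValueError):
            global_max_pool(np.zeros((3, 0, 2)))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(arrays(np.float64, (3, 5, 4), elements=st.floats(-50, 50)))
    def test_max_pool_dominates_average_pool(self, x):
        gap, gmp = global_average_pool(x), global_max_pool(x)
        assert np.all(gmp >= gap - 1e-12)
        constant = np.ptp(x.reshape(-1, x.shape[2]), axis=0) == 0
        np.testing.assert_array_equal(np.isclose(gmp, gap), constant)


class TestChannelAttention:
    def test_zero_parameters_halve_the_input(self, rng):
        p = BlockParams.for_attention(4).zero_()
        x = rng.normal(size=(5, 5, 4))
        np.testing.assert_allclose(channel_attention_apply(x, p), 0.5 * x)

    def test_saturated_gate_is_identity(self, rng):
        p = BlockParams.for_attention(4).zero_()
        p.channel_dense.b.data[:] = 20.0
        x = rng.normal(size=(5, 5, 4))
        np.testing.assert_allclose(channel_attention_apply(x, p), x, atol=1e-6)

    def test_matches_loop_oracle(self, rng):
        p = randomize_block(BlockParams.for_attention(3), rng)
        x = rng.normal(size=(6, 5, 3))
        expected = channel_attention_oracle(
            x, p.channel_dense.w.data, p.channel_dense.b.data
        )
        np.testing.assert_allclose(channel_attention_apply(x, p), expected, atol=1e-5)

    def test_weights_lie_strictly_in_unit_interval(self, rng):
        p = randomize_block(BlockParams.for_attention(6), rng)
        w = channel_attention_weights(rng.normal(size=(4, 4, 6)), p)
        assert np.all((w > 0) & (w < 1))

    def test_channel_mismatch_rejected(self, rng):
        p = BlockParams.for_attention(4)
        with pytest.raises(ValueError, match="channels"):
            channel_attention_apply(rng.normal(size=(5, 5, 3)), p)


class TestSpatialAttention:
    def test_zero_parameters_halve_the_input(self, rng):
        p = BlockParams.for_attention(4).zero_()
        x = rng.normal(size=(6, 6, 4))
        np.testing.assert_allclose(spatial_attention_apply(x, p), 0.5 * x)

    def test_single_channel_pools_degenerate_to_identity(self, rng):
        x = rng.normal(size=(5, 5, 1))
        np.testing.assert_allclose(x.mean(axis=2), x.max(axis=2))

    def test_matches_loop_oracle(self, rng):
        p = randomize_block(BlockParams.for_attention(3), rng)
        x = rng.normal(size=(6, 6, 3))
        expected = spatial_attention_oracle(
            x, p.spatial_conv.w.data, p.spatial_conv.b.data
        )
        np.testing.assert_allclose(spatial_attention_apply(x, p), expected, atol=1e-5)

    def test_gating_shrinks_every_nonzero_entry(self, rng):
        p = randomize_block(BlockParams.for_attention(3), rng)
        x = rng.normal(size=(5, 5, 3))
        gated = spatial_attention_apply(x, p)
        nz = x != 0
        assert np.all(np.abs(gated[nz]) < np.abs(x[nz]))
        w = spatial_attention_weights(x, p)
        assert np.all((w > 0) & (w < 1))


class TestSelfResidualAttentionBlock:
    def test_shape_propagation(self, rng):
        p = BlockParams.for_srab(4, 6)
        out = srab_forward(rng.normal(size=(8, 8, 4)), p)
        assert out.shape == (8, 8, 6)

    def test_zero_parameters_reduce_to_residual_plus_constant(self, rng):
        p = BlockParams.for_srab(4, 4).zero_()
        x = rng.normal(size=(6, 6, 4))
        np.testing.assert_allclose(srab_forward(x, p), x + 0.25 * LN2, atol=1e-4)

    @pytest.mark.parametrize("c_in,filters", [(3, 3), (4, 6)])
    def test_matches_reference_oracle(self, rng, c_in, filters):
        p = randomize_block(BlockParams.for_srab(c_in, filters), rng)
        x = rng.normal(size=(5, 5, c_in))
        np.testing.assert_allclose(srab_forward(x, p), srab_oracle(x, p), atol=1e-5)

    def test_projection_only_when_channels_differ(self):
        assert BlockParams.for_srab(4, 4).res_proj is None
        assert BlockParams.for_srab(4, 6).res_proj is not None

    def test_inference_is_bitwise_deterministic(self, rng):
        p = randomize_block(BlockParams.for_srab(3, 5), rng)
        x = rng.normal(size=(7, 7, 3))
        np.testing.assert_array_equal(srab_forward(x, p), srab_forward(x, p))

    def test_non_finite_input_rejected(self, rng):
        p = BlockParams.for_srab(3, 3)
        x = rng.normal(size=(4, 4, 3))
        x[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            srab_forward(x, p)

    def test_non_finite_intermediate_names_the_stage(self, rng):
        p = BlockParams.for_srab(3, 3)
        p.bn.running_var[:] = -1.0  # sqrt of negative variance -> NaN
        with pytest.raises(FloatingPointError, match="preamble"):
            srab_forward(rng.normal(size=(4, 4, 3)), p)


class TestAttentionBlock:
    def test_zero_parameters_quarter_the_input(self, rng):
        p = BlockParams.for_attention(5).zero_()
        x = rng.normal(size=(6, 6, 5))
        np.testing.assert_allclose(attention_block_forward(x, p), 0.25 * x)

    def test_saturated_gates_approach_identity(self, rng):
        p = BlockParams.for_attention(5).zero_()
        p.channel_dense.b.data[:] = 25.0
        p.spatial_conv.b.data[:] = 25.0
        x = rng.normal(size=(6, 6, 5))
        np.testing.assert_allclose(attention_block_forward(x, p), x, atol=1e-6)

    def test_matches_loop_oracle(self, rng):
        p = randomize_block(BlockParams.for_attention(4), rng)
        x = rng.normal(size=(6, 6, 4))
        np.testing.assert_allclose(
            attention_block_forward(x, p), attention_block_oracle(x, p), atol=1e-5
        )

    def test_shape_preserved(self, rng):
        p = BlockParams.for_attention(4)
        assert attention_block_forward(rng.normal(size=(8, 8, 4)), p).shape == (8, 8, 4)


class TestReverseAttentionBlock:
    def test_zero_parameters_give_half_log_two(self, rng):
        p = BlockParams.for_reverse(4, 3).zero_()
        out = reverse_attention_forward(rng.normal(size=(6, 6, 4)), p)
        np.testing.assert_allclose(out, 0.5 * LN2, atol=1e-4)

    def test_shape_propagation(self, rng):
        p = BlockParams.for_reverse(4, 3)
        assert reverse_attention_forward(rng.normal(size=(8, 8, 4)), p).shape == (8, 8, 3)

    def test_matches_reference_oracle(self, rng):
        p = randomize_block(BlockParams.for_reverse(3, 4), rng)
        x = rng.normal(size=(5, 5, 3))
        np.testing.assert_allclose(
            reverse_attention_forward(x, p), reverse_attention_oracle(x, p), atol=1e-5
        )

    def test_complement_gate_flips_the_weights(self, rng):
        plain = BlockParams.for_reverse(3, 4).zero_()
        flipped = BlockParams.for_reverse(3, 4, complement_gate=True).zero_()
        x = rng.normal(size=(5, 5, 3))
        # zero parameters: both gates are exactly 1/2, so outputs coincide;
        # with a biased gate they must differ
        np.testing.assert_allclose(
            reverse_attention_forward(x, plain), reverse_attention_forward(x, flipped)
        )
        plain.channel_dense.b.data[:] = 2.0
        flipped.channel_dense.b.data[:] = 2.0
        a = reverse_attention_forward(x, plain)
        b = reverse_attention_forward(x, flipped)
        expected_ratio = (1 - 1 / (1 + math.exp(-2.0))) / (1 / (1 + math.exp(-2.0)))
        np.testing.assert_allclose(b, a * expected_ratio, atol=1e-8)
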