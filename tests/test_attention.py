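"""Attention blocks against brute-force formula oracles and their invariants."""

import numpy as np
import pytest

import _oracles as oracle
from dstan.attention import (
    ChannelAttention,
    FeatureMap,
    SpatialAttention,
    TemporalAttention,
    dual_pool_channel_attention,
    multiscale_spatial_attention,
    temporal_attention,
)


def _zeroed(module):
    for p in module.parameters():
        p.data[...] = 0.0
    return module


class TestSpatialAttention:
    def test_matches_direct_formula_evaluation(self, rng):
        for trial in range(20):
            state = SpatialAttention(4, np.random.default_rng(trial)).astype(np.float64)
            x = rng.standard_normal((4, 5, 5))
            refined, _ = multiscale_spatial_attention(FeatureMap(x, "low"), state)
            expected, sa = oracle.spatial_attention_oracle(x, state)
            np.testing.assert_allclose(refined.values, expected, atol=1e-5)
            np.testing.assert_allclose(state.weight_map, sa, atol=1e-5)

    def test_zero_parameters_give_half_weights(self, rng):
        state = _zeroed(SpatialAttention(3, rng))
        x = rng.standard_normal((3, 6, 6)).astype(np.float32)
        refined, _ = multiscale_spatial_attention(FeatureMap(x, "low"), state)
        np.testing.assert_allclose(state.weight_map, 0.5, atol=1e-7)
        np.testing.assert_allclose(refined.values, 0.5 * x, atol=1e-6)

    def test_attenuation_bound(self, rng):
        state = SpatialAttention(4, rng)
        x = rng.standard_normal((4, 8, 8)).astype(np.float32)
        refined, _ = multiscale_spatial_attention(FeatureMap(x, "low"), state)
        assert np.all(np.abs(refined.values) <= np.abs(x) + 1e-7)
        assert np.all(state.weight_map > 0) and np.all(state.weight_map < 1)

    def test_channel_mismatch_raises(self, rng):
        state = SpatialAttention(4, rng)
        with pytest.raises(ValueError, match="channel"):
            multiscale_spatial_attention(FeatureMap(rng.standard_normal((3, 5, 5))), state)

    def test_commutes_with_channel_permutation_of_kernels(self, rng):
        state = SpatialAttention(5, rng).astype(np.float64)
        x = rng.standard_normal((5, 6, 6))
        perm = rng.permutation(5)
        out, _ = multiscale_spatial_attention(FeatureMap(x), state)
        permuted = SpatialAttention(5, rng).astype(np.float64)
        for src, dst in (("conv1", "conv1"), ("conv2", "conv2"), ("conv3", "conv3"),
                         ("conv4", "conv4")):
            getattr(permuted, dst).weight.data = getattr(state, src).weight.data.copy()
            getattr(permuted, dst).bias.data = getattr(state, src).bias.data.copy()
        for name in ("conv1", "conv2", "conv3"):
            conv = getattr(permuted, name)
            conv.weight.data = conv.weight.data[:, perm]
        out_p, _ = multiscale_spatial_attention(FeatureMap(x[perm]), permuted)
        np.testing.assert_allclose(out_p.values, out.values[perm], atol=1e-10)


class TestChannelAttention:
    def test_matches_direct_formula_evaluation(self, rng):
        for trial in range(20):
            state = ChannelAttention(8, 2, np.random.default_rng(trial)).astype(np.float64)
            x = rng.standard_normal((8, 3, 3))
            refined, _ = dual_pool_channel_attention(FeatureMap(x, "high"), state)
            expected, ca = oracle.channel_attention_oracle(x, state)
            np.testing.assert_allclose(refined.values, expected, atol=1e-5)
            np.testing.assert_allclose(state.weight_vector, ca, atol=1e-5)

    def test_zero_parameters_give_half_weights(self, rng):
        state = _zeroed(ChannelAttention(4, 2, rng))
        x = rng.standard_normal((4, 5, 5)).astype(np.float32)
        refined, _ = dual_pool_channel_attention(FeatureMap(x, "high"), state)
        np.testing.assert_allclose(state.weight_vector, 0.5, atol=1e-7)
        np.testing.assert_allclose(refined.values, 0.5 * x, atol=1e-6)

    def test_constant_channels_pool_to_constants(self, rng):
        state = ChannelAttention(4, 2, rng)
        consts = np.array([0.1, -0.4, 2.0, 0.0])
        x = np.broadcast_to(consts[:, None, None], (4, 6, 6)).copy()
        dual_pool_channel_attention(FeatureMap(x, "high"), state)
        np.testing.assert_allclose(state.gap_vector, consts, atol=1e-6)
        np.testing.assert_allclose(state.gmp_vector, consts, atol=1e-6)

    def test_indivisible_ratio_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            ChannelAttention(6, 4, rng)

    def test_invariant_to_spatial_permutation(self, rng):
        state = ChannelAttention(8, 4, rng).astype(np.float64)
        x = rng.standard_normal((8, 4, 4))
        dual_pool_channel_attention(FeatureMap(x, "high"), state)
        gap1, gmp1, ca1 = (state.gap_vector.copy(), state.gmp_vector.copy(),
                           state.weight_vector.copy())
        flat = x.reshape(8, -1)
        perm = rng.permutation(16)
        x2 = flat[:, perm].reshape(8, 4, 4)
        dual_pool_channel_attention(FeatureMap(x2, "high"), state)
        # gap is a mean: permutation only reorders the summation, so agreement
        # is exact up to float reassociation; gmp (a max) is bitwise identical
        np.testing.assert_allclose(state.gap_vector, gap1, rtol=0, atol=1e-13)
        np.testing.assert_array_equal(state.gmp_vector, gmp1)
        np.testing.assert_allclose(state.weight_vector, ca1, rtol=0, atol=1e-13)


class TestTemporalAttention:
    def test_matches_scalar_closed_form(self, rng):
        for trial in range(20):
            state = TemporalAttention(16, np.random.default_rng(trial)).astype(np.float64)
            s = rng.standard_normal((9, 16))
            weighted, weights = temporal_attention(s, state)
            exp_w, exp_r = oracle.temporal_attention_oracle(
                s, state.u.data, float(state.b.data[0]))
            np.testing.assert_allclose(weights, exp_r, atol=1e-6)
            np.testing.assert_allclose(weighted, exp_w, atol=1e-6)

    def test_zero_parameters_halve_the_input(self, rng):
        state = _zeroed(TemporalAttention(8, rng))
        s = rng.standard_normal((5, 8)).astype(np.float32)
        weighted, weights = temporal_attention(s, state)
        np.testing.assert_allclose(weights, 0.5)
        np.testing.assert_allclose(weighted, 0.5 * s, atol=1e-7)

    def test_single_frame_sequence(self, rng):
        state = TemporalAttention(4, rng)
        s = rng.standard_normal((1, 4)).astype(np.float32)
        weighted, weights = temporal_attention(s, state)
        assert weights.shape == (1,)
        assert 0 < weights[0] < 1
        np.testing.assert_allclose(weighted[0], weights[0] * s[0], rtol=1e-6)

    def test_ragged_features_rejected(self, rng):
        state = TemporalAttention(4, rng)
        with pytest.raises(ValueError):
            temporal_attention(np.zeros((3,)), state)

    def test_monotone_in_logit_shift(self, rng):
        # doubling the projection shifts every weight towards its sigmoid limit
        state = TemporalAttention(6, rng).astype(np.float64)
        s = rng.standard_normal((7, 6))
        _, w1 = temporal_attention(s, state)
        z = s @ state.u.data + state.b.data[0]
        state.u.data *= 2.0
        state.b.data *= 2.0
        _, w2 = temporal_attention(s, state)
        assert np.all((w2 >= w1) == (z >= 0))


def test_weights_always_strictly_inside_unit_interval(rng):
    """Across many random instances all three mechanisms stay in (0, 1)."""
    for trial in range(30):
        r = np.random.default_rng(trial)
        sa = SpatialAttention(3, r)
        ca = ChannelAttention(4, 2, r)
        ta = TemporalAttention(5, r)
        x = r.standard_normal((3, 4, 4)).astype(np.float32)
        multiscale_spatial_attention(FeatureMap(x), sa)
        dual_pool_channel_attention(FeatureMap(r.standard_normal((4, 3, 3)).astype(np.float32)), ca)
        temporal_attention(r.standard_normal((4, 5)).astype(np.float32), ta)
        for w in (sa.weight_map, ca.weight_vector, ta.frame_weights):
            assert np.all(w > 0) and np.all(w < 1)
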