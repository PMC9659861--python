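"""Behavioural contracts of the attention families: closed-form values,
equivalence identities between variants, locality, and shape preservation."""

import numpy as np
import pytest

from mcvit._autograd import Tensor, no_grad
from mcvit.attention import (
    AttentionConfig,
    GlobalBlock,
    LocalBlock,
    MultiHeadSelfAttention,
    SpatialReductionAttention,
    WindowMSA,
    relative_position_index,
    scaled_attention,
)


class TestScaledAttention:
    def test_zero_scores_average_values(self, rng):
        v = rng.normal(size=(1, 5, 3))
        q = k = Tensor(np.zeros((1, 5, 3)))
        out = scaled_attention(q, k, Tensor(v))
        assert np.allclose(out.data, np.broadcast_to(v.mean(axis=1, keepdims=True),
                                                     v.shape))

    def test_hand_computed_two_token_case(self):
        q = Tensor([[[1.0], [0.0]]])
        k = Tensor([[[1.0], [0.0]]])
        v = Tensor([[[1.0], [2.0]]])
        out = scaled_attention(q, k, v)  # d=1 so the scale is 1
        expected_row0 = (np.e * 1 + 1 * 2) / (np.e + 1)
        assert np.isclose(out.data[0, 0, 0], expected_row0, atol=1e-4)
        assert np.isclose(out.data[0, 0, 0], 1.2689, atol=1e-4)

    def test_large_negative_off_diagonal_bias_selects_self(self, rng):
        n, d = 4, 3
        v = rng.normal(size=(1, n, d))
        bias = np.full((n, n), -1e9)
        np.fill_diagonal(bias, 0.0)
        out = scaled_attention(Tensor(rng.normal(size=(1, n, d))),
                               Tensor(rng.normal(size=(1, n, d))),
                               Tensor(v), bias=Tensor(bias))
        assert np.allclose(out.data, v, atol=1e-6)

    def test_attention_rows_sum_to_one(self, rng):
        q, k, v = (Tensor(rng.normal(size=(2, 6, 4))) for _ in range(3))
        _, attn = scaled_attention(q, k, v, return_attn=True)
        assert np.allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_rejects_non_finite_inputs(self):
        bad = Tensor(np.array([[[np.nan]]]))
        ok = Tensor(np.ones((1, 1, 1)))
        with pytest.raises(ValueError, match="non-finite"):
            scaled_attention(bad, ok, ok)

    def test_inv_dim_scaling_differs(self, rng):
        q, k, v = (Tensor(rng.normal(size=(1, 4, 4))) for _ in range(3))
        a = scaled_attention(q, k, v, attn_scale="rsqrt").data
        b = scaled_attention(q, k, v, attn_scale="inv_dim").data
        assert not np.allclose(a, b)


class TestMSA:
    def test_shape_preserved(self, rng):
        msa = MultiHeadSelfAttention(16, 2, rng)
        x = Tensor(rng.normal(size=(2, 9, 16)))
        assert msa(x).shape == (2, 9, 16)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            MultiHeadSelfAttention(10, 3, rng)

    def test_permutation_equivariance(self, rng):
        msa = MultiHeadSelfAttention(8, 2, rng)
        x = rng.normal(size=(1, 7, 8))
        perm = rng.permutation(7)
        with no_grad():
            a = msa(Tensor(x)).data[:, perm]
            b = msa(Tensor(x[:, perm])).data
        assert np.allclose(a, b, atol=1e-10)

    def test_zero_value_projection_gives_bias(self, rng):
        msa = MultiHeadSelfAttention(8, 2, rng)
        c = 8
        msa.qkv.weight.data[:, 2 * c:] = 0.0   # value projection
        msa.qkv.bias.data[2 * c:] = 0.0
        msa.proj.bias.data[:] = 1.5
        x = Tensor(rng.normal(size=(1, 4, 8)))
        assert np.allclose(msa(x).data, 1.5)

    def test_single_token_closed_form(self, rng):
        """With one token attention weights are exactly 1, so the output is
        the projected value vector."""
        msa = MultiHeadSelfAttention(6, 2, rng)
        x = rng.normal(size=(1, 1, 6))
        v = x @ msa.qkv.weight.data[:, 12:] + msa.qkv.bias.data[12:]
        expected = v @ msa.proj.weight.data + msa.proj.bias.data
        assert np.allclose(msa(Tensor(x)).data, expected, atol=1e-12)


class TestGlobalBlock:
    def test_zero_residual_branches_give_identity(self, rng):
        blk = GlobalBlock(8, 2, 2.0, rng)
        for p in blk.parameters():
            p.data[:] = 0.0
        x = rng.normal(size=(1, 5, 8))
        assert np.allclose(blk(Tensor(x)).data, x)

    def test_shape_preserved_at_stage2_scale(self, rng):
        blk = GlobalBlock(32, 4, 4.0, rng)
        x = Tensor(rng.normal(size=(1, 16, 32)))
        assert blk(x).shape == (1, 16, 32)


def _copy_msa_weights_to_window(msa, wmsa):
    wmsa.qkv.weight.data = msa.qkv.weight.data.copy()
    wmsa.qkv.bias.data = msa.qkv.bias.data.copy()
    wmsa.proj.weight.data = msa.proj.weight.data.copy()
    wmsa.proj.bias.data = msa.proj.bias.data.copy()
    wmsa.bias_table.data[:] = 0.0


class TestWindowMSA:
    def test_full_grid_window_with_zero_bias_equals_msa(self, rng):
        dim, heads, g = 8, 2, 4
        msa = MultiHeadSelfAttention(dim, heads, rng)
        wmsa = WindowMSA(dim, heads, g, (g, g), rng)
        _copy_msa_weights_to_window(msa, wmsa)
        x = rng.normal(size=(1, g, g, dim))
        with no_grad():
            a = wmsa(Tensor(x)).data
            b = msa(Tensor(x.reshape(1, g * g, dim))).data.reshape(1, g, g, dim)
        assert np.abs(a - b).max() < 1e-5

    def test_constant_windows_give_constant_output(self, rng):
        wmsa = WindowMSA(4, 2, 2, (4, 4), rng)
        x = np.zeros((1, 4, 4, 4))
        # a different constant per 2x2 window
        for wi, (sy, sx) in enumerate([(0, 0), (0, 2), (2, 0), (2, 2)]):
            x[0, sy:sy + 2, sx:sx + 2, :] = wi + 1.0
        out = wmsa(Tensor(x)).data
        for sy, sx in [(0, 0), (0, 2), (2, 0), (2, 2)]:
            win = out[0, sy:sy + 2, sx:sx + 2, :]
            assert np.allclose(win, win[0, 0], atol=1e-10)

    def test_unshifted_windows_are_independent(self, rng):
        wmsa = WindowMSA(4, 2, 2, (4, 4), rng)
        x = rng.normal(size=(1, 4, 4, 4))
        x_zeroed = x.copy()
        x_zeroed[0, :2, :2, :] = 0.0   # kill first window only
        with no_grad():
            a = wmsa(Tensor(x)).data
            b = wmsa(Tensor(x_zeroed)).data
        assert np.allclose(a[0, :2, 2:], b[0, :2, 2:], atol=1e-12)
        assert np.allclose(a[0, 2:], b[0, 2:], atol=1e-12)

    def test_window_swap_symmetry(self, rng):
        """Relative-position-bias sharing: swapping two windows' contents
        swaps their outputs exactly (shift 0)."""
        wmsa = WindowMSA(4, 2, 2, (4, 4), rng)
        x = rng.normal(size=(1, 4, 4, 4))
        swapped = x.copy()
        swapped[0, :2, :2], swapped[0, :2, 2:] = x[0, :2, 2:].copy(), x[0, :2, :2].copy()
        with no_grad():
            a = wmsa(Tensor(x)).data
            b = wmsa(Tensor(swapped)).data
        assert np.allclose(a[0, :2, :2], b[0, :2, 2:], atol=1e-12)
        assert np.allclose(a[0, :2, 2:], b[0, :2, :2], atol=1e-12)

    def test_non_dividing_window_rejected(self, rng):
        with pytest.raises(ValueError, match="pad"):
            WindowMSA(4, 2, 3, (4, 4), rng)

    def test_relative_position_index_shares_equal_offsets(self):
        idx = relative_position_index(2)
        assert idx.shape == (4, 4)
        # token pairs (0,1) and (2,3) have the same offset (0, -1)
        assert idx[0, 1] == idx[2, 3]
        assert idx[0, 0] == idx[3, 3]


class TestLocalBlock:
    def test_zero_weights_identity(self, rng):
        blk = LocalBlock(4, 2, 2.0, 2, (4, 4), rng)
        for p in blk.parameters():
            p.data[:] = 0.0
        x = rng.normal(size=(1, 4, 4, 4))
        assert np.allclose(blk(Tensor(x)).data, x)

    def test_shift_enables_cross_window_flow(self, rng):
        """With shifted windows, a far-corner perturbation reaches tokens that
        two unshifted blocks would leave untouched."""
        blk = LocalBlock(4, 2, 2.0, 2, (4, 4), rng)
        assert blk.swmsa.shift == 1
        x = rng.normal(size=(1, 4, 4, 4))
        x2 = x.copy()
        # single-channel perturbation (a uniform shift would sit in the
        # pre-LayerNorm null space and propagate nowhere)
        x2[0, 3, 3, 0] += 10.0
        with no_grad():
            d = np.abs(blk(Tensor(x)).data - blk(Tensor(x2)).data)
        # W-MSA spreads the corner into its unshifted window; SW-MSA then
        # carries it across the window boundary to token (1, 1)
        assert d[0, 1, 1].max() > 1e-8

    def test_shape_preserved(self, rng):
        blk = LocalBlock(8, 2, 2.0, 4, (8, 8), rng)
        x = Tensor(rng.normal(size=(2, 8, 8, 8)))
        assert blk(x).shape == (2, 8, 8, 8)


class TestSRA:
    def test_ratio_one_equals_msa(self, rng):
        dim, heads, g = 8, 2, 4
        msa = MultiHeadSelfAttention(dim, heads, rng)
        sra = SpatialReductionAttention(dim, heads, 1, (g, g), rng)
        c = dim
        sra.q.weight.data = msa.qkv.weight.data[:, :c].copy()
        sra.q.bias.data = msa.qkv.bias.data[:c].copy()
        sra.kv.weight.data = msa.qkv.weight.data[:, c:].copy()
        sra.kv.bias.data = msa.qkv.bias.data[c:].copy()
        sra.proj.weight.data = msa.proj.weight.data.copy()
        sra.proj.bias.data = msa.proj.bias.data.copy()
        x = rng.normal(size=(1, g, g, dim))
        with no_grad():
            a = sra(Tensor(x)).data
            b = msa(Tensor(x.reshape(1, g * g, dim))).data.reshape(1, g, g, dim)
        assert np.abs(a - b).max() < 1e-5

    def test_key_value_token_count_reduced(self, rng):
        captured = {}
        sra = SpatialReductionAttention(8, 2, 8, (32, 32), rng)
        orig_forward = sra.kv.forward

        def capture(x):
            captured["n"] = x.shape[1]
            return orig_forward(x)

        sra.kv.forward = capture
        with no_grad():
            sra(Tensor(np.random.default_rng(1).normal(size=(1, 32, 32, 8))))
        assert captured["n"] == 16  # (32/8)^2

    def test_non_dividing_ratio_rejected(self, rng):
        with pytest.raises(ValueError, match="does not divide"):
            SpatialReductionAttention(8, 2, 3, (4, 4), rng)

    def test_shape_preserved(self, rng):
        sra = SpatialReductionAttention(8, 2, 2, (4, 4), rng)
        x = Tensor(rng.normal(size=(2, 4, 4, 8)))
        assert sra(x).shape == (2, 4, 4, 8)


class TestAttentionConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            AttentionConfig(dim=10, n_heads=3)
        with pytest.raises(ValueError, match="shift"):
            AttentionConfig(dim=8, n_heads=2, window=4, shift=4)
        cfg = AttentionConfig(dim=8, n_heads=2)
        assert cfg.head_dim == 4


def test_no_nans_for_bounded_inputs_at_full_dims(rng):
    """Numerical robustness at the published stage dims for inputs in [-10, 10]."""
    x = Tensor(rng.uniform(-10, 10, size=(1, 64, 128)))
    blk = GlobalBlock(128, 2, 8.0, rng)
    with no_grad():
        out = blk(x)
    assert np.all(np.isfinite(out.data))
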