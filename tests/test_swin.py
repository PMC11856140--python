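"""Shifted-window attention primitives against dense/loop oracles."""

import itertools

import numpy as np
import pytest

from snakereg import autodiff as ad
from snakereg.autodiff import Tensor
from snakereg.swin import (PatchEmbed, PatchExpand, PatchMerge, SwinBlock,
                           SwinConfig, WindowAttention, attention_mask,
                           window_partition, window_reverse)


class TestWindowPartition:
    @pytest.mark.parametrize("shape", [(4, 4, 4), (5, 3, 4), (3, 3, 3), (2, 6, 4)])
    def test_partition_reverse_bijection_all_shifts(self, shape, rng):
        x = Tensor(rng.standard_normal(shape + (3,)).astype(np.float32))
        window = (2, 2, 2)
        for shift in itertools.product((0, 1), repeat=3):
            wins = window_partition(x, window, shift)
            back = window_reverse(wins, shape, window, shift)
            assert np.array_equal(back.data, x.data), f"shift={shift}"

    def test_window_count(self, rng):
        x = Tensor(rng.standard_normal((5, 4, 3, 2)).astype(np.float32))
        wins = window_partition(x, (2, 2, 2), (0, 0, 0))
        assert wins.shape[0] == int(np.ceil(5 / 2) * np.ceil(4 / 2) * np.ceil(3 / 2))

    def test_shifted_token_lands_in_wrapped_window(self, rng):
        """Cyclic shift by 1: the grid origin moves to the wrapped position
        (3,3,3), i.e. into the last window (explicit index bookkeeping)."""
        x = np.zeros((4, 4, 4, 1), dtype=np.float32)
        x[0, 0, 0, 0] = 1.0
        wins = window_partition(Tensor(x), (2, 2, 2), (1, 1, 1)).data
        hot = np.argwhere(wins[:, :, 0] == 1.0)
        assert len(hot) == 1
        wi, ti = hot[0]
        assert wi == 7  # last of the 8 windows
        assert ti == 7  # last position inside that window: (1,1,1) local = (3,3,3) global


class TestAttention:
    def test_single_token_returns_value_projection(self, rng):
        attn = WindowAttention(4, 1, (1, 1, 1), rng, rel_bias=False)
        tok = rng.standard_normal((1, 1, 4)).astype(np.float32)
        out = attn(Tensor(tok)).data
        qkv = tok @ attn.qkv.weight.data + attn.qkv.bias.data
        expected = qkv[..., 8:] @ attn.proj.weight.data + attn.proj.bias.data
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_matches_dense_attention_oracle(self, rng):
        """Tiny case (2 tokens, 1 head, C=4): hand-rolled softmax attention."""
        attn = WindowAttention(4, 1, (1, 1, 2), rng, rel_bias=False)
        tok = rng.standard_normal((3, 2, 4)).astype(np.float32)
        out = attn(Tensor(tok)).data
        qkv = tok @ attn.qkv.weight.data + attn.qkv.bias.data
        q, k, v = qkv[..., :4], qkv[..., 4:8], qkv[..., 8:]
        logits = q @ k.transpose(0, 2, 1) / np.sqrt(4.0)
        w = np.exp(logits - logits.max(-1, keepdims=True))
        w /= w.sum(-1, keepdims=True)
        assert np.allclose(w.sum(-1), 1.0, atol=1e-6)  # softmax rows normalized
        expected = (w @ v) @ attn.proj.weight.data + attn.proj.bias.data
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_permutation_equivariance_without_bias(self, rng):
        attn = WindowAttention(6, 2, (1, 2, 2), rng, rel_bias=False)
        tok = rng.standard_normal((1, 4, 6)).astype(np.float32)
        perm = [2, 0, 3, 1]
        out = attn(Tensor(tok)).data
        out_p = attn(Tensor(tok[:, perm])).data
        np.testing.assert_allclose(out[:, perm], out_p, atol=1e-5)

    def test_heads_must_divide_channels(self, rng):
        with pytest.raises(ValueError, match="divide"):
            WindowAttention(6, 4, (1, 1, 1), rng)

    def test_mask_blocks_cross_boundary_mixing(self):
        mask = attention_mask((4, 4, 4), (2, 2, 2), (1, 1, 1))
        assert mask is not None and (mask < 0).any()
        assert attention_mask((4, 4, 4), (2, 2, 2), (0, 0, 0)) is None


class TestSwinBlock:
    def test_zero_sublayer_weights_is_identity(self, rng):
        blk = SwinBlock(8, 2, (2, 2, 2), rng, shifted=True)
        for p in (blk.attn.proj.weight, blk.attn.proj.bias,
                  blk.mlp.fc2.weight, blk.mlp.fc2.bias):
            p.data[:] = 0
        x = Tensor(rng.standard_normal((4, 4, 4, 8)).astype(np.float32))
        np.testing.assert_array_equal(blk(x).data, x.data)

    def test_degenerate_shift_equals_unshifted(self, rng):
        """On a grid no larger than the window the cyclic shift vanishes."""
        cfg_rng = np.random.default_rng(5)
        b1 = SwinBlock(8, 2, (2, 2, 2), np.random.default_rng(5), shifted=True)
        b2 = SwinBlock(8, 2, (2, 2, 2), np.random.default_rng(5), shifted=False)
        x = Tensor(rng.standard_normal((2, 2, 2, 8)).astype(np.float32))
        np.testing.assert_allclose(b1(x).data, b2(x).data, atol=1e-6)

    def test_block_matches_stepwise_composition(self, rng):
        """The block equals the four-line pre-norm residual composition
        applied independently."""
        blk = SwinBlock(8, 2, (2, 2, 2), rng, shifted=False)
        x = Tensor(rng.standard_normal((2, 2, 2, 8)).astype(np.float32))
        out = blk(x).data
        h = window_partition(blk.norm1(x), (2, 2, 2), (0, 0, 0))
        h = blk.attn(h, None, (2, 2, 2))
        z = ad.add(x, window_reverse(h, (2, 2, 2), (2, 2, 2), (0, 0, 0)))
        z = ad.add(z, blk.mlp(blk.norm2(z)))
        np.testing.assert_allclose(out, z.data, atol=1e-6)


class TestPatchOps:
    def test_embed_shape_contract(self, rng):
        pe = PatchEmbed(16, rng)
        tg = pe(Tensor(rng.standard_normal((2, 8, 8, 8)).astype(np.float32)))
        assert tg.grid_shape == (2, 2, 2) and tg.channels == 16

    def test_embed_rejects_single_channel(self, rng):
        pe = PatchEmbed(16, rng)
        with pytest.raises(ValueError, match="pair"):
            pe(Tensor(np.zeros((1, 8, 8, 8), dtype=np.float32)))

    def test_embed_constant_input_gives_equal_tokens(self, rng):
        pe = PatchEmbed(8, rng)
        tg = pe(Tensor(np.full((2, 8, 8, 8), 2.5, dtype=np.float32)))
        t = tg.tokens.data.reshape(-1, 8)
        assert np.abs(t - t[0]).max() < 1e-6

    def test_embed_matches_patch_loop_oracle(self, rng):
        pe = PatchEmbed(16, rng)
        pair = rng.standard_normal((2, 8, 8, 8)).astype(np.float32)
        tg = pe(Tensor(pair))
        for (i, j, k) in [(0, 0, 0), (1, 0, 1), (0, 1, 1)]:
            patch = pair[:, 4 * i:4 * i + 4, 4 * j:4 * j + 4, 4 * k:4 * k + 4].reshape(-1)
            tok = patch @ pe.proj.weight.data + pe.proj.bias.data
            tok = (tok - tok.mean()) / np.sqrt(tok.var() + 1e-5)
            tok = tok * pe.norm.weight.data + pe.norm.bias.data
            np.testing.assert_allclose(tg.tokens.data[i, j, k], tok, atol=1e-5)

    def test_merge_shape_and_neighbor_order(self, rng):
        pm = PatchMerge(8, rng)
        x = rng.standard_normal((4, 4, 4, 8)).astype(np.float32)
        out = pm(Tensor(x)).data
        assert out.shape == (2, 2, 2, 16)
        # loop oracle for one merged token, (d, h, w) scan order
        cat = np.concatenate([x[dz, dy, dx] for dz in (0, 1) for dy in (0, 1)
                              for dx in (0, 1)])
        ln = (cat - cat.mean()) / np.sqrt(cat.var() + 1e-5)
        ln = ln * pm.norm.weight.data + pm.norm.bias.data
        np.testing.assert_allclose(out[0, 0, 0], ln @ pm.reduction.weight.data, atol=1e-5)

    def test_expand_shape_and_redistribution_order(self, rng):
        px = PatchExpand(16, rng)
        x = rng.standard_normal((2, 2, 2, 16)).astype(np.float32)
        out = px(Tensor(x)).data
        assert out.shape == (4, 4, 4, 8)
        proj = (x[0, 0, 0] @ px.expand.weight.data).reshape(2, 2, 2, 8)
        for dz, dy, dx in itertools.product((0, 1), repeat=3):
            t = proj[dz, dy, dx]
            t = (t - t.mean()) / np.sqrt(t.var() + 1e-5)
            t = t * px.norm.weight.data + px.norm.bias.data
            np.testing.assert_allclose(out[dz, dy, dx], t, atol=1e-5)

    def test_merge_pads_odd_grids(self, rng):
        pm = PatchMerge(4, rng)
        out = pm(Tensor(rng.standard_normal((3, 3, 3, 4)).astype(np.float32)))
        assert out.shape == (2, 2, 2, 8)


class TestSwinConfig:
    def test_heads_must_divide_width(self):
        with pytest.raises(ValueError, match="divide"):
            SwinConfig(embed_dim=10, depths=(1,), heads=(3,))

    def test_depths_heads_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            SwinConfig(depths=(1, 1), heads=(2,))
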