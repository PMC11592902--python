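"""Transformer encoder: patching, attention arithmetic, block contracts."""

import numpy as np
import pytest

from cytorl.nn import LayerNorm, Tensor
from cytorl.vit import (EncoderBlock, EncoderConfig, MultiHeadSelfAttention,
                        PatchConfig, PatchEmbed, ViTEncoder, add_positions,
                        scaled_dot_attention)

rng = np.random.default_rng(777)


class TestPatchify:
    @pytest.mark.parametrize("hw,p,expected", [((8, 8), 4, 4),
                                               ((224, 224), 16, 196),
                                               ((4, 4), 2, 4)])
    def test_patch_count_arithmetic(self, hw, p, expected):
        assert PatchConfig(p, 8).n_patches(*hw) == expected

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError, match="does not divide"):
            PatchConfig(3, 8).n_patches(8, 8)

    def test_constant_map_with_identity_projection_gives_equal_patches(self):
        cfg = PatchConfig(2, 4)  # in_dim = 1*2*2 = 4 = embed_dim
        emb = PatchEmbed(1, cfg, np.random.default_rng(0))
        emb.proj.weight.data = np.eye(4)
        emb.proj.bias.data = np.zeros(4)
        fmap = Tensor(np.full((1, 1, 4, 4), 3.25))
        out = emb(fmap).data
        assert out.shape == (1, 4, 4)
        assert np.allclose(out, out[:, :1, :])  # all patch vectors equal

    def test_add_positions_identity_and_content(self):
        z = Tensor(rng.normal(size=(2, 4, 8)))
        zero = Tensor(np.zeros((4, 8)))
        assert np.allclose(add_positions(z, zero).data, z.data)
        e = Tensor(rng.normal(size=(4, 8)))
        assert np.allclose(add_positions(Tensor(np.zeros((2, 4, 8))), e).data,
                           np.broadcast_to(e.data, (2, 4, 8)))

    def test_distinct_positions_distinguish_identical_patches(self):
        z = Tensor(np.ones((1, 3, 2)))
        e = Tensor(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))
        out = add_positions(z, e).data
        assert not np.allclose(out[0, 0], out[0, 1])


class TestScaledDotAttention:
    def test_identical_keys_give_uniform_weights_and_mean_output(self):
        q = Tensor(rng.normal(size=(3, 4)))
        k = Tensor(np.tile(rng.normal(size=(1, 4)), (5, 1)))
        v = Tensor(rng.normal(size=(5, 4)))
        out, w = scaled_dot_attention(q, k, v)
        assert np.allclose(w.data, 1 / 5)
        assert np.allclose(out.data, np.tile(v.data.mean(0), (3, 1)))

    def test_single_token_weight_one(self):
        q = Tensor(rng.normal(size=(1, 4)))
        k = Tensor(rng.normal(size=(1, 4)))
        v = Tensor(rng.normal(size=(1, 4)))
        out, w = scaled_dot_attention(q, k, v)
        assert np.allclose(w.data, 1.0)
        assert np.allclose(out.data, v.data)

    def test_two_key_worked_example(self):
        """Hand-evaluated: softmax(1/sqrt(2), 0) ~ (0.6698, 0.3302)."""
        q = Tensor(np.array([[1.0, 0.0]]))
        k = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
        v = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
        out, w = scaled_dot_attention(q, k, v)
        assert np.allclose(w.data, [[0.6698, 0.3302]], atol=5e-5)
        assert np.allclose(out.data, [[0.6698, 0.3302]], atol=5e-5)

    def test_weight_rows_sum_to_one_random(self):
        for _ in range(50):
            tq, tk = rng.integers(1, 16, 2)
            q = Tensor(rng.normal(size=(int(tq), 8)))
            k = Tensor(rng.normal(size=(int(tk), 8)))
            v = Tensor(rng.normal(size=(int(tk), 8)))
            _, w = scaled_dot_attention(q, k, v)
            assert np.allclose(w.data.sum(-1), 1.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(Tensor(np.zeros((2, 3))),
                                 Tensor(np.zeros((2, 4))),
                                 Tensor(np.zeros((2, 4))))


class TestMHSA:
    def test_single_head_reduces_to_scaled_dot_attention(self):
        mhsa = MultiHeadSelfAttention(8, 1, np.random.default_rng(3))
        z = Tensor(rng.normal(size=(2, 5, 8)))
        out = mhsa(z).data
        # oracle: explicit single-head computation with the same weights
        q = z.data @ mhsa.wq.weight.data + mhsa.wq.bias.data
        k = z.data @ mhsa.wk.weight.data + mhsa.wk.bias.data
        v = z.data @ mhsa.wv.weight.data + mhsa.wv.bias.data
        expect = []
        for b in range(2):
            o, _ = scaled_dot_attention(Tensor(q[b]), Tensor(k[b]), Tensor(v[b]))
            expect.append(o.data @ mhsa.wo.weight.data + mhsa.wo.bias.data)
        assert np.allclose(out, np.stack(expect))

    @pytest.mark.parametrize("heads", [1, 2, 4])
    def test_shape_preserved(self, heads):
        mhsa = MultiHeadSelfAttention(8, heads, np.random.default_rng(0))
        z = Tensor(rng.normal(size=(3, 6, 8)))
        assert mhsa(z).shape == (3, 6, 8)

    def test_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            MultiHeadSelfAttention(8, 3, np.random.default_rng(0))

    def test_permutation_equivariance_without_positions(self):
        mhsa = MultiHeadSelfAttention(8, 2, np.random.default_rng(1))
        z = rng.normal(size=(1, 6, 8))
        perm = rng.permutation(6)
        out = mhsa(Tensor(z)).data
        out_perm = mhsa(Tensor(z[:, perm])).data
        assert np.allclose(out[:, perm], out_perm)


class TestEncoderBlock:
    def test_layernorm_rows_standardised_before_affine(self):
        ln = LayerNorm(16)
        x = Tensor(rng.normal(size=(4, 16)) * 3 + 1)
        normed = ln.normalize(x).data
        assert np.allclose(normed.mean(-1), 0.0, atol=1e-9)
        assert np.allclose(normed.var(-1), 1.0, atol=1e-4)

    def test_zero_weight_sublayers_reduce_to_double_layernorm(self):
        blk = EncoderBlock(8, 2, 16, np.random.default_rng(0))
        for lin in (blk.mhsa.wo, blk.ffn.fc2):
            lin.weight.data[:] = 0.0
            lin.bias.data[:] = 0.0
        z = Tensor(rng.normal(size=(1, 4, 8)))
        out = blk(z).data
        expect = blk.ln2(blk.ln1(z)).data
        assert np.allclose(out, expect)

    def test_stacked_blocks_preserve_sequence_length_and_finiteness(self):
        enc = ViTEncoder(3, (8, 8), PatchConfig(4, 8), EncoderConfig(2, 2, 16),
                         n_classes=4)
        for _ in range(10):
            fmap = Tensor(rng.normal(size=(2, 3, 8, 8)))
            tokens = enc.encode(fmap)
            assert tokens.shape == (2, 4, 8)
            assert np.all(np.isfinite(tokens.data))


class TestClassificationHead:
    def setup_method(self):
        self.enc = ViTEncoder(1, (4, 4), PatchConfig(2, 8),
                              EncoderConfig(1, 2, 16), n_classes=3)

    def test_zero_logit_head_uniform(self):
        self.enc.head.weight.data[:] = 0.0
        self.enc.head.bias.data[:] = 0.0
        probs = self.enc(Tensor(rng.normal(size=(2, 1, 4, 4)))).data
        assert np.allclose(probs, 1 / 3)

    def test_probabilities_sum_to_one(self):
        probs = self.enc(Tensor(rng.normal(size=(5, 1, 4, 4)))).data
        assert np.allclose(probs.sum(-1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_logit_shift_invariance(self):
        tokens = self.enc.encode(Tensor(rng.normal(size=(2, 1, 4, 4))))
        p1 = self.enc.classify(tokens).data
        self.enc.head.bias.data += 7.5  # constant shift on every logit
        p2 = self.enc.classify(tokens).data
        assert np.allclose(p1, p2)
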