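"""Supporter pathway: Conv3D, BiLSTM symmetry, attention pooling, fusion."""

import numpy as np
import pytest

from cytorl.nn import Conv3dSame, Tensor, functional as F
from cytorl.supporter import (AttentionPool, BiLSTM, Conv1x1Projection,
                              FusionHead, Supporter, SupporterConfig,
                              project_residual, stack_feature_maps)

rng = np.random.default_rng(2024)


class TestConv3d:
    def _conv_with_kernel(self, kernel, bias=0.0):
        conv = Conv3dSame((3, 3, 3), np.random.default_rng(0))
        conv.weight.data = kernel
        conv.bias.data = np.asarray(bias)
        return conv

    def test_identity_kernel_passes_volume_through(self):
        kernel = np.zeros((3, 3, 3))
        kernel[1, 1, 1] = 1.0
        conv = self._conv_with_kernel(kernel)
        x = Tensor(rng.normal(size=(2, 3, 5, 5)))
        assert np.allclose(conv(x).data, x.data)

    def test_zero_kernel_with_bias_gives_constant(self):
        conv = self._conv_with_kernel(np.zeros((3, 3, 3)), bias=0.7)
        x = Tensor(rng.normal(size=(1, 3, 4, 4)))
        assert np.allclose(conv(x).data, 0.7)

    def test_averaging_kernel_preserves_constants(self):
        conv = self._conv_with_kernel(np.full((3, 3, 3), 1 / 27))
        x = Tensor(np.full((1, 5, 6, 6), 4.0))
        out = conv(x).data
        # interior voxels see 27 constant neighbours
        assert np.allclose(out[0, 2, 2:4, 2:4], 4.0)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            F.conv3d_same(Tensor(np.zeros((1, 4, 4, 4))),
                          Tensor(np.zeros((2, 3, 3))), None)


class TestBiLSTM:
    def test_output_dim_is_twice_hidden(self):
        net = BiLSTM(3, 5, np.random.default_rng(0))
        for t in (1, 4, 9):
            out = net(Tensor(rng.normal(size=(2, t, 3))))
            assert out.shape == (2, t, 10)

    def test_reversing_input_swaps_directional_halves(self):
        """h_t of the reversed sequence equals swapped halves at T+1-t,
        verified by running both directions explicitly."""
        hidden = 4
        net = BiLSTM(3, hidden, np.random.default_rng(1))
        # tie the two directional cells so reversal symmetry is exact
        net.bwd.load_state_dict(net.fwd.state_dict())
        seq = rng.normal(size=(1, 4, 3))
        out = net(Tensor(seq)).data
        out_rev = net(Tensor(seq[:, ::-1].copy())).data
        fwd, bwd = out[..., :hidden], out[..., hidden:]
        fwd_r, bwd_r = out_rev[..., :hidden], out_rev[..., hidden:]
        assert np.allclose(fwd, bwd_r[:, ::-1])
        assert np.allclose(bwd, fwd_r[:, ::-1])

    def test_single_step_deterministic_given_seed(self):
        a = BiLSTM(3, 4, np.random.default_rng(9))
        b = BiLSTM(3, 4, np.random.default_rng(9))
        x = Tensor(rng.normal(size=(2, 1, 3)))
        assert np.allclose(a(x).data, b(x).data)


class TestAttentionPool:
    def test_identical_steps_give_uniform_weights_and_mean_context(self):
        pool = AttentionPool(6, 4, np.random.default_rng(0))
        h1 = rng.normal(size=(1, 1, 6))
        h = Tensor(np.tile(h1, (2, 5, 1)))
        alpha, c = pool(h)
        assert np.allclose(alpha.data, 1 / 5)
        assert np.allclose(c.data, h1[0])

    def test_single_step_weight_one(self):
        pool = AttentionPool(6, 4, np.random.default_rng(0))
        h = Tensor(rng.normal(size=(3, 1, 6)))
        alpha, c = pool(h)
        assert np.allclose(alpha.data, 1.0)
        assert np.allclose(c.data, h.data[:, 0])

    def test_engineered_scores_quarter_half_quarter(self):
        """Scores (0, ln 2, 0) must give alpha (0.25, 0.5, 0.25) and the
        matching convex combination; engineered via a 1-D pool whose score
        is tanh(h_t)."""
        pool = AttentionPool(1, 1, np.random.default_rng(0))
        pool.wh.weight.data = np.array([[1.0]])
        pool.wh.bias.data = np.array([0.0])
        pool.v.data = np.array([[1.0]])
        hvals = np.arctanh(np.array([0.0, np.log(2.0), 0.0]))
        h = Tensor(hvals.reshape(1, 3, 1))
        alpha, c = pool(h)
        assert np.allclose(alpha.data, [[0.25, 0.5, 0.25]])
        expect = 0.25 * hvals[0] + 0.5 * hvals[1] + 0.25 * hvals[2]
        assert np.allclose(c.data, [[expect]])

    def test_weights_normalised_and_context_in_convex_hull(self):
        pool = AttentionPool(6, 4, np.random.default_rng(0))
        for t in list(range(1, 33)):
            h = Tensor(rng.normal(size=(2, t, 6)))
            alpha, c = pool(h)
            assert np.allclose(alpha.data.sum(-1), 1.0)
            assert np.all(c.data <= h.data.max(axis=1) + 1e-12)
            assert np.all(c.data >= h.data.min(axis=1) - 1e-12)


class TestProjection:
    def test_identity_weights_pass_through(self):
        proj = Conv1x1Projection(3, np.random.default_rng(0))
        proj.conv.weight.data = np.eye(3).reshape(3, 3, 1, 1)
        proj.conv.bias.data = np.zeros(3)
        x = Tensor(rng.normal(size=(2, 3, 4, 4)))
        assert np.allclose(proj(x).data, x.data)

    def test_no_spatial_mixing(self):
        proj = Conv1x1Projection(3, np.random.default_rng(1))
        x = np.zeros((1, 3, 4, 4))
        x[0, :, 2, 1] = rng.normal(size=3)  # single active position
        out = proj(x_t := Tensor(x)).data
        bias_only = proj(Tensor(np.zeros_like(x))).data
        changed = np.any(out != bias_only, axis=1)[0]
        assert changed[2, 1]
        assert changed.sum() == 1

    def test_zero_weights_pure_residual(self):
        proj = Conv1x1Projection(3, np.random.default_rng(0))
        proj.conv.weight.data[:] = 0.0
        proj.conv.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(1, 3, 4, 4)))
        res = Tensor(rng.normal(size=(1, 3, 4, 4)))
        assert np.allclose(project_residual(x, proj, res).data, res.data)


class TestFusionHead:
    def setup_method(self):
        self.head = FusionHead(8, 4, 6, 3, np.random.default_rng(0))
        self.args = (Tensor(rng.normal(size=(2, 8, 4, 4))),
                     Tensor(rng.normal(size=(2, 5, 4))),
                     Tensor(rng.normal(size=(2, 6))))

    def test_probabilities_sum_to_one(self):
        probs = self.head(*self.args).data
        assert np.allclose(probs.sum(-1), 1.0, atol=1e-6)

    def test_zero_weights_uniform(self):
        self.head.fc.weight.data[:] = 0.0
        self.head.fc.bias.data[:] = 0.0
        assert np.allclose(self.head(*self.args).data, 1 / 3)

    def test_logit_shift_invariance(self):
        p1 = self.head(*self.args).data
        self.head.fc.bias.data += 3.0
        assert np.allclose(self.head(*self.args).data, p1)


class TestSupporterEndToEnd:
    def test_stacks_pools_and_is_deterministic(self):
        cfg = SupporterConfig(stack_depth=2, lstm_hidden=4, attention_dim=4,
                              max_seq_hw=4, seed=11)
        sup_a, sup_b = Supporter(cfg), Supporter(cfg)
        stages = [Tensor(rng.normal(size=(2, 4, 8, 8))),
                  Tensor(rng.normal(size=(2, 8, 4, 4)))]
        a_alpha, a_c = sup_a(stages)
        b_alpha, b_c = sup_b(stages)
        assert a_c.shape == (2, 8)
        assert np.allclose(a_alpha.data.sum(-1), 1.0)
        assert np.allclose(a_c.data, b_c.data)

    def test_stacked_volume_geometry(self):
        cfg = SupporterConfig(stack_depth=2, max_seq_hw=4)
        stages = [Tensor(rng.normal(size=(1, 4, 8, 8))),
                  Tensor(rng.normal(size=(1, 8, 4, 4)))]
        vol = stack_feature_maps(stages, cfg)
        assert vol.shape == (1, 2, 4, 4)
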