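"""Architecture: branch shapes, attention, causal convolutions, residual
blocks, parameter budget and receptive field."""

import numpy as np
import pytest

from mbtcn.model import (BranchConfig, Model, ModelConfig, ResidualBlock,
                         branch_forward, branch_output_length, build_model,
                         concat_branches, dilated_causal_conv,
                         multi_head_attention, param_count, receptive_field)
from mbtcn.nn.autodiff import Tensor
from mbtcn.nn.layers import MultiHeadAttention


def expected_param_count(cfg: ModelConfig) -> int:
    """Closed-form shape sum over the architecture description.

    Conv: k*Cin*Cout + Cout; batch-norm: 4*C (gamma, beta, running mean/var);
    attention: four d x d projections; dense: in*out + out.
    """
    total = 0
    for b in cfg.branches:
        f1, f2 = b.filters, b.out_channels
        total += b.kernel_1 * 1 * f1 + f1 + 4 * f1
        total += b.kernel_2 * f1 * f2 + f2 + 4 * f2
    d = cfg.d_model
    total += 4 * d                      # post-concat normalization
    total += 4 * d * d                  # W_Q, W_K, W_V, W_O
    in_ch = d
    for _dil in cfg.tcn_dilations:
        total += cfg.tcn_kernel * in_ch * cfg.tcn_filters + cfg.tcn_filters
        total += 4 * cfg.tcn_filters
        total += cfg.tcn_kernel * cfg.tcn_filters ** 2 + cfg.tcn_filters
        total += 4 * cfg.tcn_filters
        if in_ch != cfg.tcn_filters:
            total += in_ch * cfg.tcn_filters + cfg.tcn_filters
        in_ch = cfg.tcn_filters
    total += cfg.seq_length * cfg.tcn_filters * cfg.n_classes + cfg.n_classes
    return total


class TestBranches:
    def test_branch_output_length_for_250(self):
        assert branch_output_length(250) == 62

    def test_branch_forward_shapes(self):
        m = build_model(seed=0)
        x = Tensor(np.random.default_rng(0).standard_normal((3, 250, 1)))
        for branch, cfg in zip(m.branches, m.config.branches):
            out = branch(x)
            assert out.shape == (3, 62, cfg.out_channels)

    def test_branch_forward_wrapper_shape_and_length_guard(self, rng):
        x = rng.standard_normal((2, 250))
        out = branch_forward(x, BranchConfig(kernel_1=14, dilation_2=2))
        assert out.shape == (2, 62, 16)
        with pytest.raises(ValueError, match="too short"):
            branch_forward(rng.standard_normal((1, 3)), BranchConfig(4))

    def test_zero_input_gives_zero_preactivations(self):
        m = build_model(seed=0)
        conv = m.branches[0].layers[0]
        out = conv(Tensor(np.zeros((2, 250, 1))))
        assert np.allclose(out.data, 0.0)   # zero-initialized biases

    def test_concat_adds_channels_and_blocks_permute(self, rng):
        a, b, c = (rng.standard_normal((62, k)) for k in (16, 16, 16))
        fused = concat_branches([a, b, c])
        assert fused.shape == (62, 48)
        permuted = concat_branches([c, a, b])
        assert np.array_equal(permuted[:, :16], c)
        assert np.array_equal(permuted[:, 16:32], a)

    def test_concat_single_branch_is_identity(self, rng):
        a = rng.standard_normal((10, 4))
        assert np.array_equal(concat_branches([a]), a)

    def test_concat_length_mismatch_is_internal_error(self, rng):
        with pytest.raises(RuntimeError, match="padding"):
            concat_branches([rng.standard_normal((10, 2)),
                             rng.standard_normal((9, 2))])


class TestAttention:
    def test_single_position_softmax_is_one(self, rng):
        mha = MultiHeadAttention(4, 2, rng=np.random.default_rng(0))
        x = rng.standard_normal((1, 1, 4))
        out = mha(Tensor(x))
        assert np.allclose(mha.last_attention, 1.0)
        v = (x @ mha.w_v.data)
        expected = v @ mha.w_o.data
        assert np.allclose(out.data, expected, atol=1e-12)

    def test_identity_projections_match_dense_oracle(self):
        mha = MultiHeadAttention(2, 1, rng=np.random.default_rng(0))
        for w in mha.parameters():
            w.data[:] = np.eye(2)
        x = np.array([[[1.0, 0.5], [-0.2, 0.3]]])
        out = mha(Tensor(x)).data
        scores = x[0] @ x[0].T / np.sqrt(2.0)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        attn = e / e.sum(axis=1, keepdims=True)
        assert np.allclose(out[0], attn @ x[0], atol=1e-12)

    def test_attention_rows_sum_to_one(self, rng):
        mha = MultiHeadAttention(8, 4, rng=np.random.default_rng(1))
        mha(Tensor(rng.standard_normal((2, 9, 8))))
        sums = mha.last_attention.sum(axis=-1)
        assert np.abs(sums - 1.0).max() < 1e-6

    def test_permutation_equivariance_over_positions(self, rng):
        mha = MultiHeadAttention(6, 3, rng=np.random.default_rng(2))
        x = rng.standard_normal((1, 7, 6))
        perm = np.random.default_rng(3).permutation(7)
        out = mha(Tensor(x)).data
        out_p = mha(Tensor(x[:, perm, :])).data
        assert np.allclose(out_p, out[:, perm, :], atol=1e-10)

    def test_indivisible_dimension_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            MultiHeadAttention(7, 2, rng=np.random.default_rng(0))


class TestDilatedCausalConv:
    def test_identity_kernel(self, rng):
        x = rng.standard_normal(20)
        for d in (1, 2, 5):
            assert np.allclose(dilated_causal_conv(x, [1.0], d), x)

    def test_direct_summation_example(self):
        y = dilated_causal_conv([1, 2, 3, 4], [1, 1], dilation=2)
        assert np.allclose(y, [1, 2, 4, 6])

    def test_causality_under_random_perturbations(self, rng):
        x = rng.standard_normal(50)
        taps = rng.standard_normal(4)
        for _ in range(10):
            t = int(rng.integers(1, 50))
            x2 = x.copy()
            x2[t] += rng.standard_normal()
            y, y2 = (dilated_causal_conv(v, taps, 3) for v in (x, x2))
            assert np.allclose(y[:t], y2[:t])

    def test_matches_direct_sum_oracle(self, rng):
        x = rng.standard_normal(30)
        taps = rng.standard_normal(5)
        d = 4
        y = dilated_causal_conv(x, taps, d)
        for t in range(len(x)):
            ref = sum(taps[i] * (x[t - d * i] if t - d * i >= 0 else 0.0)
                      for i in range(len(taps)))
            assert np.isclose(y[t], ref)


class TestResidualBlock:
    @staticmethod
    def block(in_ch=6, filters=6, kernel=3, dilation=2, seed=0):
        rng = np.random.default_rng(seed)
        return ResidualBlock(in_ch, filters, kernel, dilation, dropout=0.0,
                             rng=rng, dropout_rng=np.random.default_rng(1))

    def test_zero_f_with_matching_channels_gives_relu_of_input(self, rng):
        blk = self.block()
        blk.conv1.w.data[:] = 0.0
        blk.conv2.w.data[:] = 0.0
        blk.set_training(False)
        x = rng.standard_normal((2, 10, 6))
        out = blk(Tensor(x)).data
        # F(x) = bn(relu(0)) = bn's beta = 0, so output = relu(x)
        assert np.allclose(out, np.maximum(x, 0.0))

    def test_matches_compositional_oracle(self, rng):
        blk = self.block(in_ch=4, filters=5, kernel=3, dilation=2, seed=3)
        blk.set_training(False)
        x = rng.standard_normal((2, 12, 4))

        def conv_ref(x3, w, b, dil):
            B, L, Cin = x3.shape
            k, _, Cout = w.shape
            y = np.zeros((B, L, Cout))
            for bb in range(B):
                for ci in range(Cin):
                    for co in range(Cout):
                        y[bb, :, co] += dilated_causal_conv(
                            x3[bb, :, ci], w[:, ci, co], dil)
            return y + b

        def bn_ref(x3, bn):
            return ((x3 - bn.running_mean)
                    / np.sqrt(bn.running_var + bn.eps)
                    * bn.gamma.data + bn.beta.data)

        f = bn_ref(np.maximum(conv_ref(x, blk.conv1.w.data,
                                       blk.conv1.b.data, 2), 0), blk.bn1)
        f = bn_ref(np.maximum(conv_ref(f, blk.conv2.w.data,
                                       blk.conv2.b.data, 2), 0), blk.bn2)
        skip = conv_ref(x, blk.skip.w.data, blk.skip.b.data, 1)
        expected = np.maximum(f + skip, 0.0)
        assert np.allclose(blk(Tensor(x)).data, expected, atol=1e-10)

    @pytest.mark.parametrize("dilation", [1, 2, 4, 8])
    def test_preserves_length(self, rng, dilation):
        blk = self.block(dilation=dilation)
        out = blk(Tensor(rng.standard_normal((1, 30, 6))))
        assert out.shape == (1, 30, 6)


class TestBuildModel:
    def test_parameter_budget_under_0_15_mb(self):
        m = build_model(ModelConfig(), seed=0)
        assert param_count(m) * 4 / (1024 * 1024) <= 0.15

    def test_param_count_matches_closed_form(self):
        for cfg in (ModelConfig(), ModelConfig.wide_template()):
            m = build_model(cfg, seed=0)
            assert param_count(m) == expected_param_count(cfg)

    def test_softmax_rows_are_probability_vectors(self, rng):
        m = build_model(seed=1)
        probs = m.predict_proba(rng.standard_normal((6, 250)))
        assert (probs >= 0).all()
        assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-6

    def test_receptive_field_matches_impulse_probe(self):
        cfg = ModelConfig(tcn_layers=2, tcn_kernel=3, tcn_filters=4)
        rf = receptive_field(cfg)          # 1 + 2*2*(1+2) = 13
        assert rf == 13
        m = build_model(cfg, seed=0)
        for blk in m.tcn:
            for conv in (blk.conv1, blk.conv2, *(
                    [blk.skip] if blk.skip is not None else [])):
                conv.w.data[:] = np.abs(conv.w.data) + 0.01
            blk.set_training(False)
        L = 40
        x = np.zeros((1, L, m.config.d_model))
        x[0, 0, :] = 1.0
        h = Tensor(x)
        for blk in m.tcn:
            h = blk(h)
        active = np.flatnonzero(np.abs(h.data[0]).sum(axis=1) > 1e-12)
        assert active.max() == rf - 1

    def test_receptive_field_grows_with_depth(self):
        rfs = [receptive_field(ModelConfig(tcn_layers=k))
               for k in (2, 3, 4, 5)]
        assert all(b > a for a, b in zip(rfs, rfs[1:]))

    def test_tcn_stack_is_causal_end_to_end(self, rng):
        m = build_model(ModelConfig(tcn_layers=3), seed=2)
        for blk in m.tcn:
            blk.set_training(False)
        x = rng.standard_normal((1, 30, m.config.d_model))

        def run(v):
            h = Tensor(v)
            for blk in m.tcn:
                h = blk(h)
            return h.data

        base = run(x)
        t = 17
        x2 = x.copy()
        x2[0, t, :] += 1.0
        assert np.allclose(run(x2)[0, :t], base[0, :t])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(heads=5)
        with pytest.raises(ValueError, match="AAMI"):
            ModelConfig(n_classes=3)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        m = build_model(seed=4)
        x = rng.standard_normal((3, 250))
        p1 = m.predict_proba(x)
        path = tmp_path / "model.mbtcn"
        m.save(path)
        m2 = Model.load(path)
        assert np.array_equal(m2.predict_proba(x), p1)
        assert m2.config == m.config
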