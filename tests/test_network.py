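"""Architecture contracts: branches, attention, fusion, loss."""

import math

import numpy as np
import pytest

from mpi_deblur.autodiff import Tensor
from mpi_deblur.network import (
    DeblurNet,
    NetworkConfig,
    multi_supervised_loss,
)

CFG64 = NetworkConfig(input_size=20)


def _net64(cfg=CFG64, seed=0) -> DeblurNet:
    """Network in float64 for oracle-grade comparisons."""
    return DeblurNet(cfg, rng_seed=seed).astype(np.float64)


class TestCnnModule:
    def test_zero_image_zero_features(self):
        net = _net64()
        zero = Tensor(np.zeros((1, net.config.base_channels, 20, 20)))
        uc, x_a = net.cnn_module(zero)
        # all biases are zero-initialized, so conv/ReLU of zeros stays zero
        assert np.all(uc.data == 0) and np.all(x_a.data == 0)

    def test_spatial_shape_preserved(self):
        net = _net64()
        x = Tensor(np.random.default_rng(0).random((2, net.config.base_channels, 20, 20)))
        uc, x_a = net.cnn_module(x)
        assert uc.shape[2:] == (20, 20)
        assert x_a.shape == (2, 1, 20, 20)

    def test_branch_ablation_additivity(self):
        # zeroing the keep-branch weights leaves only the resized pooled path
        net = _net64()
        rng = np.random.default_rng(3)
        x = Tensor(rng.random((1, net.config.base_channels, 20, 20)))
        stage = net.cnn_stages[0]
        full = stage(x)
        kept = stage.conv_keep(x).relu()
        stage.conv_keep.weight.data[:] = 0
        stage.conv_keep.bias.data[:] = 0
        pooled_only = stage(x)
        assert np.allclose(full.data - kept.data, pooled_only.data, atol=1e-12)


class TestConvProjection:
    def test_token_count_is_hw(self):
        net = _net64()
        C = net.config.base_channels
        q, k, v = net.conv_projection(Tensor(np.random.default_rng(0).random((2, C, 13, 13))))
        assert q.shape == k.shape == v.shape == (2, 13 * 13, net.config.embed_dim)

    def test_identity_kernels_give_flattened_input(self):
        cfg = NetworkConfig(base_channels=4, embed_dim=4, n_heads=2, input_size=8)
        net = _net64(cfg)
        C = 4
        # delta depthwise kernel + identity pointwise replicated for Q, K, V
        net.proj_depthwise.weight.data[:] = 0
        net.proj_depthwise.weight.data[:, 1, 1] = 1.0
        net.proj_depthwise.bias.data[:] = 0
        eye = np.eye(C)
        net.proj_pointwise.weight.data = np.concatenate([eye, eye, eye], 0)[:, :, None, None]
        net.proj_pointwise.bias.data[:] = 0
        x = np.random.default_rng(1).random((1, C, 6, 6))
        q, k, v = net.conv_projection(Tensor(x))
        flat = x.reshape(1, C, 36).transpose(0, 2, 1)
        for t in (q, k, v):
            assert np.allclose(t.data, flat, atol=1e-12)

    def test_dwsc_equals_dense_conv_with_delta_depthwise(self):
        # with a delta depthwise kernel, DWSC reduces to the pointwise (1x1) conv
        net = _net64()
        C, E = net.config.base_channels, net.config.embed_dim
        net.proj_depthwise.weight.data[:] = 0
        net.proj_depthwise.weight.data[:, 1, 1] = 1.0
        net.proj_depthwise.bias.data[:] = 0
        x = Tensor(np.random.default_rng(2).random((1, C, 7, 7)))
        dwsc = net.proj_pointwise(net.proj_depthwise(x))
        dense = x.conv2d(net.proj_pointwise.weight, net.proj_pointwise.bias)
        assert np.allclose(dwsc.data, dense.data, atol=1e-12)


class TestEmha:
    def test_uniform_attention_for_equal_keys(self):
        cfg = NetworkConfig(base_channels=4, embed_dim=4, n_heads=1, input_size=8)
        net = _net64(cfg)
        rng = np.random.default_rng(0)
        q = Tensor(rng.random((1, 6, 4)))
        k = Tensor(np.ones((1, 6, 4)))  # all K rows equal -> uniform weights
        v = Tensor(rng.random((1, 6, 4)))
        res = Tensor(np.zeros((1, 6, 4)))
        out = net.emha(q, k, v, res)
        vh = net.wv(v).data
        expected = 0.5 * np.repeat(vh.mean(axis=1, keepdims=True), 6, axis=1)
        assert np.allclose(out.data, expected, atol=1e-10)

    def test_attention_rows_sum_to_one(self):
        net = _net64()
        rng = np.random.default_rng(5)
        E = net.config.embed_dim
        q = net.wq(Tensor(rng.random((2, 9, E))))
        k = net.wk(Tensor(rng.random((2, 9, E))))
        h, d = net.config.n_heads, E // net.config.n_heads
        qh = q.data.reshape(2, 9, h, d).transpose(0, 2, 1, 3)
        kh = k.data.reshape(2, 9, h, d).transpose(0, 2, 1, 3)
        scores = Tensor(qh @ kh.transpose(0, 1, 3, 2) / math.sqrt(d))
        attn = scores.softmax(-1)
        assert np.allclose(attn.data.sum(-1), 1.0, atol=1e-9)

    def test_matches_bruteforce_attention_oracle(self):
        cfg = NetworkConfig(base_channels=4, embed_dim=4, n_heads=2, input_size=8)
        net = _net64(cfg, seed=3)
        rng = np.random.default_rng(8)
        T, E, h = 6, 4, 2
        d = E // h
        q0, k0, v0 = (rng.standard_normal((1, T, E)) for _ in range(3))
        res = rng.standard_normal((1, T, E))
        out = net.emha(Tensor(q0), Tensor(k0), Tensor(v0), Tensor(res))

        # brute-force loop: per-head linear projections + softmax(QK^T/sqrt(d))V
        def lin(m, x):
            return x @ m.weight.data + m.bias.data

        q, k, v = lin(net.wq, q0)[0], lin(net.wk, k0)[0], lin(net.wv, v0)[0]
        merged = np.zeros((T, E))
        for head in range(h):
            sl = slice(head * d, (head + 1) * d)
            qh, kh, vh = q[:, sl], k[:, sl], v[:, sl]
            for t in range(T):
                scores = np.array([qh[t] @ kh[s] / math.sqrt(d) for s in range(T)])
                weights = np.exp(scores - scores.max())
                weights /= weights.sum()
                merged[t, sl] = sum(weights[s] * vh[s] for s in range(T))
        expected = (merged + res[0]) / 2.0
        assert np.allclose(out.data[0], expected, atol=1e-10)

    def test_sum_residual_mode(self):
        cfg = NetworkConfig(base_channels=4, embed_dim=4, n_heads=1, input_size=8,
                            attention_residual="sum")
        net = _net64(cfg)
        rng = np.random.default_rng(1)
        q, k, v = (Tensor(rng.standard_normal((1, 5, 4))) for _ in range(3))
        res = rng.standard_normal((1, 5, 4))
        out_sum = net.emha(q, k, v, Tensor(res))
        net_avg = _net64(NetworkConfig(base_channels=4, embed_dim=4, n_heads=1, input_size=8))
        net_avg.load_state_dict({k_: v_ for k_, v_ in net.state_dict().items()})
        out_avg = net_avg.emha(q, k, v, Tensor(res))
        assert np.allclose(out_sum.data, 2.0 * out_avg.data, atol=1e-12)


class TestTransformerModule:
    def test_zeroed_mlp_gives_residual_identity(self):
        net = _net64()
        net.mlp_out.weight.data[:] = 0
        net.mlp_out.bias.data[:] = 0
        u = Tensor(np.random.default_rng(0).random((2, 10, net.config.embed_dim)))
        out = net.refine_tokens(u)
        assert np.allclose(out.data, u.data, atol=1e-15)

    def test_token_permutation_equivariance(self):
        # no positional encoding: permuting tokens permutes the output
        net = _net64()
        rng = np.random.default_rng(4)
        E = net.config.embed_dim
        tokens = rng.standard_normal((1, 12, E))
        perm = rng.permutation(12)
        q, k, v = (Tensor(tokens.copy()) for _ in range(3))
        u = net.refine_tokens(net.emha(q, k, v, Tensor(tokens.copy())))
        qp, kp, vp = (Tensor(tokens[:, perm].copy()) for _ in range(3))
        up = net.refine_tokens(net.emha(qp, kp, vp, Tensor(tokens[:, perm].copy())))
        assert np.allclose(up.data, u.data[:, perm], atol=1e-10)

    def test_branch_output_shape(self):
        net = _net64()
        C = net.config.base_channels
        feat = Tensor(np.random.default_rng(0).random((2, C, 20, 20)))
        ut, x_b = net.transformer_module(feat)
        assert ut.shape == (2, net.config.embed_dim, 20, 20)
        assert x_b.shape == (2, 1, 20, 20)


class TestChannelAttentionFusion:
    def test_attention_weights_in_open_unit_interval(self):
        net = _net64()
        rng = np.random.default_rng(0)
        C, E = net.config.base_channels, net.config.embed_dim
        uc = Tensor(rng.random((2, C, 20, 20)))
        ut = Tensor(rng.random((2, E, 20, 20)))
        uf = net.fuse_conv(__import__("mpi_deblur.autodiff", fromlist=["concat"]).concat([uc, ut], 1)).relu()
        pooled = uf.mean(axis=(2, 3))
        gate = net.att_w2(net.att_w1(pooled).relu()).sigmoid()
        assert np.all(gate.data > 0) and np.all(gate.data < 1)

    def test_saturated_gate_recovers_uf(self):
        net = _net64()
        net.att_w2.weight.data[:] = 0
        net.att_w2.bias.data[:] = 50.0  # sigmoid saturates to ~1
        rng = np.random.default_rng(1)
        uc = Tensor(rng.random((1, net.config.base_channels, 20, 20)))
        ut = Tensor(rng.random((1, net.config.embed_dim, 20, 20)))
        fused, _ = net.channel_attention_fusion(uc, ut)
        from mpi_deblur.autodiff import concat

        uf = net.fuse_conv(concat([uc, ut], 1)).relu()
        assert np.allclose(fused.data, uf.data, atol=1e-12)

    def test_hand_set_gate_matches_broadcast_oracle(self):
        net = _net64()
        rng = np.random.default_rng(2)
        C = net.config.base_channels
        uf = rng.random((2, C, 5, 5))
        gate = rng.random((2, C))
        out = Tensor(uf) * Tensor(gate).reshape(2, C, 1, 1)
        expected = np.empty_like(uf)
        for b in range(2):
            for c in range(C):
                expected[b, c] = uf[b, c] * gate[b, c]
        assert np.allclose(out.data, expected, atol=1e-12)

    def test_spatial_misalignment_rejected(self):
        net = _net64()
        uc = Tensor(np.zeros((1, net.config.base_channels, 20, 20)))
        ut = Tensor(np.zeros((1, net.config.embed_dim, 10, 10)))
        with pytest.raises(ValueError, match="misaligned"):
            net.channel_attention_fusion(uc, ut)


class TestForward:
    def test_deterministic_and_shape_preserving(self):
        net = _net64()
        x = np.random.default_rng(0).random((20, 20))
        o1, o2 = net.forward(x), net.forward(x)
        for a, b in ((o1.x_a, o2.x_a), (o1.x_b, o2.x_b), (o1.x_f, o2.x_f)):
            assert a.shape == (1, 1, 20, 20)
            assert np.array_equal(a.data, b.data)

    def test_all_parameters_receive_gradient(self):
        net = _net64()
        rng = np.random.default_rng(6)
        x = rng.random((2, 1, 20, 20))
        y = rng.random((2, 1, 20, 20))
        loss = multi_supervised_loss(net.forward(x), y, net.config)
        loss.backward()
        for name, p in net.named_parameters():
            assert p.grad is not None and np.abs(p.grad).max() > 0, name

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(embed_dim=10, n_heads=4)
        with pytest.raises(ValueError):
            NetworkConfig(lambda_a=0.0, lambda_b=0.0, lambda_f=0.0)
        with pytest.raises(ValueError):
            NetworkConfig(use_cnn=False, use_transformer=False)


class TestLoss:
    def test_zero_iff_exact(self):
        net = _net64()
        x = np.random.default_rng(0).random((1, 1, 20, 20))
        out = net.forward(x)
        y_a = out.x_a.data
        loss = multi_supervised_loss(out, y_a, NetworkConfig(lambda_a=1, lambda_b=0, lambda_f=0))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-30)

    def test_constant_offset_closed_form(self):
        from mpi_deblur.network import MultiOutput

        c = 0.37
        y = np.zeros((1, 1, 4, 5))
        pred = MultiOutput(x_a=Tensor(y + c), x_b=None, x_f=Tensor(y))
        cfg = NetworkConfig(lambda_a=1.0, lambda_b=0.0, lambda_f=0.0)
        loss = multi_supervised_loss(pred, y, cfg)
        assert float(loss.data) == pytest.approx(c**2, abs=1e-12)

    def test_matches_loop_oracle(self):
        from mpi_deblur.network import MultiOutput

        rng = np.random.default_rng(9)
        y = rng.random((1, 1, 4, 4))
        xa, xb, xf = (rng.random((1, 1, 4, 4)) for _ in range(3))
        cfg = NetworkConfig(lambda_a=0.5, lambda_b=0.5, lambda_f=1.0)
        pred = MultiOutput(x_a=Tensor(xa), x_b=Tensor(xb), x_f=Tensor(xf))
        loss = float(multi_supervised_loss(pred, y, cfg).data)

        expected = 0.0
        for lam, x in ((0.5, xa), (0.5, xb), (1.0, xf)):
            acc = 0.0
            for i in range(4):
                for j in range(4):
                    acc += (x[0, 0, i, j] - y[0, 0, i, j]) ** 2
            expected += lam * acc / 16.0
        assert loss == pytest.approx(expected, abs=1e-12)

    def test_all_zero_lambdas_rejected(self):
        net = _net64()
        out = net.forward(np.zeros((1, 1, 20, 20)))
        bad = NetworkConfig(lambda_a=1.0)  # valid config ...
        object.__setattr__(bad, "lambda_a", 0.0)
        object.__setattr__(bad, "lambda_b", 0.0)
        object.__setattr__(bad, "lambda_f", 0.0)  # ... forced invalid
        with pytest.raises(ValueError):
            multi_supervised_loss(out, np.zeros((1, 1, 20, 20)), bad)


class TestVariants:
    @pytest.mark.parametrize("variant,expect_heads", [
        ("cnn_only", ("x_a",)),
        ("transformer_only", ("x_b",)),
        ("fusion_no_attention", ("x_a", "x_b", "x_f")),
    ])
    def test_variant_heads_and_param_counts(self, variant, expect_heads):
        from mpi_deblur.pipeline import _variant_config

        full = DeblurNet(CFG64, rng_seed=0)
        net = DeblurNet(_variant_config(CFG64, variant), rng_seed=0)
        assert net.num_parameters() < full.num_parameters()
        out = net.forward(np.zeros((1, 1, 20, 20)))
        for head in expect_heads:
            assert getattr(out, head) is not None
        assert out.x_f.shape == (1, 1, 20, 20)
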