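"""Network stages against literal loop-based oracles, parameter accounting,
freeze schedule, and checkpoints."""

import numpy as np
import pytest

from fallgcn import autodiff as ad
from fallgcn.autodiff import Tensor
from fallgcn.graph_topology import assemble_adjacency, builtin_layout, \
    divide_subgraphs
from fallgcn.network import (ModelConfig, ModelParams, agcn_block, forward,
                             forward_logits, load_checkpoint, mtcn_forward,
                             parameter_count, save_checkpoint,
                             set_adjacency_trainable, sgcn_forward, smp,
                             subgraph_attention, tmp)
from fallgcn.feature_encoding import encode_batch
from tests.conftest import make_sequence


# ------------------------------------------------------------------ oracles

def sgcn_oracle(x, A, weights, biases):
    """Literal triple-loop spatial graph convolution."""
    C, T, V = x.shape
    Cp = weights[0].shape[1]
    out = np.zeros((Cp, T, V))
    for l in range(A.shape[0]):
        h = np.zeros((Cp, T, V))
        for t in range(T):
            for v in range(V):
                h[:, t, v] = weights[l].T @ x[:, t, v] + biases[l]
        for t in range(T):
            for v in range(V):
                for w in range(V):
                    out[:, t, v] += A[l, v, w] * h[:, t, w]
    return np.maximum(out, 0.0)


def sga_oracle(x, params, block_index):
    """Literal per-part attention (evaluation mode, running BN stats)."""
    blk = params.blocks[block_index]
    scheme = params.scheme
    N, C, T, V = x.shape
    W, b = blk["sga_w"].data, blk["sga_b"].data
    gam, bet = blk["sga_gamma"].data, blk["sga_beta"].data
    W2, b2 = blk["sga_w2"].data, blk["sga_b2"].data
    rm, rv = blk["bn_mean"], blk["bn_var"]
    out = np.zeros_like(x)
    counts = np.zeros(V)
    for part in scheme.parts:
        for v in part:
            counts[v] += 1
    for n in range(N):
        for part in scheme.parts:
            pooled = np.stack([x[n, :, :, v].mean(axis=1) for v in part])
            h = pooled @ W + b
            h = (h - rm) / np.sqrt(rv + 1e-5) * gam + bet
            h = 1.0 / (1.0 + np.exp(-h))
            gate = (h @ W2).ravel() + b2[0]
            e = np.exp(gate - gate.max())
            wts = e / e.sum()
            for m, v in enumerate(part):
                out[n, :, :, v] += x[n, :, :, v] * wts[m]
    return out / counts[None, None, None, :]


def mtcn_oracle(x, params):
    """Literal loop-based multi-scale temporal convolution (eval mode)."""
    C, T = x.shape
    branches = []
    for br in params.mtcn:
        Wk, bk = br["w"].data, br["b"].data
        K, _, D = Wk.shape
        pad = K // 2
        xp = np.pad(x, ((0, 0), (pad, pad)))
        h = np.zeros((D, T))
        for d in range(D):
            for t in range(T):
                for k in range(K):
                    h[d, t] += Wk[k, :, d] @ xp[:, t + k]
                h[d, t] += bk[d]
        h = ((h.T - br["bn_mean"]) / np.sqrt(br["bn_var"] + 1e-5)
             * br["gamma"].data + br["beta"].data).T
        branches.append(np.maximum(h, 0.0))
    fused = np.concatenate(branches, axis=0)
    return (fused.T @ params.mtcn_proj_w.data
            + params.mtcn_proj_b.data).T


def f64_rand_params(tiny_config, seed):
    params = ModelParams(tiny_config, seed=seed, dtype=np.float64)
    r = np.random.default_rng(seed + 1000)
    for t in params.named_tensors().values():
        if t is not params.adjacency:
            t.data = r.normal(0, 0.5, t.data.shape)
    return params


# -------------------------------------------------------------------- tests

class TestSgcn:
    def test_identity_subset_zero_is_relu(self, path5, rng):
        A = np.zeros((3, 5, 5))
        A[0] = np.eye(5)
        x = rng.normal(0, 1, (4, 3, 5))
        w = [np.eye(4) for _ in range(3)]
        b = [np.zeros(4) for _ in range(3)]
        out = sgcn_forward(x, A, [Tensor(wi) for wi in w],
                           [Tensor(bi) for bi in b])
        np.testing.assert_allclose(out.data, np.maximum(x, 0), rtol=1e-12)

    def test_zero_input_gives_zero_output(self, path5):
        layout = builtin_layout("toy-path-3")
        A = assemble_adjacency(layout, divide_subgraphs(layout, 2)).values
        x = np.zeros((2, 4, 3))
        w = [np.random.default_rng(i).normal(0, 1, (2, 5)) for i in range(3)]
        out = sgcn_forward(x, A, [Tensor(wi) for wi in w])
        assert not out.data.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed, path5):
        rng = np.random.default_rng(seed)
        A = assemble_adjacency(path5, divide_subgraphs(path5, 2)).values
        x = rng.normal(0, 1, (3, 4, 5))
        w = [rng.normal(0, 1, (3, 6)) for _ in range(3)]
        b = [rng.normal(0, 1, 6) for _ in range(3)]
        out = sgcn_forward(x, A, [Tensor(wi) for wi in w],
                           [Tensor(bi) for bi in b])
        expected = sgcn_oracle(x, A, w, b)
        np.testing.assert_allclose(out.data, expected, rtol=1e-9,
                                   atol=1e-12)


class TestSubgraphAttention:
    def test_zero_parameters_scale_each_part_node_by_inverse_size(
            self, tiny_config):
        params = ModelParams(tiny_config, seed=0, dtype=np.float64)
        blk = params.blocks[0]
        for key in ("sga_w", "sga_b", "sga_gamma", "sga_beta", "sga_w2",
                    "sga_b2"):
            blk[key].data[...] = 0.0
        V = params.layout.V
        x = np.abs(np.random.default_rng(0).normal(1, 0.2, (4, 3, V)))
        out, amap = subgraph_attention(x, params, 0, training=False)
        for p, part in enumerate(params.scheme.parts):
            m = len(part)
            np.testing.assert_allclose(amap.weights[0, p, :m], 1.0 / m,
                                       rtol=1e-12)
            assert not amap.weights[0, p, m:].any()
        counts = params.scheme.membership_counts()
        for v in range(V):
            if counts[v] == 1:
                part = next(p for p in params.scheme.parts if v in p)
                np.testing.assert_allclose(out.data[:, :, v],
                                           x[:, :, v] / len(part),
                                           rtol=1e-12)

    def test_single_part_reduces_to_global_node_softmax(self, path5):
        cfg = ModelConfig(layout_name="toy-path-5", C1=2,
                          block_channels=(4, 8, 12), Kt=3,
                          mtcn_kernels=(3,), mtcn_branch_width=4,
                          num_classes=2, use_subgraph_division=False)
        params = ModelParams(cfg, seed=1, dtype=np.float64)
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (2, 4, 6, 5))
        out, amap = subgraph_attention(x, params, 0, training=False)
        assert amap.weights.shape == (2, 1, 5)
        np.testing.assert_allclose(amap.weights.sum(axis=2), 1.0,
                                   rtol=1e-12)
        expected = sga_oracle(x, params, 0)
        np.testing.assert_allclose(out.data, expected, rtol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle_on_random_toys(self, seed, tiny_config):
        params = f64_rand_params(tiny_config, seed)
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (2, 4, 3, params.layout.V))
        out, amap = subgraph_attention(x, params, 0, training=False)
        np.testing.assert_allclose(out.data, sga_oracle(x, params, 0),
                                   rtol=1e-8, atol=1e-12)

    def test_part_weights_sum_to_one_with_padded_slots_zero(
            self, tiny_config, rng):
        params = f64_rand_params(tiny_config, 7)
        x = rng.normal(0, 1, (3, 4, 5, params.layout.V))
        _, amap = subgraph_attention(x, params, 0, training=False)
        for p, size in enumerate(amap.part_sizes):
            np.testing.assert_allclose(
                amap.weights[:, p, :size].sum(axis=1), 1.0, rtol=1e-12)
            assert not amap.weights[:, p, size:].any()

    def test_indivisible_channels_rejected_at_build(self):
        with pytest.raises(ValueError, match="divisible by 4"):
            ModelConfig(layout_name="toy-path-5", C1=2,
                        block_channels=(6, 10, 14), num_classes=2)


class TestMtcn:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, seed, tiny_config):
        params = f64_rand_params(tiny_config, seed + 50)
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (12, 7))  # (C_trunk, T)
        out = mtcn_forward(x, params)
        np.testing.assert_allclose(out.data, mtcn_oracle(x, params),
                                   rtol=1e-8, atol=1e-12)

    def test_zero_input_zero_output(self, tiny_config):
        params = ModelParams(tiny_config, seed=0, dtype=np.float64)
        out = mtcn_forward(np.zeros((12, 9)), params)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_kernel_subset_changes_parameter_count_by_branch_arithmetic(
            self, tiny_config):
        base = tiny_config
        only3 = ModelConfig.from_dict(
            {**base.to_dict(), "mtcn_kernels": [3]})
        trunk = base.block_channels[-1]
        bw = base.mtcn_branch_width
        def branch_cost(k):
            return k * trunk * bw + bw + 2 * bw  # conv + bias + BN affine
        # removing branch 5 also shrinks the fusion projection input
        proj_delta = bw * trunk
        expected = branch_cost(5) + proj_delta
        assert (parameter_count(base) - parameter_count(only3) == expected)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ModelConfig(mtcn_kernels=(3, 4))

    def test_empty_kernel_tuple_skips_stage(self, tiny_config):
        cfg = ModelConfig.from_dict(
            {**tiny_config.to_dict(), "mtcn_kernels": []})
        params = ModelParams(cfg, seed=0, dtype=np.float64)
        seqs = [make_sequence(params.layout, T=6, seed=1, label=0)]
        probs, _ = forward(params, seqs)
        assert probs.shape == (1, cfg.num_classes)
        with pytest.raises(ValueError, match="kernel"):
            mtcn_forward(np.zeros((12, 5)), params)


class TestPooling:
    def test_constant_input_pools_to_constant(self):
        x = np.full((2, 3, 4), 1.5)
        np.testing.assert_array_equal(smp(x).data, np.full((2, 3), 1.5))
        np.testing.assert_array_equal(tmp(np.full((2, 5), 1.5)).data,
                                      np.full(2, 1.5))

    def test_dominant_joint_wins_smp(self, rng):
        x = rng.normal(0, 1, (3, 4, 5))
        x[:, :, 2] = 10.0 + np.abs(x[:, :, 2])
        np.testing.assert_array_equal(smp(x).data, x[:, :, 2])

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(0, 1, (4, 6, 7))
        s = smp(x).data
        for c in range(4):
            for t in range(6):
                assert s[c, t] == max(x[c, t, v] for v in range(7))
        y = rng.normal(0, 1, (4, 6))
        m = tmp(y).data
        for c in range(4):
            assert m[c] == max(y[c, t] for t in range(6))


class TestForward:
    def test_block_output_channels_follow_config(self):
        cfg = ModelConfig()  # full default: 64, 128, 256
        params = ModelParams(cfg, seed=0)
        h = np.random.default_rng(0).normal(
            0, 1, (1, 32, 8, 25)).astype(np.float32)
        for i, cout in enumerate(cfg.block_channels):
            h_t, _ = agcn_block(h, params, i)
            assert h_t.shape == (1, cout, 8, 25)
            h = h_t.data

    def test_sga_disabled_block_is_sgcn_temporal_path(self, tiny_config):
        cfg = ModelConfig.from_dict(
            {**tiny_config.to_dict(), "use_subgraph_attention": False})
        params = ModelParams(cfg, seed=0, dtype=np.float64)
        x = np.random.default_rng(1).normal(0, 1, (2, 4, 5, 6))
        out, amap = agcn_block(x, params, 0)
        assert amap is None
        blk = params.blocks[0]
        h = sgcn_forward(x, params.adjacency, blk["sgcn_w"], blk["sgcn_b"])
        h = ad.batch_norm(h, blk["sgcn_gamma"], blk["sgcn_beta"],
                          blk["sgcn_bn_mean"], blk["sgcn_bn_var"], False,
                          feature_axis=1)
        h = ad.temporal_conv(h, blk["tconv_w"], blk["tconv_b"])
        h = ad.batch_norm(h, blk["tconv_gamma"], blk["tconv_beta"],
                          blk["tconv_bn_mean"], blk["tconv_bn_var"], False,
                          feature_axis=1)
        np.testing.assert_allclose(out.data, np.maximum(h.data, 0),
                                   rtol=1e-12)

    def test_probabilities_form_a_simplex_on_many_random_inputs(
            self, tiny_params):
        rng = np.random.default_rng(0)
        encoded = Tensor(rng.normal(0, 3, (1000, 4, 6, 6)))
        logits, _ = forward_logits(tiny_params, encoded, training=False)
        probs = np.exp(logits.data - logits.data.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_labels_do_not_influence_forward(self, tiny_params):
        a = make_sequence(tiny_params.layout, T=6, seed=3, label=0)
        b = make_sequence(tiny_params.layout, T=6, seed=3, label=2)
        pa, _ = forward(tiny_params, a)
        pb, _ = forward(tiny_params, b)
        np.testing.assert_array_equal(pa, pb)

    def test_frame_permutation_of_constant_input_is_invariant(
            self, tiny_params):
        frame = np.random.default_rng(5).normal(0, 1, (3, 1, 6))
        seq_values = np.repeat(frame, 6, axis=1)
        from fallgcn.skeleton_io import SkeletonSequence
        seq = SkeletonSequence(seq_values, tiny_params.layout)
        p1, _ = forward(tiny_params, seq)
        p2, _ = forward(tiny_params, seq)  # any frame order is the same seq
        np.testing.assert_array_equal(p1, p2)


class TestParameterCount:
    def test_default_model_within_lightweight_budget(self):
        assert parameter_count(ModelConfig()) <= 1_200_000

    def test_head_grows_by_trunk_plus_one_per_class(self):
        base = ModelConfig()
        more = ModelConfig(num_classes=12)
        assert (parameter_count(more) - parameter_count(base)
                == 6 * (256 + 1))

    def test_toy_config_matches_closed_form_sum(self, tiny_config):
        cfg = tiny_config
        V, C1 = 6, cfg.C1
        enc = 2 * (2 * 3 * C1 + C1) + (V * C1 + C1) + (C1 * C1 + C1)
        adj = 3 * V * V
        blocks = 0
        cin = 2 * C1
        for cout in cfg.block_channels:
            c4 = cout // 4
            blocks += 3 * (cin * cout + cout)          # SGCN maps
            blocks += cfg.Kt * cout * cout + cout      # temporal conv
            blocks += 2 * cout + 2 * cout              # two BN affines
            blocks += cout * c4 + c4 + 2 * c4 + c4 + 1  # SGA
            cin = cout
        trunk = cfg.block_channels[-1]
        bw = cfg.mtcn_branch_width
        mtcn = sum(k * trunk * bw + bw + 2 * bw for k in cfg.mtcn_kernels)
        mtcn += bw * len(cfg.mtcn_kernels) * trunk + trunk
        head = trunk * cfg.num_classes + cfg.num_classes
        assert parameter_count(cfg) == enc + adj + blocks + mtcn + head

    def test_removing_sga_or_branches_strictly_decreases_count(self):
        full = parameter_count(ModelConfig())
        no_sga = parameter_count(ModelConfig(use_subgraph_attention=False))
        fewer_k = parameter_count(ModelConfig(mtcn_kernels=(3, 5)))
        assert no_sga < full
        assert fewer_k < full


class TestFreezeSchedule:
    @pytest.mark.parametrize("epoch,trainable", [
        (0, False), (5, False), (9, False), (10, True), (11, True),
        (59, True)])
    def test_adjacency_frozen_then_trainable(self, tiny_config, epoch,
                                             trainable):
        params = ModelParams(tiny_config, seed=0)
        set_adjacency_trainable(params, epoch)
        assert params.adjacency_trainable is trainable
        assert params.adjacency.requires_grad is trainable

    def test_values_untouched_by_toggling(self, tiny_config):
        params = ModelParams(tiny_config, seed=0)
        before = params.adjacency.data.copy()
        set_adjacency_trainable(params, 30)
        np.testing.assert_array_equal(params.adjacency.data, before)


class TestCheckpoint:
    def test_bit_exact_round_trip(self, tmp_path, tiny_config):
        params = ModelParams(tiny_config, seed=4)
        params.epoch = 13
        set_adjacency_trainable(params, 13)
        params.blocks[0]["bn_mean"][...] = 0.25
        path = tmp_path / "ckpt.npz"
        save_checkpoint(params, path)
        back = load_checkpoint(path)
        assert back.epoch == 13
        assert back.adjacency_trainable is True
        for (name, t), (_, t2) in zip(params.named_tensors().items(),
                                      back.named_tensors().items()):
            np.testing.assert_array_equal(t.data, t2.data)
        for name, buf in params.buffers().items():
            np.testing.assert_array_equal(buf, back.buffers()[name])
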