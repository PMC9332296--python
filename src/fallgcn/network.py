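"""The lightweight subgraph-based fall-recognition network.

Architecture, in execution order:

1. feature encoding (see :mod:`fallgcn.feature_encoding`) -> 2*C1 channels;
2. three stacked adaptive graph-convolution blocks.  Each block is a
   spatial graph convolution (one 1x1 channel map per adjacency subset,
   aggregated by the partitioned adjacency tensor and summed), a temporal
   convolution with kernel Kt x 1 (same-length padding), and a sub-graph
   attention (SGA) stage that pools each body part over frames, squeezes
   channels 4x, gates with batch-norm + sigmoid, and softmax-reweights the
   part's joints.  Output channels are 64, 128 and 256 per block.  The
   adjacency tensor itself is a model parameter, frozen for the first 10
   epochs of training and learnable afterwards;
3. spatial max-pooling (SMP) over joints, a multi-scale temporal
   convolution (MTCN) with parallel kernels 3/5/7 whose branch outputs are
   concatenated and projected back to the trunk width, temporal max-pooling
   (TMP) over frames, and an affine softmax head.

Everything is sized so the default 25-joint, 6-class model stays within a
1.2 M learnable-parameter budget; ``parameter_count`` reports the exact
figure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .feature_encoding import EncoderParams, encode_batch
from .graph_topology import (AdjacencyTensor, JointLayout, SubgraphScheme,
                             assemble_adjacency, builtin_layout,
                             divide_subgraphs, whole_graph_scheme)

__all__ = [
    "ModelConfig", "ModelParams", "AttentionMap", "sgcn_forward",
    "subgraph_attention", "agcn_block", "smp", "tmp", "mtcn_forward",
    "forward", "forward_logits", "parameter_count",
    "set_adjacency_trainable", "save_checkpoint", "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the full model)."""

    layout_name: str = "ntu25"
    in_channels: int = 3
    C1: int = 16
    block_channels: tuple[int, ...] = (64, 128, 256)
    Kt: int = 3
    mtcn_kernels: tuple[int, ...] = (3, 5, 7)
    mtcn_branch_width: int = 128
    num_classes: int = 6
    use_subgraph_division: bool = True
    use_subgraph_attention: bool = True
    adjacency_freeze_epochs: int = 10

    def __post_init__(self):
        self.block_channels = tuple(self.block_channels)
        self.mtcn_kernels = tuple(self.mtcn_kernels)
        if any(b >= a for a, b in zip(self.block_channels[1:],
                                      self.block_channels)):
            raise ValueError("block_channels must be strictly increasing")
        if len(set(self.mtcn_kernels)) != len(self.mtcn_kernels):
            raise ValueError("mtcn_kernels must be distinct")
        if any(k % 2 == 0 or k < 1 for k in self.mtcn_kernels):
            raise ValueError("mtcn_kernels must be odd and positive")
        if self.Kt % 2 == 0 or self.Kt < 1:
            raise ValueError("Kt must be odd and positive")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        if self.use_subgraph_attention:
            for c in self.block_channels:
                if c % 4 != 0:
                    raise ValueError(
                        "sub-graph attention needs channels divisible by 4")

    @classmethod
    def desk(cls, **overrides) -> "ModelConfig":
        """Reduced-width preset for CPU-scale experiments: same topology and
        depth, narrower channels."""
        base = dict(C1=8, block_channels=(16, 32, 64),
                    mtcn_branch_width=32)
        base.update(overrides)
        return cls(**base)

    def layout(self) -> JointLayout:
        return builtin_layout(self.layout_name)

    def scheme(self) -> SubgraphScheme:
        layout = self.layout()
        if self.use_subgraph_division:
            return divide_subgraphs(layout)
        return whole_graph_scheme(layout)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["block_channels"] = list(self.block_channels)
        d["mtcn_kernels"] = list(self.mtcn_kernels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["block_channels"] = tuple(d["block_channels"])
        d["mtcn_kernels"] = tuple(d["mtcn_kernels"])
        return cls(**d)


@dataclass
class AttentionMap:
    """Per-part node-attention weights of one SGA stage.

    ``weights``: (N, g, M) softmax weights (padded slots exactly 0, each
    part's row sums to 1); ``gates``: the pre-softmax gate values.
    """

    weights: np.ndarray
    gates: np.ndarray
    part_sizes: tuple[int, ...]
    block_index: int


def _he(rng, shape, fan_in, dtype):
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(dtype),
                  requires_grad=True)


def _zeros(shape, dtype):
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)


class ModelParams:
    """All learnable tensors plus the scheme-derived constant matrices."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)
        dtype = self.dtype
        rng = np.random.default_rng(seed)
        layout = config.layout()
        scheme = config.scheme()
        self.layout = layout
        self.scheme = scheme
        V, C1 = layout.V, config.C1

        self.encoder = EncoderParams.init(config.in_channels, C1, V, rng,
                                          dtype=dtype)

        # learnable adjacency, initialised from the assembled subgraph
        # tensor; requires_grad toggled by the freeze schedule
        init_adj = assemble_adjacency(layout, scheme, normalized=True)
        self.adjacency = Tensor(init_adj.values.astype(dtype),
                                requires_grad=False)
        self.adjacency_trainable = False

        # constant gather/scatter matrices for SGA
        M = scheme.M
        self.part_sizes = tuple(len(p) for p in scheme.parts)
        self.gather = []    # (M, V) one-hot rows, zero rows for padding
        self.scatter = []   # (V, M)
        for part in scheme.parts:
            S = np.zeros((M, V), dtype=dtype)
            for m, v in enumerate(part):
                S[m, v] = 1.0
            self.gather.append(S)
            self.scatter.append(S.T.copy())
        counts = scheme.membership_counts().astype(dtype)
        self.inv_counts = 1.0 / counts          # every joint is in >=1 part
        self.slot_mask = np.zeros((scheme.g, M), dtype=bool)
        for p, size in enumerate(self.part_sizes):
            self.slot_mask[p, :size] = True

        cin = 2 * C1
        self.blocks = []
        for cout in config.block_channels:
            blk = {
                "sgcn_w": [_he(rng, (cin, cout), cin, dtype)
                           for _ in range(3)],
                "sgcn_b": [_zeros(cout, dtype) for _ in range(3)],
                "tconv_w": _he(rng, (config.Kt, cout, cout),
                               config.Kt * cout, dtype),
                "tconv_b": _zeros(cout, dtype),
            }
            for stage in ("sgcn", "tconv"):
                blk[f"{stage}_gamma"] = Tensor(np.ones(cout, dtype=dtype),
                                               requires_grad=True)
                blk[f"{stage}_beta"] = _zeros(cout, dtype)
                blk[f"{stage}_bn_mean"] = np.zeros(cout, dtype=dtype)
                blk[f"{stage}_bn_var"] = np.ones(cout, dtype=dtype)
            if config.use_subgraph_attention:
                c4 = cout // 4
                blk.update({
                    "sga_w": _he(rng, (cout, c4), cout, dtype),
                    "sga_b": _zeros(c4, dtype),
                    "sga_gamma": Tensor(np.ones(c4, dtype=dtype),
                                        requires_grad=True),
                    "sga_beta": _zeros(c4, dtype),
                    "sga_w2": _he(rng, (c4, 1), c4, dtype),
                    "sga_b2": _zeros(1, dtype),
                })
                blk["bn_mean"] = np.zeros(c4, dtype=dtype)  # running buffers
                blk["bn_var"] = np.ones(c4, dtype=dtype)
            self.blocks.append(blk)
            cin = cout

        trunk = config.block_channels[-1]
        self.mtcn = []
        for k in config.mtcn_kernels:
            bw = config.mtcn_branch_width
            self.mtcn.append({
                "w": _he(rng, (k, trunk, bw), k * trunk, dtype),
                "b": _zeros(bw, dtype),
                "gamma": Tensor(np.ones(bw, dtype=dtype),
                                requires_grad=True),
                "beta": _zeros(bw, dtype),
                "bn_mean": np.zeros(bw, dtype=dtype),
                "bn_var": np.ones(bw, dtype=dtype),
            })
        if config.mtcn_kernels:
            fused = config.mtcn_branch_width * len(config.mtcn_kernels)
            self.mtcn_proj_w = _he(rng, (fused, trunk), fused, dtype)
            self.mtcn_proj_b = _zeros(trunk, dtype)
        self.head_w = _he(rng, (trunk, config.num_classes), trunk, dtype)
        self.head_b = _zeros(config.num_classes, dtype)
        self.epoch = 0

    # ------------------------------------------------------------- plumbing

    def named_tensors(self) -> dict[str, Tensor]:
        out = dict(self.encoder.tensors())
        out["adjacency"] = self.adjacency
        for i, blk in enumerate(self.blocks):
            for l in range(3):
                out[f"block{i}.sgcn_w{l}"] = blk["sgcn_w"][l]
                out[f"block{i}.sgcn_b{l}"] = blk["sgcn_b"][l]
            out[f"block{i}.tconv_w"] = blk["tconv_w"]
            out[f"block{i}.tconv_b"] = blk["tconv_b"]
            for stage in ("sgcn", "tconv"):
                out[f"block{i}.{stage}_gamma"] = blk[f"{stage}_gamma"]
                out[f"block{i}.{stage}_beta"] = blk[f"{stage}_beta"]
            if self.config.use_subgraph_attention:
                for k in ("sga_w", "sga_b", "sga_gamma", "sga_beta",
                          "sga_w2", "sga_b2"):
                    out[f"block{i}.{k}"] = blk[k]
        for j, br in enumerate(self.mtcn):
            out[f"mtcn{j}.w"] = br["w"]
            out[f"mtcn{j}.b"] = br["b"]
            out[f"mtcn{j}.gamma"] = br["gamma"]
            out[f"mtcn{j}.beta"] = br["beta"]
        if self.config.mtcn_kernels:
            out["mtcn.proj_w"] = self.mtcn_proj_w
            out["mtcn.proj_b"] = self.mtcn_proj_b
        out["head.w"] = self.head_w
        out["head.b"] = self.head_b
        return out

    def trainable_tensors(self) -> list[Tensor]:
        return [t for t in self.named_tensors().values() if t.requires_grad]

    def buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for i, blk in enumerate(self.blocks):
            for stage in ("sgcn", "tconv"):
                out[f"block{i}.{stage}_bn_mean"] = blk[f"{stage}_bn_mean"]
                out[f"block{i}.{stage}_bn_var"] = blk[f"{stage}_bn_var"]
            if "bn_mean" in blk:
                out[f"block{i}.bn_mean"] = blk["bn_mean"]
                out[f"block{i}.bn_var"] = blk["bn_var"]
        for j, br in enumerate(self.mtcn):
            out[f"mtcn{j}.bn_mean"] = br["bn_mean"]
            out[f"mtcn{j}.bn_var"] = br["bn_var"]
        return out


# ------------------------------------------------------------------ stages

def _batched(x) -> tuple[Tensor, bool]:
    t = x if isinstance(x, Tensor) else Tensor(x)
    if t.data.ndim == 3:
        return ad.reshape(t, (1,) + t.shape), True
    return t, False


def sgcn_forward(x, adjacency, weights, biases=None) -> Tensor:
    """Spatial graph convolution: per-subset 1x1 channel maps aggregated by
    the matching adjacency subset, summed over the 3 subsets, then ReLU.

    ``x``: (C,T,V) or (N,C,T,V); ``adjacency``: AdjacencyTensor, (3,V,V)
    array, or a trainable Tensor; ``weights``: one (C,C') map per subset.
    """
    if isinstance(adjacency, AdjacencyTensor):
        adjacency = adjacency.values
    adj = adjacency if isinstance(adjacency, Tensor) else Tensor(adjacency)
    if adj.shape[0] != len(weights):
        raise ValueError("one weight map per adjacency subset required")
    xb, squeeze = _batched(x)
    acc = None
    for l in range(adj.shape[0]):
        w = weights[l] if isinstance(weights[l], Tensor) else Tensor(weights[l])
        b = None
        if biases is not None:
            b = biases[l] if isinstance(biases[l], Tensor) else Tensor(biases[l])
        h = ad.conv1x1(xb, w, b)
        h = ad.node_map(h, ad.index_axis(adj, 0, l))
        acc = h if acc is None else ad.add(acc, h)
    out = ad.relu(acc)
    return ad.reshape(out, out.shape[1:]) if squeeze else out


def subgraph_attention(x, params: ModelParams, block_index: int,
                       training: bool = False):
    """Sub-graph attention: reweight each body part's joints.

    Per part: gather its joints (padded to M slots), average-pool over
    frames, squeeze channels 4x through a shared affine map, batch-norm +
    sigmoid, map to one gate per joint slot, softmax over the part's valid
    slots, multiply the part's features by the weights, and scatter back to
    the joint axis (averaging where parts share a joint).

    Returns ``(out, AttentionMap)`` with ``out`` shaped like ``x``.
    """
    blk = params.blocks[block_index]
    xb, squeeze = _batched(x)
    n = xb.shape[0]
    g = len(params.gather)
    parts_feats = []
    pooled_rows = []
    for p in range(g):
        xp = ad.node_map(xb, Tensor(params.gather[p]))   # (N,C,T,M)
        parts_feats.append(xp)
        pooled = ad.mean_axis(xp, axis=2)                # (N,C,M)
        pooled_rows.append(ad.reshape(
            ad.transpose(pooled, (0, 2, 1)),
            (n, 1, pooled.shape[2], pooled.shape[1])))   # (N,1,M,C)
    z = ad.concat(pooled_rows, axis=1)                   # (N,g,M,C)
    h = ad.dense(z, blk["sga_w"], blk["sga_b"])          # (N,g,M,C/4)
    h = ad.batch_norm(h, blk["sga_gamma"], blk["sga_beta"],
                      blk["bn_mean"], blk["bn_var"], training)
    h = ad.sigmoid(h)
    gate = ad.dense(h, blk["sga_w2"], blk["sga_b2"])     # (N,g,M,1)
    gate = ad.reshape(gate, gate.shape[:3])              # (N,g,M)
    w = ad.masked_softmax(gate, params.slot_mask[None], axis=2)
    acc = None
    for p in range(g):
        wp = ad.index_axis(w, 1, p)                      # (N,M)
        wp4 = ad.reshape(wp, (n, 1, 1, wp.shape[1]))
        yp = ad.mul(parts_feats[p], wp4)                 # (N,C,T,M)
        sp = ad.node_map(yp, Tensor(params.scatter[p]))  # (N,C,T,V)
        acc = sp if acc is None else ad.add(acc, sp)
    out = ad.mul(acc, Tensor(params.inv_counts[None, None, None, :]))
    amap = AttentionMap(weights=w.data.copy(), gates=gate.data.copy(),
                        part_sizes=params.part_sizes,
                        block_index=block_index)
    return (ad.reshape(out, out.shape[1:]) if squeeze else out), amap


def agcn_block(x, params: ModelParams, block_index: int,
               training: bool = False):
    """One adaptive graph-convolution block: SGCN -> temporal conv -> SGA."""
    blk = params.blocks[block_index]
    xb, squeeze = _batched(x)
    h = sgcn_forward(xb, params.adjacency, blk["sgcn_w"], blk["sgcn_b"])
    h = ad.batch_norm(h, blk["sgcn_gamma"], blk["sgcn_beta"],
                      blk["sgcn_bn_mean"], blk["sgcn_bn_var"], training,
                      feature_axis=1)
    h = ad.temporal_conv(h, blk["tconv_w"], blk["tconv_b"])
    h = ad.batch_norm(h, blk["tconv_gamma"], blk["tconv_beta"],
                      blk["tconv_bn_mean"], blk["tconv_bn_var"], training,
                      feature_axis=1)
    h = ad.relu(h)
    amap = None
    if params.config.use_subgraph_attention:
        h, amap = subgraph_attention(h, params, block_index, training)
    return (ad.reshape(h, h.shape[1:]) if squeeze else h), amap


def smp(x) -> Tensor:
    """Spatial max-pooling: elementwise maximum over the joint axis."""
    t = x if isinstance(x, Tensor) else Tensor(x)
    return ad.max_axis(t, axis=t.data.ndim - 1)


def tmp(x) -> Tensor:
    """Temporal max-pooling: elementwise maximum over the frame axis."""
    t = x if isinstance(x, Tensor) else Tensor(x)
    return ad.max_axis(t, axis=t.data.ndim - 1)


def mtcn_forward(x, params: ModelParams, training: bool = False) -> Tensor:
    """Multi-scale temporal convolution on (C,T) or (N,C,T) input.

    Each branch convolves along frames with its own kernel size and ReLU;
    branch outputs are concatenated on the channel axis and projected back
    to the trunk width by a 1x1 map.
    """
    if not params.config.mtcn_kernels:
        raise ValueError("mtcn_forward requires at least one kernel")
    t = x if isinstance(x, Tensor) else Tensor(x)
    squeeze = t.data.ndim == 2
    if squeeze:
        t = ad.reshape(t, (1,) + t.shape)
    t4 = ad.reshape(t, t.shape + (1,))                  # (N,C,T,1)
    branches = []
    for br in params.mtcn:
        h = ad.temporal_conv(t4, br["w"], br["b"])
        h = ad.batch_norm(h, br["gamma"], br["beta"], br["bn_mean"],
                          br["bn_var"], training, feature_axis=1)
        branches.append(ad.relu(h))
    fused = ad.concat(branches, axis=1)
    out = ad.conv1x1(fused, params.mtcn_proj_w, params.mtcn_proj_b)
    out = ad.reshape(out, out.shape[:3])
    return ad.reshape(out, out.shape[1:]) if squeeze else out


def forward_logits(params: ModelParams, encoded: Tensor,
                   training: bool = False):
    """Run the trunk on an encoded batch (N, 2*C1, T, V) -> logits (N, K)
    plus the per-block attention maps."""
    h = encoded
    attention = []
    for i in range(len(params.blocks)):
        h, amap = agcn_block(h, params, i, training)
        if amap is not None:
            attention.append(amap)
    h = smp(h)                                          # (N,C,T)
    if params.config.mtcn_kernels:
        h = mtcn_forward(h, params, training)
    h = tmp(h)                                          # (N,C)
    logits = ad.dense(h, params.head_w, params.head_b)
    return logits, attention


def forward(params: ModelParams, sequences, training: bool = False):
    """Class probabilities for a list of equal-length sequences (or one
    sequence): encode, run the trunk, softmax.  Returns (probs, attention)."""
    from .skeleton_io import SkeletonSequence
    single = isinstance(sequences, SkeletonSequence)
    seqs = [sequences] if single else list(sequences)
    encoded = encode_batch(seqs, params.encoder)
    logits, attention = forward_logits(params, encoded, training)
    probs = ad.softmax_probs(logits.data)
    return (probs[0] if single else probs), attention


def parameter_count(config: ModelConfig) -> int:
    """Exact number of learnable scalars in the model (the adjacency tensor
    is always counted, frozen or not)."""
    params = ModelParams(config, seed=0)
    return int(sum(t.size for t in params.named_tensors().values()))


def set_adjacency_trainable(params: ModelParams, epoch: int,
                            config: ModelConfig | None = None) -> ModelParams:
    """Apply the adjacency freeze schedule: frozen for the first
    ``adjacency_freeze_epochs`` epochs, learnable afterwards."""
    cfg = config or params.config
    trainable = epoch >= cfg.adjacency_freeze_epochs
    params.adjacency.requires_grad = trainable
    params.adjacency_trainable = trainable
    return params


# -------------------------------------------------------------- checkpoints

def save_checkpoint(params: ModelParams, path) -> None:
    arrays = {name: t.data for name, t in params.named_tensors().items()}
    arrays.update(params.buffers())
    arrays["__config__"] = np.array(json.dumps(params.config.to_dict()))
    arrays["__epoch__"] = np.array(params.epoch)
    arrays["__version__"] = np.array(CHECKPOINT_VERSION)
    arrays["__adj_trainable__"] = np.array(int(params.adjacency_trainable))
    np.savez(path, **arrays)


def load_checkpoint(path) -> ModelParams:
    with np.load(path, allow_pickle=False) as data:
        if int(data["__version__"]) != CHECKPOINT_VERSION:
            raise ValueError("unsupported checkpoint version")
        config = ModelConfig.from_dict(json.loads(str(data["__config__"])))
        params = ModelParams(config, seed=0,
                             dtype=data["head.w"].dtype)
        for name, t in params.named_tensors().items():
            t.data = data[name].copy()
        for name, buf in params.buffers().items():
            buf[...] = data[name]
        params.epoch = int(data["__epoch__"])
        set_adjacency_trainable(params, params.epoch)
        params.adjacency_trainable = bool(int(data["__adj_trainable__"]))
        params.adjacency.requires_grad = params.adjacency_trainable
    return params
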