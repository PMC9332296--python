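"""Per-joint dynamic feature construction and joint-type semantic encoding.

Each joint at each frame is described by four raw streams: its absolute
position, its position relative to the per-frame centre joint, and its
first- and second-order motion (one- and two-frame forward differences,
zero-filled at the trailing frames so T is preserved).  Positions and
motions are each passed through a 1x1 convolution + ReLU into a C1-wide
embedding and summed.  Separately, each joint's identity (one-hot over V)
goes through a two-layer ReLU MLP into another C1-wide "type semantics"
vector, which is concatenated along the channel axis — the network
therefore sees 2*C1 channels (32 with the default C1 = 16).

Streams are concatenated in a fixed, documented order: (absolute, relative)
and (first-order, second-order); position and motion embeddings use separate
weights since the two carry different physical meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .skeleton_io import SkeletonSequence

__all__ = [
    "EncoderParams", "relative_positions", "first_order_motion",
    "second_order_motion", "encode_joint_stream", "joint_type_semantics",
    "fuse_semantics", "encode_sequence",
]


@dataclass
class EncoderParams:
    """Learnable parameters of the feature encoder."""

    pos_weights: Tensor     # (2*C_coord, C1)
    pos_bias: Tensor        # (C1,)
    motion_weights: Tensor  # (2*C_coord, C1)
    motion_bias: Tensor     # (C1,)
    sem_W1: Tensor          # (V, C1)
    sem_b1: Tensor          # (C1,)
    sem_W2: Tensor          # (C1, C1)
    sem_b2: Tensor          # (C1,)

    @classmethod
    def init(cls, c_coord: int, c1: int, v: int, rng: np.random.Generator,
             dtype=np.float32) -> "EncoderParams":
        def w(shape):
            fan_in = shape[0]
            return Tensor(rng.normal(0, np.sqrt(2.0 / fan_in), shape)
                          .astype(dtype), requires_grad=True)
        def b(n):
            return Tensor(np.zeros(n, dtype=dtype), requires_grad=True)
        return cls(w((2 * c_coord, c1)), b(c1), w((2 * c_coord, c1)), b(c1),
                   w((v, c1)), b(c1), w((c1, c1)), b(c1))

    def tensors(self) -> dict[str, Tensor]:
        return {f"encoder.{k}": getattr(self, k) for k in (
            "pos_weights", "pos_bias", "motion_weights", "motion_bias",
            "sem_W1", "sem_b1", "sem_W2", "sem_b2")}


def relative_positions(seq: SkeletonSequence) -> np.ndarray:
    """Joint positions relative to the centre joint of the *same* frame."""
    return seq.values - seq.values[:, :, [seq.layout.center]]


def first_order_motion(seq: SkeletonSequence) -> np.ndarray:
    """One-frame forward difference; the last frame is zero-filled."""
    out = np.zeros_like(seq.values)
    out[:, :-1] = seq.values[:, 1:] - seq.values[:, :-1]
    return out


def second_order_motion(seq: SkeletonSequence) -> np.ndarray:
    """Two-frame forward difference; the last two frames are zero-filled."""
    out = np.zeros_like(seq.values)
    if seq.T > 2:
        out[:, :-2] = seq.values[:, 2:] - seq.values[:, :-2]
    return out


def encode_joint_stream(abs_rel: np.ndarray, motion: np.ndarray,
                        params: EncoderParams) -> Tensor:
    """Embed positions and motions to C1 channels and sum them.

    ``abs_rel`` and ``motion`` are (2*C_coord, T, V) stacks; the output is a
    (C1, T, V) tensor E = ReLU(W_pos * abs_rel) + ReLU(W_mot * motion).
    """
    if abs_rel.shape != motion.shape:
        raise ValueError("position and motion stacks must share a shape")
    if abs_rel.shape[0] != params.pos_weights.shape[0]:
        raise ValueError(
            f"stream has {abs_rel.shape[0]} channels, encoder expects "
            f"{params.pos_weights.shape[0]}")
    pos = ad.relu(ad.conv1x1(Tensor(abs_rel[None]), params.pos_weights,
                             params.pos_bias))
    mot = ad.relu(ad.conv1x1(Tensor(motion[None]), params.motion_weights,
                             params.motion_bias))
    return ad.reshape(ad.add(pos, mot), pos.shape[1:])


def joint_type_semantics(layout, params: EncoderParams) -> Tensor:
    """Type-semantics embedding p̄_i = ReLU(W2 ReLU(W1 onehot(i) + b1) + b2)
    for every joint, returned as a (C1, V) tensor."""
    if params.sem_W1.shape[0] != layout.V:
        raise ValueError("semantics weights do not match layout.V")
    onehot = Tensor(np.eye(layout.V,
                           dtype=params.sem_W1.data.dtype))  # row i = onehot(i)
    h = ad.relu(ad.dense(onehot, params.sem_W1, params.sem_b1))
    p = ad.relu(ad.dense(h, params.sem_W2, params.sem_b2))  # (V, C1)
    return ad.transpose(p, (1, 0))


def fuse_semantics(enc: Tensor, sem: Tensor) -> Tensor:
    """Concatenate dynamic features (C1,T,V) with type semantics (C1,V)
    broadcast over frames -> (2*C1, T, V)."""
    if enc.shape[0] != sem.shape[0] or enc.shape[2] != sem.shape[1]:
        raise ValueError(
            f"cannot fuse enc {enc.shape} with semantics {sem.shape}")
    T = enc.shape[1]
    sem3 = ad.reshape(sem, (sem.shape[0], 1, sem.shape[1]))
    tile = ad.mul(sem3, Tensor(np.ones((1, T, 1),
                                       dtype=sem.data.dtype)))  # over frames
    return ad.concat([enc, tile], axis=0)


def encode_sequence(seq: SkeletonSequence, params: EncoderParams) -> Tensor:
    """Full encoding of one sequence into a (2*C1, T, V) tensor."""
    abs_rel = np.concatenate([seq.values, relative_positions(seq)], axis=0)
    motion = np.concatenate(
        [first_order_motion(seq), second_order_motion(seq)], axis=0)
    enc = encode_joint_stream(abs_rel, motion, params)
    sem = joint_type_semantics(seq.layout, params)
    return fuse_semantics(enc, sem)


def encode_batch(seqs, params: EncoderParams) -> Tensor:
    """Encode a list of equal-length sequences into (N, 2*C1, T, V)."""
    dtype = params.pos_weights.data.dtype
    abs_rel = np.stack([np.concatenate(
        [s.values, relative_positions(s)], axis=0) for s in seqs]
    ).astype(dtype)
    motion = np.stack([np.concatenate(
        [first_order_motion(s), second_order_motion(s)], axis=0)
        for s in seqs]).astype(dtype)
    pos = ad.relu(ad.conv1x1(Tensor(abs_rel), params.pos_weights,
                             params.pos_bias))
    mot = ad.relu(ad.conv1x1(Tensor(motion), params.motion_weights,
                             params.motion_bias))
    enc = ad.add(pos, mot)                       # (N, C1, T, V)
    sem = joint_type_semantics(seqs[0].layout, params)   # (C1, V)
    n, _, T, v = enc.shape
    sem4 = ad.reshape(sem, (1, sem.shape[0], 1, v))
    ones = Tensor(np.ones((n, 1, T, 1), dtype=dtype))
    tile = ad.mul(sem4, ones)                    # broadcast over N and T
    return ad.concat([enc, tile], axis=1)
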