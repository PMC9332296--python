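"""Reading, normalising, padding and augmenting skeleton sequences.

A :class:`SkeletonSequence` is a ``C x T x V`` array of per-joint channels
over time.  Two on-disk pose dialects are supported: per-frame OpenPose JSON
(BODY_25: x, y, score triplets; channels become (x, y, score) with the score
duplicated into the ``confidence`` array) and the plain-text NTU RGB+D
``.skeleton`` format (x, y, z per joint).  Joints the pose extractor missed
are all-zero with confidence 0 — never NaN.

Preprocessing follows the standard recipe for skeleton action recognition:
subtract the centre joint of the first frame from every coordinate, replay
the sequence cyclically up to a fixed frame count (300 by default), and
optionally rotate the whole skeleton by a random small angle to emulate a
camera viewpoint change.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np

from .graph_topology import JointLayout, builtin_layout

log = logging.getLogger(__name__)

BUNDLE_VERSION = 1

__all__ = [
    "SkeletonSequence", "read_openpose_json", "read_ntu_skeleton",
    "normalize_to_center", "pad_by_replay", "fit_length", "rotate_augment",
    "save_bundle", "load_bundle",
]


@dataclass
class SkeletonSequence:
    """One person's joint coordinates over time, ``values: C x T x V``.

    ``coord_channels`` marks how many leading channels are spatial
    coordinates (2 for image-plane OpenPose output whose third channel is
    the detection score, 3 for Kinect x/y/z); only those are shifted by
    normalisation or mixed by rotation.
    """

    values: np.ndarray
    layout: JointLayout
    label: int | None = None
    confidence: np.ndarray | None = None
    source_id: str = ""
    coord_channels: int = 3

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be C x T x V")
        if self.values.shape[1] < 1:
            raise ValueError("sequence needs at least one frame")
        if self.values.shape[2] != self.layout.V:
            raise ValueError(
                f"joint axis {self.values.shape[2]} != layout.V {self.layout.V}")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain NaN/inf")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=np.float64)
            if self.confidence.shape != self.values.shape[1:]:
                raise ValueError("confidence must be T x V")
            if (self.confidence < 0).any() or (self.confidence > 1).any():
                raise ValueError("confidence must lie in [0, 1]")
        if not (1 <= self.coord_channels <= self.values.shape[0]):
            raise ValueError("coord_channels out of range")

    @property
    def C(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @property
    def V(self) -> int:
        return self.values.shape[2]


# ------------------------------------------------------------------- readers

def read_openpose_json(paths, layout: JointLayout) -> SkeletonSequence:
    """Assemble a sequence from ordered per-frame OpenPose JSON files.

    Channels are (x, y, score); when several people are detected the one
    with the highest summed keypoint score is kept.  Frames with no person
    become all-zero columns with zero confidence.
    """
    paths = list(paths)
    T = len(paths)
    values = np.zeros((3, T, layout.V))
    for t, path in enumerate(paths):
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed OpenPose JSON in {path}: {exc}") from exc
        people = doc.get("people", [])
        if not people:
            continue
        best = None
        for person in people:
            kp = np.asarray(person["pose_keypoints_2d"], dtype=np.float64)
            if kp.size != 3 * layout.V:
                raise ValueError(
                    f"{path}: {kp.size // 3} keypoints but layout "
                    f"{layout.name!r} has {layout.V} joints")
            kp = kp.reshape(layout.V, 3)
            score = kp[:, 2].sum()
            if best is None or score > best[0]:
                best = (score, kp)
        values[:, t, :] = best[1].T
    conf = np.clip(values[2], 0.0, 1.0)
    values[2] = conf
    return SkeletonSequence(values, layout, confidence=conf,
                            source_id=str(paths[0]) if paths else "",
                            coord_channels=2)


def read_ntu_skeleton(path, layout: JointLayout | None = None) -> SkeletonSequence:
    """Parse an NTU RGB+D ``.skeleton`` text file (first body only).

    The dialect: frame count, then per frame a body count, per body an info
    line, a joint count, and one line per joint whose first three fields
    are x y z.
    """
    if layout is None:
        layout = builtin_layout("ntu25")
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    pos = 0

    def next_line():
        nonlocal pos
        while pos < len(lines) and not lines[pos]:
            pos += 1
        if pos >= len(lines):
            raise ValueError(f"{path}: truncated file at line {pos + 1}")
        pos += 1
        return lines[pos - 1]

    try:
        T = int(next_line())
    except ValueError as exc:
        raise ValueError(f"{path}: bad frame count header") from exc
    if T < 1:
        raise ValueError(f"{path}: empty sequence (0 frames)")
    values = np.zeros((3, T, layout.V))
    for t in range(T):
        nbodies = int(next_line())
        for b in range(nbodies):
            next_line()  # body info line (tracking id, flags, ...)
            njoints = int(next_line())
            if njoints != layout.V:
                raise ValueError(
                    f"{path}: frame {t} has {njoints} joints, layout "
                    f"{layout.name!r} expects {layout.V}")
            for j in range(njoints):
                fields = next_line().split()
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}: short joint line at line {pos}")
                if b == 0:  # keep the first body only
                    values[:, t, j] = [float(x) for x in fields[:3]]
    return SkeletonSequence(values, layout, source_id=str(path),
                            coord_channels=3)


# ------------------------------------------------------------- preprocessing

def normalize_to_center(seq: SkeletonSequence) -> SkeletonSequence:
    """Shift all frames so the centre joint of frame 0 is the origin.

    Only the coordinate channels are shifted; a score channel is left
    alone.  If the centre joint was not detected in frame 0 (confidence 0),
    the first joint with nonzero confidence stands in, with a warning.
    """
    center = seq.layout.center
    if seq.confidence is not None and seq.confidence[0, center] == 0:
        nonzero = np.flatnonzero(seq.confidence[0] > 0)
        if nonzero.size:
            log.warning(
                "centre joint %d undetected in frame 0 of %s; using joint %d",
                center, seq.source_id or "<sequence>", nonzero[0])
            center = int(nonzero[0])
        else:
            log.warning("no joint detected in frame 0 of %s; no shift applied",
                        seq.source_id or "<sequence>")
            return replace(seq, values=seq.values.copy())
    nc = seq.coord_channels
    values = seq.values.copy()
    origin = seq.values[:nc, 0, center]
    values[:nc] -= origin[:, None, None]
    return replace(seq, values=values)


def pad_by_replay(seq: SkeletonSequence, target_T: int) -> SkeletonSequence:
    """Extend a sequence to ``target_T`` frames by replaying it cyclically."""
    if target_T < seq.T:
        raise ValueError(
            f"cannot replay-pad {seq.T} frames down to {target_T}; "
            "subsample first (see fit_length)")
    idx = np.arange(target_T) % seq.T
    conf = seq.confidence[idx] if seq.confidence is not None else None
    return replace(seq, values=seq.values[:, idx, :], confidence=conf)


def fit_length(seq: SkeletonSequence, target_T: int) -> SkeletonSequence:
    """Bring a sequence to exactly ``target_T`` frames: sequences longer than
    the target are subsampled with a uniform stride, shorter ones replayed."""
    if seq.T > target_T:
        idx = np.linspace(0, seq.T - 1, target_T).round().astype(int)
        conf = seq.confidence[idx] if seq.confidence is not None else None
        seq = replace(seq, values=seq.values[:, idx, :], confidence=conf)
    return pad_by_replay(seq, target_T)


def _rotation_matrix(angles) -> np.ndarray:
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def rotate_augment(seq: SkeletonSequence, max_angle: float,
                   seed: int) -> SkeletonSequence:
    """Rotate the whole skeleton by random per-axis angles in
    ``[-max_angle, +max_angle]`` radians (in-plane rotation only when the
    sequence has two coordinate channels).  Deterministic in ``seed``."""
    if max_angle < 0:
        raise ValueError("max_angle must be nonnegative")
    rng = np.random.default_rng(seed)
    nc = seq.coord_channels
    values = seq.values.copy()
    if nc >= 3:
        angles = rng.uniform(-max_angle, max_angle, size=3)
        rot = _rotation_matrix(angles)
        values[:3] = np.einsum("ij,jtv->itv", rot, values[:3])
    else:
        theta = rng.uniform(-max_angle, max_angle)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        values[:2] = np.einsum("ij,jtv->itv", rot, values[:2])
    return replace(seq, values=values)


# ------------------------------------------------------------------- bundles

def save_bundle(sequences, path) -> None:
    """Write sequences to a compressed ``.npz`` bundle (lossless)."""
    sequences = list(sequences)
    layouts = {seq.layout.name for seq in sequences}
    if len(layouts) > 1:
        raise ValueError(f"bundle requires a single layout, got {layouts}")
    arrays = {
        "version": np.array(BUNDLE_VERSION),
        "n": np.array(len(sequences)),
    }
    if sequences:
        arrays["layout"] = np.array(
            json.dumps(sequences[0].layout.to_dict()))
    for i, seq in enumerate(sequences):
        arrays[f"values_{i}"] = seq.values
        arrays[f"meta_{i}"] = np.array(json.dumps({
            "label": seq.label, "source_id": seq.source_id,
            "coord_channels": seq.coord_channels,
            "has_confidence": seq.confidence is not None}))
        if seq.confidence is not None:
            arrays[f"confidence_{i}"] = seq.confidence
    np.savez_compressed(path, **arrays)


def load_bundle(path) -> list[SkeletonSequence]:
    with np.load(path, allow_pickle=False) as data:
        version = int(data["version"])
        if version != BUNDLE_VERSION:
            raise ValueError(
                f"bundle version {version} unsupported "
                f"(expected {BUNDLE_VERSION})")
        n = int(data["n"])
        if n == 0:
            return []
        layout = JointLayout.from_dict(json.loads(str(data["layout"])))
        out = []
        for i in range(n):
            meta = json.loads(str(data[f"meta_{i}"]))
            conf = (data[f"confidence_{i}"]
                    if meta["has_confidence"] else None)
            out.append(SkeletonSequence(
                data[f"values_{i}"], layout,
                label=meta["label"], confidence=conf,
                source_id=meta["source_id"],
                coord_channels=meta["coord_channels"]))
        return out
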