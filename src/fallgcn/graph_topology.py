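"""Skeleton graph layouts, body-part subgraph division, and the partitioned
adjacency tensor.

The skeleton is modelled as an undirected tree of joints.  For graph
convolution, neighbour aggregation is split into ``l = 3`` adjacency subsets
following the spatial-configuration partition of ST-GCN: subset 0 holds
self-connections, subset 1 the centripetal bonds (the receiving joint is
nearer the body centre than the sender), and subset 2 the centrifugal
reverse.  The skeleton is additionally divided into five body-part subgraphs
(torso + four limbs) that share their root joints (shoulders, hips); each
part contributes its own partitioned adjacency and the per-part matrices are
superimposed and clipped to binary, so partitioning never invents or loses a
bone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "JointLayout", "SubgraphScheme", "AdjacencyTensor", "builtin_layout",
    "divide_subgraphs", "subgraph_adjacency", "assemble_adjacency",
    "hop_distances",
]


@dataclass(frozen=True)
class JointLayout:
    """A named skeleton topology: joints, bones, and the centre joint."""

    name: str
    V: int
    edges: tuple[tuple[int, int], ...]
    center: int
    joint_names: tuple[str, ...] = ()

    def __post_init__(self):
        for i, j in self.edges:
            if not (0 <= i < self.V and 0 <= j < self.V):
                raise ValueError(f"edge ({i},{j}) out of range for V={self.V}")
            if i == j:
                raise ValueError(f"self-loop ({i},{j}) in edge list")
        if not (0 <= self.center < self.V):
            raise ValueError(f"center {self.center} out of range")
        if self.joint_names and len(self.joint_names) != self.V:
            raise ValueError("joint_names length must equal V")
        if not _connected(self.V, self.edges):
            raise ValueError(f"layout {self.name!r} graph is not connected")

    def edge_set(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges}

    def to_dict(self) -> dict:
        return {"name": self.name, "V": self.V,
                "edges": [list(e) for e in self.edges],
                "center": self.center,
                "joint_names": list(self.joint_names)}

    @classmethod
    def from_dict(cls, d: dict) -> "JointLayout":
        return cls(name=d["name"], V=int(d["V"]),
                   edges=tuple((int(a), int(b)) for a, b in d["edges"]),
                   center=int(d["center"]),
                   joint_names=tuple(d.get("joint_names", ())))


@dataclass(frozen=True)
class SubgraphScheme:
    """Division of a layout into overlapping body-part node sets."""

    parts: tuple[tuple[int, ...], ...]
    layout: JointLayout
    part_names: tuple[str, ...] = ()

    def __post_init__(self):
        V = self.layout.V
        union = set()
        for part in self.parts:
            if len(set(part)) != len(part):
                raise ValueError("duplicate joint inside a part")
            union |= set(part)
        if union != set(range(V)):
            raise ValueError("parts do not cover all joints")
        for i, j in self.layout.edges:
            if not any(i in p and j in p for p in
                       (set(p) for p in self.parts)):
                raise ValueError(
                    f"bone ({i},{j}) crosses parts with no shared container")

    @property
    def g(self) -> int:
        return len(self.parts)

    @property
    def M(self) -> int:
        return max(len(p) for p in self.parts)

    @property
    def shared(self) -> frozenset:
        counts = np.zeros(self.layout.V, dtype=int)
        for part in self.parts:
            counts[list(part)] += 1
        return frozenset(np.flatnonzero(counts >= 2).tolist())

    def membership_counts(self) -> np.ndarray:
        counts = np.zeros(self.layout.V, dtype=int)
        for part in self.parts:
            counts[list(part)] += 1
        return counts

    def to_dict(self) -> dict:
        return {"layout": self.layout.to_dict(),
                "parts": [list(p) for p in self.parts],
                "part_names": list(self.part_names)}


@dataclass
class AdjacencyTensor:
    """Stacked ``l x V x V`` adjacency subsets (l = 3)."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3 or v.shape[0] != 3 or v.shape[1] != v.shape[2]:
            raise ValueError("adjacency tensor must be 3 x V x V")
        if (v < 0).any():
            raise ValueError("adjacency entries must be nonnegative")
        if np.any(v[0] * (1 - np.eye(v.shape[1])) != 0):
            raise ValueError("subset 0 must be diagonal")
        if np.any(np.diagonal(v[1]) != 0) or np.any(np.diagonal(v[2]) != 0):
            raise ValueError("subsets 1 and 2 must have zero diagonal")
        self.values = v

    @property
    def l(self) -> int:
        return self.values.shape[0]

    @property
    def V(self) -> int:
        return self.values.shape[1]

    def support(self) -> np.ndarray:
        """Boolean V x V matrix of positions covered by any subset."""
        return (self.values > 0).any(axis=0)


# --------------------------------------------------------------- layouts

def _connected(V: int, edges) -> bool:
    adj = [[] for _ in range(V)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == V


def hop_distances(layout: JointLayout, source: int | None = None) -> np.ndarray:
    """Breadth-first hop distance of every joint from ``source``
    (default: the layout centre)."""
    src = layout.center if source is None else source
    adj = [[] for _ in range(layout.V)]
    for i, j in layout.edges:
        adj[i].append(j)
        adj[j].append(i)
    dist = np.full(layout.V, -1, dtype=int)
    dist[src] = 0
    queue = [src]
    while queue:
        nxt = []
        for u in queue:
            for w in adj[u]:
                if dist[w] < 0:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        queue = nxt
    return dist


# Kinect v2 joint order used by the NTU RGB+D skeleton files (0-based).
_NTU25_NAMES = (
    "spine_base", "spine_mid", "neck", "head",
    "shoulder_l", "elbow_l", "wrist_l", "hand_l",
    "shoulder_r", "elbow_r", "wrist_r", "hand_r",
    "hip_l", "knee_l", "ankle_l", "foot_l",
    "hip_r", "knee_r", "ankle_r", "foot_r",
    "spine_shoulder", "hand_tip_l", "thumb_l", "hand_tip_r", "thumb_r",
)
_NTU25_EDGES = (
    (0, 1), (1, 20), (2, 20), (3, 2),
    (4, 20), (5, 4), (6, 5), (7, 6), (21, 7), (22, 7),
    (8, 20), (9, 8), (10, 9), (11, 10), (23, 11), (24, 11),
    (12, 0), (13, 12), (14, 13), (15, 14),
    (16, 0), (17, 16), (18, 17), (19, 18),
)

# OpenPose BODY_25 keypoint order.
_BODY25_NAMES = (
    "nose", "neck", "shoulder_r", "elbow_r", "wrist_r",
    "shoulder_l", "elbow_l", "wrist_l", "mid_hip",
    "hip_r", "knee_r", "ankle_r", "hip_l", "knee_l", "ankle_l",
    "eye_r", "eye_l", "ear_r", "ear_l",
    "big_toe_l", "small_toe_l", "heel_l",
    "big_toe_r", "small_toe_r", "heel_r",
)
_BODY25_EDGES = (
    (0, 1), (1, 2), (2, 3), (3, 4), (1, 5), (5, 6), (6, 7),
    (1, 8), (8, 9), (9, 10), (10, 11), (8, 12), (12, 13), (13, 14),
    (0, 15), (15, 17), (0, 16), (16, 18),
    (14, 19), (19, 20), (14, 21), (11, 22), (22, 23), (11, 24),
)

_NTU25_PARTS = (
    ("torso", (0, 1, 20, 2, 3, 4, 8, 12, 16)),
    ("arm_l", (4, 5, 6, 7, 21, 22)),
    ("arm_r", (8, 9, 10, 11, 23, 24)),
    ("leg_l", (12, 13, 14, 15)),
    ("leg_r", (16, 17, 18, 19)),
)
# Head/face joints live with the torso; the mid-hip is shared by the torso
# and both legs so every pelvis bone stays inside a part.
_BODY25_PARTS = (
    ("torso", (0, 1, 8, 15, 16, 17, 18, 2, 5, 9, 12)),
    ("arm_l", (5, 6, 7)),
    ("arm_r", (2, 3, 4)),
    ("leg_l", (8, 12, 13, 14, 19, 20, 21)),
    ("leg_r", (8, 9, 10, 11, 22, 23, 24)),
)


def builtin_layout(name: str) -> JointLayout:
    """Return one of the canonical layouts: ``ntu25``, ``body25`` or a toy
    path graph ``toy-path-k`` (joints 0-1-...-k-1, centre k//2)."""
    if name == "ntu25":
        return JointLayout("ntu25", 25, _NTU25_EDGES, center=1,
                           joint_names=_NTU25_NAMES)
    if name == "body25":
        return JointLayout("body25", 25, _BODY25_EDGES, center=8,
                           joint_names=_BODY25_NAMES)
    if name.startswith("toy-path-"):
        k = int(name.rsplit("-", 1)[1])
        if k < 2:
            raise ValueError("toy path needs at least 2 joints")
        edges = tuple((i, i + 1) for i in range(k - 1))
        return JointLayout(name, k, edges, center=k // 2)
    raise ValueError(
        f"unknown layout {name!r}; available: ntu25, body25, toy-path-<k>")


def divide_subgraphs(layout: JointLayout, g: int = 5) -> SubgraphScheme:
    """Divide a layout into body-part subgraphs (torso + four limbs).

    For the builtin body layouts only ``g = 5`` is meaningful; toy path
    layouts are split into ``g`` overlapping contiguous chunks for testing.
    """
    if layout.name == "ntu25":
        if g != 5:
            raise ValueError("ntu25 supports only the five-part division")
        names, parts = zip(*_NTU25_PARTS)
        return SubgraphScheme(tuple(parts), layout, tuple(names))
    if layout.name == "body25":
        if g != 5:
            raise ValueError("body25 supports only the five-part division")
        names, parts = zip(*_BODY25_PARTS)
        return SubgraphScheme(tuple(parts), layout, tuple(names))
    if layout.name.startswith("toy-path-"):
        V = layout.V
        if g < 1 or g > V - 1:
            raise ValueError("invalid part count for toy path")
        # overlapping chunks sharing one boundary joint
        bounds = np.linspace(0, V - 1, g + 1).round().astype(int)
        parts = tuple(tuple(range(bounds[i], bounds[i + 1] + 1))
                      for i in range(g))
        return SubgraphScheme(parts, layout)
    raise ValueError(f"no builtin division for layout {layout.name!r}")


def whole_graph_scheme(layout: JointLayout) -> SubgraphScheme:
    """Degenerate scheme with a single part holding every joint (used when
    subgraph division is ablated)."""
    return SubgraphScheme((tuple(range(layout.V)),), layout, ("all",))


# ----------------------------------------------------- adjacency construction

def subgraph_adjacency(layout: JointLayout, part, l_index: int) -> np.ndarray:
    """The ``V x V`` adjacency matrix of one part's l-th subset.

    Subset 0: self-loops of part joints.  Subset 1 (centripetal): for each
    bone inside the part, the joint nearer the layout centre receives from
    the farther one.  Subset 2: the transpose.  Rows index the receiving
    joint.  A bone whose endpoints are equidistant from the centre (possible
    only in cyclic layouts) is placed symmetrically in both subsets.
    """
    if l_index not in (0, 1, 2):
        raise ValueError("l_index must be 0, 1 or 2")
    part = set(int(v) for v in part)
    if not part <= set(range(layout.V)):
        raise ValueError("part contains joints outside the layout")
    A = np.zeros((layout.V, layout.V))
    if l_index == 0:
        for v in part:
            A[v, v] = 1.0
        return A
    dist = hop_distances(layout)
    for i, j in layout.edges:
        if i not in part or j not in part:
            continue
        near, far = (i, j) if dist[i] < dist[j] else (j, i)
        if dist[i] == dist[j]:
            A[i, j] = A[j, i] = 1.0
        elif l_index == 1:
            A[near, far] = 1.0
        else:
            A[far, near] = 1.0
    return A


def _row_normalize(a: np.ndarray) -> np.ndarray:
    deg = a.sum(axis=1, keepdims=True)
    return np.divide(a, deg, out=np.zeros_like(a), where=deg > 0)


def assemble_adjacency(layout: JointLayout, scheme: SubgraphScheme,
                       normalized: bool = True) -> AdjacencyTensor:
    """Superimpose every part's partitioned adjacency into the full
    ``3 x V x V`` tensor.

    Bones shared by two parts are counted once (binary clip), so the summed
    support over subsets is exactly self-loops plus the layout's bones.
    When ``normalized``, each subset is row-normalised (D^-1 A), making each
    receiving joint average over its senders.
    """
    V = layout.V
    values = np.zeros((3, V, V))
    for part in scheme.parts:
        for l_index in range(3):
            values[l_index] += subgraph_adjacency(layout, part, l_index)
    values = (values > 0).astype(np.float64)
    if normalized:
        values = np.stack([_row_normalize(values[l]) for l in range(3)])
    return AdjacencyTensor(values, normalized=normalized)


def save_topology(layout: JointLayout, scheme: SubgraphScheme, path) -> None:
    with open(path, "w") as fh:
        json.dump(scheme.to_dict(), fh, indent=1)


def load_topology(path) -> tuple[JointLayout, SubgraphScheme]:
    with open(path) as fh:
        d = json.load(fh)
    layout = JointLayout.from_dict(d["layout"])
    scheme = SubgraphScheme(
        tuple(tuple(int(v) for v in p) for p in d["parts"]), layout,
        tuple(d.get("part_names", ())))
    return layout, scheme
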