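"""Deterministic kinematic generator of labelled stick-figure sequences.

The generator stands in for recorded fall datasets.  It emulates the two
structural facts the recognition task rests on: during a fall the body's
centre of gravity drops from a high to a low position, and the displacement
magnitude differs strongly across body parts (the head moves far more than
the legs).  The five confusable daily activities (drop, pick up, sit down,
wear a shoe, take off a shoe) share partial centre-of-gravity descent or
limb motion with falls, which is exactly what makes the classification
non-trivial.

Each class is a documented constant template: a start/end height for the
hip (the centre-of-gravity proxy), the fraction of the sequence spent
descending, per-part displacement scales, a limb-oscillation frequency, and
a coordinate noise level.  Sequences are 3-D (y is the vertical axis, in
metres); a projection switch produces 2-D + score variants so the OpenPose
reading path can be exercised too.

Templates are constants chosen for structure, not fitted to any recording;
they do not reproduce biomechanical detail.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .graph_topology import JointLayout, builtin_layout
from .skeleton_io import SkeletonSequence

__all__ = ["MotionClassSpec", "CLASS_NAMES", "CLASS_SPECS", "class_spec",
           "generate_sequence", "generate_dataset", "rest_pose"]

CLASS_NAMES = ("drop", "pick_up", "sit_down", "wear_shoe",
               "take_off_shoe", "fall")

#: world-coordinate bounding box every generated joint stays inside
BOUNDING_BOX = ((-3.0, 3.0), (-0.5, 3.0), (-3.0, 3.0))


@dataclass(frozen=True)
class MotionClassSpec:
    """Kinematic template of one action class."""

    name: str
    start_height: float          # hip height at t=0 (m)
    end_height_ratio: float      # hip height at the end, as a fraction
    descent_fraction: float      # fraction of the sequence spent descending
    head_scale: float            # extra displacement amplitude per part (m)
    torso_scale: float
    arm_scale: float
    leg_scale: float
    arm_freq: float              # limb oscillation cycles per sequence
    leg_freq: float
    lean: float                  # forward pitch of the trunk at the end (rad)
    noise_std: float = 0.01      # i.i.d. Gaussian coordinate noise (m)
    duration_range: tuple[int, int] = (40, 70)


# Class templates.  The fall drops the hip below 30% of its start height
# with the head displaced far more than the legs; sit-down/pick-up descend
# part-way (confusable); the shoe classes keep the centre of gravity up and
# differ mainly in arm/leg phase.
CLASS_SPECS: dict[str, MotionClassSpec] = {
    "drop": MotionClassSpec(
        "drop", 1.0, 0.72, 0.35, 0.10, 0.05, 0.55, 0.06,
        arm_freq=1.0, leg_freq=0.3, lean=0.5),
    "pick_up": MotionClassSpec(
        "pick_up", 1.0, 0.55, 0.55, 0.28, 0.16, 0.40, 0.10,
        arm_freq=0.5, leg_freq=0.4, lean=0.9),
    "sit_down": MotionClassSpec(
        "sit_down", 1.0, 0.50, 0.60, 0.10, 0.10, 0.12, 0.30,
        arm_freq=0.4, leg_freq=0.6, lean=0.25),
    "wear_shoe": MotionClassSpec(
        "wear_shoe", 1.0, 0.88, 0.25, 0.08, 0.05, 0.35, 0.45,
        arm_freq=2.2, leg_freq=1.2, lean=0.35),
    "take_off_shoe": MotionClassSpec(
        "take_off_shoe", 1.0, 0.90, 0.20, 0.06, 0.04, 0.30, 0.50,
        arm_freq=1.6, leg_freq=2.0, lean=0.20),
    "fall": MotionClassSpec(
        "fall", 1.0, 0.12, 0.45, 0.85, 0.45, 0.25, 0.12,
        arm_freq=0.8, leg_freq=0.5, lean=1.45),
}
assert set(CLASS_SPECS) == set(CLASS_NAMES)
assert CLASS_SPECS["fall"].end_height_ratio < 0.3
assert CLASS_SPECS["fall"].head_scale > CLASS_SPECS["fall"].leg_scale


def class_spec(name: str) -> MotionClassSpec:
    try:
        return CLASS_SPECS[name]
    except KeyError:
        raise ValueError(
            f"unknown class {name!r}; known: {', '.join(CLASS_NAMES)}"
        ) from None


# -------------------------------------------------------------- stick figure

def _part_of(layout: JointLayout) -> list[str]:
    """Coarse body-part tag per joint, by name."""
    if not layout.joint_names:
        return ["torso"] * layout.V
    tags = []
    for nm in layout.joint_names:
        if any(s in nm for s in ("head", "neck", "nose", "eye", "ear")):
            tags.append("head")
        elif any(s in nm for s in ("shoulder", "elbow", "wrist", "hand",
                                   "thumb")):
            tags.append("arm")
        elif any(s in nm for s in ("hip", "knee", "ankle", "foot", "toe",
                                   "heel")):
            tags.append("leg")
        else:
            tags.append("torso")
    return tags


def rest_pose(layout: JointLayout) -> np.ndarray:
    """A standing pose (3, V): x lateral, y up, z forward, metres.

    Proportions are schematic; the hip/centre joint sits at y = 1.
    """
    tags = _part_of(layout)
    pose = np.zeros((3, layout.V))
    arm_i, leg_i = 0, 0
    for v, (nm, tag) in enumerate(zip(layout.joint_names, tags)):
        side = -1.0 if nm.endswith("_l") else 1.0
        if tag == "head":
            y = 1.62 if "neck" in nm else 1.72
            pose[:, v] = (0.05 * side if nm.endswith(("_l", "_r")) else 0.0,
                          y, 0.0)
        elif tag == "torso":
            spine_y = {"spine_base": 0.88, "mid_hip": 1.0,
                       "spine_mid": 1.0, "spine_shoulder": 1.4}
            pose[:, v] = (0.0, spine_y.get(nm, 1.1), 0.0)
        elif tag == "arm":
            order = ("shoulder", "elbow", "wrist", "hand_tip", "hand",
                     "thumb")
            depth = next((i for i, s in enumerate(order) if s in nm), 2)
            pose[:, v] = (side * (0.22 + 0.07 * depth),
                          1.48 - 0.16 * depth, 0.0)
        else:  # leg
            order = ("hip", "knee", "ankle", "heel", "foot", "toe")
            depth = next((i for i, s in enumerate(order) if s in nm), 2)
            pose[:, v] = (side * 0.12, max(1.0 - 0.33 * depth, 0.02),
                          0.02 * depth)
    if not layout.joint_names:  # toy layouts: a vertical chain
        pose[1] = np.linspace(0.0, 1.0, layout.V)
    # anchor the centre joint at (0, 1, 0)
    pose[0] -= pose[0, layout.center]
    pose[2] -= pose[2, layout.center]
    pose[1] += 1.0 - pose[1, layout.center]
    return pose


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def generate_sequence(spec: MotionClassSpec, layout: JointLayout | None = None,
                      T: int = 48, seed: int = 0,
                      project_2d: bool = False) -> SkeletonSequence:
    """Generate one labelled sequence from a class template.

    The hip height interpolates from ``start_height`` to
    ``end_height_ratio * start_height`` over the descent window; each body
    part is additionally displaced along the fall direction in proportion
    to its template scale, limbs oscillate at class-specific frequencies,
    and i.i.d. Gaussian noise is added to every coordinate.  Identical
    ``(spec, layout, T, seed)`` give bitwise-identical output.

    With ``project_2d`` the x/y image-plane projection is returned with a
    constant score channel, mimicking pose-extractor output.
    """
    if spec.name not in CLASS_SPECS:
        raise ValueError(f"unknown class {spec.name!r}")
    if T < 8:
        raise ValueError("need at least 8 frames")
    layout = layout or builtin_layout("ntu25")
    rng = np.random.default_rng(seed)
    base = rest_pose(layout)
    tags = _part_of(layout)
    scale_of = {"head": spec.head_scale, "torso": spec.torso_scale,
                "arm": spec.arm_scale, "leg": spec.leg_scale}
    part_scale = np.array([scale_of[t] for t in tags])
    is_arm = np.array([t == "arm" for t in tags])
    is_leg = np.array([t == "leg" for t in tags])
    heights = base[1] - base[1, layout.center]   # offset above the hip

    u = np.linspace(0.0, 1.0, T)
    prog = _smoothstep(u / max(spec.descent_fraction, 1e-9))
    hip_y = spec.start_height + (
        spec.end_height_ratio - 1.0) * spec.start_height * prog
    pitch = spec.lean * prog                     # trunk pitch, rad

    values = np.empty((3, T, layout.V))
    phase = rng.uniform(0.0, 2 * np.pi)
    for t in range(T):
        cp, sp = np.cos(pitch[t]), np.sin(pitch[t])
        # rotate the standing offsets about the hip (pitch in the y-z plane)
        y = hip_y[t] + heights * cp
        z = base[2] + heights * sp
        x = base[0].copy()
        # per-part displacement along the motion direction
        x += 0.15 * part_scale * prog[t] * np.sign(base[0] + 1e-9)
        z += part_scale * prog[t]
        # limb oscillation
        osc_a = np.sin(2 * np.pi * spec.arm_freq * u[t] + phase)
        osc_l = np.cos(2 * np.pi * spec.leg_freq * u[t] + phase)
        z += 0.12 * spec.arm_scale * osc_a * is_arm
        x += 0.10 * spec.leg_scale * osc_l * is_leg
        values[:, t, :] = (x, y, z)
    values += rng.normal(0.0, spec.noise_std, size=values.shape)
    for axis, (lo, hi) in enumerate(BOUNDING_BOX):
        np.clip(values[axis], lo, hi, out=values[axis])

    label = CLASS_NAMES.index(spec.name)
    if project_2d:
        vals2 = np.stack([values[0], values[1],
                          np.ones_like(values[0])])
        conf = np.ones((T, layout.V))
        return SkeletonSequence(vals2, layout, label=label, confidence=conf,
                                source_id=f"synth:{spec.name}:{seed}",
                                coord_channels=2)
    return SkeletonSequence(values, layout, label=label,
                            source_id=f"synth:{spec.name}:{seed}",
                            coord_channels=3)


def generate_dataset(n_per_class: int, layout: JointLayout | None = None,
                     T_range: tuple[int, int] = (40, 70), seed: int = 0,
                     classes=CLASS_NAMES, noise_std: float | None = None,
                     project_2d: bool = False) -> list[SkeletonSequence]:
    """A balanced labelled dataset, ``n_per_class`` sequences per class.

    Per-sequence seeds and durations derive from the master seed, so the
    whole dataset is reproducible from ``(n_per_class, T_range, seed)``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    layout = layout or builtin_layout("ntu25")
    master = np.random.default_rng(seed)
    out = []
    for name in classes:
        spec = class_spec(name)
        if noise_std is not None:
            spec = replace(spec, noise_std=noise_std)
        lo, hi = spec.duration_range
        lo, hi = max(lo, T_range[0]), min(hi, T_range[1])
        if lo > hi:
            lo, hi = T_range
        for _ in range(n_per_class):
            T = int(master.integers(lo, hi + 1))
            sub = int(master.integers(0, 2**31 - 1))
            out.append(generate_sequence(spec, layout, T=T, seed=sub,
                                         project_2d=project_2d))
    return out
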