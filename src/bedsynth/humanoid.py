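"""Parametric articulated human body.

A procedural stand-in for statistical body models (SMPL-X class): a fixed
kinematic tree, 10 shape coefficients (*betas*), joint-wise axis-angle poses,
forward kinematics, and a capsule/ellipsoid surface mesh.  The tree ships as a
versioned plain-text asset and contains the 22 SMPL-X-compatible body joints
plus 5 face markers, so the 17 COCO person keypoints are a subset.

Conventions
-----------
* World frame: right-handed, +z up; pelvis (root) at the origin; rest pose is
  supine along +x (head towards +x), left body side towards +y.
* Rotations compose down the tree: ``R_global(j) = R_global(parent) @ R_local(j)``;
  a child's position is ``x(parent) + R_global(parent) @ (s * rest_offset)``
  where ``s`` is the stature scale derived from ``betas[0]``.
* Axis-angle vectors have norm (= angle) in ``[0, pi]``.

An adapter seam is deliberately left open: anything producing joint positions
over this tree (e.g. a real SMPL-X fit) can feed :func:`pose_from_joint_positions`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError, ParameterError

__all__ = [
    "KinematicTree",
    "BodyShape",
    "PoseAA",
    "HumanMesh",
    "COCO_KEYPOINT_NAMES",
    "load_kinematic_tree",
    "load_joint_limits",
    "default_tree",
    "sample_body_shape",
    "forward_kinematics",
    "pose_from_joint_positions",
    "build_surface_mesh",
]

#: The 17 person keypoints in canonical COCO order.
COCO_KEYPOINT_NAMES = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

# Stature / girth sensitivity of the first two shape coefficients.
_STATURE_GAIN = 0.05
_GIRTH_GAIN = 0.08


@dataclass(frozen=True)
class KinematicTree:
    """Joint hierarchy with rest-pose offsets (metres)."""

    joint_names: tuple[str, ...]
    parent_index: np.ndarray  # (J,) int, -1 for the root
    rest_offset: np.ndarray  # (J, 3) float

    def __post_init__(self) -> None:
        J = len(self.joint_names)
        if self.parent_index.shape != (J,) or self.rest_offset.shape != (J, 3):
            raise ParameterError("tree arrays inconsistent with joint count")
        roots = np.flatnonzero(self.parent_index < 0)
        if len(roots) != 1 or roots[0] != 0:
            raise ParameterError("tree must have exactly one root at index 0")
        if np.any(self.parent_index[1:] >= np.arange(1, J)):
            raise ParameterError("parents must precede children (topological order)")
        # mirror symmetry of left/right pairs about the sagittal (y=0) plane
        idx = {n: i for i, n in enumerate(self.joint_names)}
        for name, i in idx.items():
            if name.startswith("left_"):
                j = idx.get("right_" + name[5:])
                if j is None:
                    raise ParameterError(f"unpaired left joint {name!r}")
                mirrored = self.rest_offset[i] * np.array([1.0, -1.0, 1.0])
                if not np.allclose(mirrored, self.rest_offset[j], atol=1e-12):
                    raise ParameterError(f"{name!r} offset is not mirror-symmetric")

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    def index(self, name: str) -> int:
        return self.joint_names.index(name)

    @property
    def coco17_indices(self) -> np.ndarray:
        """Tree indices of the 17 COCO keypoints, in COCO order."""
        return np.array([self.index(n) for n in COCO_KEYPOINT_NAMES])

    def children(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.parent_index == j)

    def rest_joints(self) -> np.ndarray:
        """Joint positions in the rest pose (zero rotations, zero betas)."""
        pos = np.zeros((self.n_joints, 3))
        for j in range(1, self.n_joints):
            pos[j] = pos[self.parent_index[j]] + self.rest_offset[j]
        return pos


@dataclass(frozen=True)
class BodyShape:
    """Ten dimensionless shape coefficients, each in [-1, 1]."""

    betas: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, dtype=float)
        if b.shape != (10,):
            raise ParameterError("betas must have length exactly 10")
        if np.any(np.abs(b) > 1.0):
            raise ParameterError("every beta must lie in [-1, 1]")
        object.__setattr__(self, "betas", b)

    @classmethod
    def zeros(cls) -> "BodyShape":
        return cls(np.zeros(10))

    @property
    def stature_scale(self) -> float:
        """Uniform bone-length scale; 1.0 at betas = 0."""
        return 1.0 + _STATURE_GAIN * float(self.betas[0])

    @property
    def girth_scale(self) -> float:
        """Limb/torso radius scale; monotone increasing in every beta."""
        return 1.0 + _GIRTH_GAIN * float(np.mean(self.betas))


@dataclass(frozen=True)
class PoseAA:
    """Root translation plus per-joint axis-angle rotations in tree order."""

    root_translation: np.ndarray
    joint_rotation: np.ndarray  # (J, 3); norm = angle in [0, pi]

    def __post_init__(self) -> None:
        t = np.asarray(self.root_translation, dtype=float)
        r = np.asarray(self.joint_rotation, dtype=float)
        if t.shape != (3,):
            raise ParameterError("root_translation must be a 3-vector")
        if r.ndim != 2 or r.shape[1] != 3:
            raise ParameterError("joint_rotation must be (J, 3)")
        norms = np.linalg.norm(r, axis=1)
        if np.any(norms > np.pi + 1e-9):
            raise ParameterError("axis-angle norms must lie in [0, pi]")
        object.__setattr__(self, "root_translation", t)
        object.__setattr__(self, "joint_rotation", r)

    @classmethod
    def rest(cls, tree: KinematicTree) -> "PoseAA":
        return cls(np.zeros(3), np.zeros((tree.n_joints, 3)))


@dataclass
class HumanMesh:
    """Triangle mesh with per-face body-part labels and the posed joints."""

    vertices: np.ndarray  # (V, 3) metres
    faces: np.ndarray  # (F, 3) int
    joints3d: np.ndarray  # (J, 3) metres
    part_label: np.ndarray = field(default=None)  # (F,) str

    def __post_init__(self) -> None:
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ParameterError("face indices out of range")
        if self.part_label is None:
            self.part_label = np.full(len(self.faces), "body", dtype=object)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)


# ---------------------------------------------------------------------------
# asset loading


def _asset_path(name: str) -> Path:
    return Path(resources.files("bedsynth") / "assets" / name)


def load_kinematic_tree(path: str | Path | None = None) -> KinematicTree:
    """Load the versioned plain-text tree asset and validate its invariants."""
    path = _asset_path("kinematic_tree.txt") if path is None else Path(path)
    names: list[str] = []
    parents: list[int] = []
    offsets: list[list[float]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ParameterError(f"malformed tree line: {line!r}")
        name, parent, *xyz = parts
        names.append(name)
        parents.append(-1 if parent == "-" else names.index(parent))
        offsets.append([float(v) for v in xyz])
    return KinematicTree(tuple(names), np.array(parents), np.array(offsets))


def load_joint_limits(
    tree: KinematicTree, path: str | Path | None = None
) -> np.ndarray:
    """Per-joint symmetric component bounds (radians), aligned to tree order."""
    path = _asset_path("joint_limits.txt") if path is None else Path(path)
    limits = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, value = line.split()
        limits[name] = float(value)
    missing = [n for n in tree.joint_names if n not in limits]
    if missing:
        raise ParameterError(f"joint limits missing for {missing}")
    return np.array([limits[n] for n in tree.joint_names])


_DEFAULT_TREE: KinematicTree | None = None


def default_tree() -> KinematicTree:
    """The shipped tree asset (cached)."""
    global _DEFAULT_TREE
    if _DEFAULT_TREE is None:
        _DEFAULT_TREE = load_kinematic_tree()
    return _DEFAULT_TREE


# ---------------------------------------------------------------------------
# sampling and kinematics


def sample_body_shape(
    rng: np.random.Generator, sigma: float = 0.5, max_tries: int = 1000
) -> BodyShape:
    """Draw 10 betas from Normal(0, sigma), rejected until inside [-1, 1].

    Rejection (redraw) rather than clipping avoids probability spikes at the
    interval ends.
    """
    if not sigma > 0:
        raise ParameterError("sigma must be positive")
    betas = np.empty(10)
    for i in range(10):
        for _ in range(max_tries):
            v = rng.normal(0.0, sigma)
            if -1.0 <= v <= 1.0:
                betas[i] = v
                break
        else:  # pragma: no cover - unreachable for sane sigma
            betas[i] = np.clip(rng.normal(0.0, sigma), -1.0, 1.0)
    return BodyShape(betas)


def forward_kinematics(
    pose: PoseAA, shape: BodyShape, tree: KinematicTree
) -> np.ndarray:
    """Posed 3D joint positions, (J, 3) metres; deterministic."""
    if pose.joint_rotation.shape[0] != tree.n_joints:
        raise ParameterError("pose joint count does not match tree")
    s = shape.stature_scale
    J = tree.n_joints
    R_global = np.empty((J, 3, 3))
    pos = np.empty((J, 3))
    R_global[0] = Rotation.from_rotvec(pose.joint_rotation[0]).as_matrix()
    pos[0] = pose.root_translation
    for j in range(1, J):
        p = tree.parent_index[j]
        R_local = Rotation.from_rotvec(pose.joint_rotation[j]).as_matrix()
        R_global[j] = R_global[p] @ R_local
        pos[j] = pos[p] + R_global[p] @ (s * tree.rest_offset[j])
    return pos


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest rotation matrix mapping unit vector a onto unit vector b."""
    c = float(np.dot(a, b))
    axis = np.cross(a, b)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(np.pi * perp).as_matrix()
    angle = np.arctan2(n, c)
    return Rotation.from_rotvec(axis / n * angle).as_matrix()


def pose_from_joint_positions(
    joints: np.ndarray, tree: KinematicTree, shape: BodyShape | None = None
) -> PoseAA:
    """Recover a joint-wise axis-angle pose from Cartesian joint positions.

    Each joint's local rotation is the rotation carrying its rest-pose child
    offsets onto the observed child directions, expressed in the parent's
    accumulated frame; root translation is carried separately so the rotational
    representation is invariant to translating all joints. Twist about a bone
    axis is unobservable from positions alone and is set to zero for
    single-child joints (multi-child joints are solved by least-squares
    alignment, which does recover twist).
    """
    joints = np.asarray(joints, dtype=float)
    if joints.shape != (tree.n_joints, 3):
        raise ParameterError("joint count does not match tree")
    s = (shape or BodyShape.zeros()).stature_scale
    J = tree.n_joints
    rotvecs = np.zeros((J, 3))
    R_global = np.empty((J, 3, 3))

    order = list(range(J))  # topological by construction
    for j in order:
        p = tree.parent_index[j]
        R_parent = np.eye(3) if p < 0 else R_global[p]
        kids = tree.children(j)
        if len(kids) == 0:
            R_global[j] = R_parent
            continue
        rest_dirs, obs_dirs = [], []
        for c in kids:
            o = s * tree.rest_offset[c]
            if np.linalg.norm(o) < 1e-12:
                raise GeometryError(
                    f"zero-length rest bone at joint {tree.joint_names[c]!r}"
                )
            v = joints[c] - joints[j]
            if np.linalg.norm(v) < 1e-12:
                raise GeometryError(
                    f"zero-length observed bone at joint {tree.joint_names[c]!r}"
                )
            rest_dirs.append(o / np.linalg.norm(o))
            obs_dirs.append(R_parent.T @ (v / np.linalg.norm(v)))
        if len(kids) == 1:
            R_local = _minimal_rotation(rest_dirs[0], obs_dirs[0])
        else:
            rot, _ = Rotation.align_vectors(np.array(obs_dirs), np.array(rest_dirs))
            R_local = rot.as_matrix()
        R_global[j] = R_parent @ R_local
        rotvecs[j] = Rotation.from_matrix(R_local).as_rotvec()
    return PoseAA(joints[0].copy(), rotvecs)


# ---------------------------------------------------------------------------
# surface mesh

# bone radius (metres at girth_scale 1) and part label, keyed by child joint
_BONE_PARTS: dict[str, tuple[float, str]] = {
    "left_hip": (0.075, "torso"),
    "right_hip": (0.075, "torso"),
    "spine1": (0.105, "torso"),
    "spine2": (0.110, "torso"),
    "spine3": (0.105, "torso"),
    "neck": (0.050, "head"),
    "left_collar": (0.055, "torso"),
    "right_collar": (0.055, "torso"),
    "left_shoulder": (0.050, "left_upper_arm"),
    "right_shoulder": (0.050, "right_upper_arm"),
    "left_elbow": (0.045, "left_upper_arm"),
    "right_elbow": (0.045, "right_upper_arm"),
    "left_wrist": (0.035, "left_lower_arm"),
    "right_wrist": (0.035, "right_lower_arm"),
    "left_knee": (0.070, "left_upper_leg"),
    "right_knee": (0.070, "right_upper_leg"),
    "left_ankle": (0.055, "left_lower_leg"),
    "right_ankle": (0.055, "right_lower_leg"),
    "left_foot": (0.040, "left_foot"),
    "right_foot": (0.040, "right_foot"),
}

_HEAD_RADII = np.array([0.10, 0.085, 0.115])


def _ring_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal frame perpendicular to unit axis d."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(np.dot(d, ref))) > 0.999:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _capsule(
    p0: np.ndarray, p1: np.ndarray, radius: float, n_seg: int
) -> tuple[np.ndarray, np.ndarray]:
    """Closed capsule-like tube between two points (apex-capped cylinder)."""
    d = p1 - p0
    L = np.linalg.norm(d)
    if L < 1e-12:
        raise GeometryError("degenerate capsule axis")
    d = d / L
    u, v = _ring_frame(d)
    theta = 2.0 * np.pi * np.arange(n_seg) / n_seg
    circle = np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)
    ring0 = p0 + radius * circle
    ring1 = p1 + radius * circle
    apex0 = p0 - 0.8 * radius * d
    apex1 = p1 + 0.8 * radius * d
    verts = np.vstack([ring0, ring1, apex0[None, :], apex1[None, :]])
    faces = []
    a0, a1 = 2 * n_seg, 2 * n_seg + 1
    for k in range(n_seg):
        k2 = (k + 1) % n_seg
        faces.append([k, k2, n_seg + k])
        faces.append([k2, n_seg + k2, n_seg + k])
        faces.append([k2, k, a0])
        faces.append([n_seg + k, n_seg + k2, a1])
    return verts, np.array(faces)


def _ellipsoid(
    center: np.ndarray, radii: np.ndarray, n_seg: int, n_rings: int
) -> tuple[np.ndarray, np.ndarray]:
    phi = np.pi * np.arange(1, n_rings + 1) / (n_rings + 1)
    theta = 2.0 * np.pi * np.arange(n_seg) / n_seg
    verts = [center + radii * np.array([0.0, 0.0, 1.0])]
    for p in phi:
        for t in theta:
            verts.append(
                center
                + radii * np.array([np.cos(t) * np.sin(p), np.sin(t) * np.sin(p), np.cos(p)])
            )
    verts.append(center + radii * np.array([0.0, 0.0, -1.0]))
    verts = np.array(verts)
    faces = []
    bottom = len(verts) - 1

    def vid(ring: int, k: int) -> int:
        return 1 + ring * n_seg + (k % n_seg)

    for k in range(n_seg):
        faces.append([0, vid(0, k), vid(0, k + 1)])
        faces.append([bottom, vid(n_rings - 1, k + 1), vid(n_rings - 1, k)])
    for r in range(n_rings - 1):
        for k in range(n_seg):
            faces.append([vid(r, k), vid(r + 1, k), vid(r, k + 1)])
            faces.append([vid(r, k + 1), vid(r + 1, k), vid(r + 1, k + 1)])
    return verts, np.array(faces)


def build_surface_mesh(
    joints3d: np.ndarray,
    shape: BodyShape,
    tree: KinematicTree | None = None,
    n_seg: int = 8,
) -> HumanMesh:
    """Procedural body surface: one capsule per bone plus a head ellipsoid.

    Segment radii scale with the girth coefficient; vertex/face counts are a
    pure function of ``n_seg``. This is the built-in stand-in surface behind
    the statistical-body-model adapter seam.
    """
    tree = tree or default_tree()
    joints3d = np.asarray(joints3d, dtype=float)
    if joints3d.shape != (tree.n_joints, 3):
        raise ParameterError("joint count does not match tree")
    if n_seg < 3 or n_seg % 2:
        raise ParameterError("n_seg must be an even integer >= 4")
    g = shape.girth_scale
    all_v: list[np.ndarray] = []
    all_f: list[np.ndarray] = []
    labels: list[str] = []
    offset = 0
    for name, (radius, part) in _BONE_PARTS.items():
        j = tree.index(name)
        p = tree.parent_index[j]
        v, f = _capsule(joints3d[p], joints3d[j], radius * g, n_seg)
        all_v.append(v)
        all_f.append(f + offset)
        labels.extend([part] * len(f))
        offset += len(v)
    head = tree.index("head")
    v, f = _ellipsoid(joints3d[head], _HEAD_RADII * g, n_seg, max(3, n_seg // 2))
    all_v.append(v)
    all_f.append(f + offset)
    labels.extend(["head"] * len(f))
    return HumanMesh(
        np.vstack(all_v),
        np.vstack(all_f),
        joints3d.copy(),
        np.array(labels, dtype=object),
    )
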