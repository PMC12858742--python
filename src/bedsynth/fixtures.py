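"""Synthetic stand-ins for every external asset.

Nothing in the toolkit downloads anything: ward-like backgrounds with exact
bed boxes are drawn procedurally, lying-pose sequences come from a
joint-limited reflected random walk over the kinematic tree (a motion-capture
archive stand-in), and detection simulators produce boxes at controlled IoU
against ground truth for exercising the evaluation and statistics stack
end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cocoio import Detection
from .composite import BackgroundAsset
from .errors import ParameterError
from .evalkit import iou
from .humanoid import KinematicTree, PoseAA, default_tree, load_joint_limits

__all__ = [
    "PoseSequenceSpec",
    "generate_background",
    "generate_pose_sequence",
    "perturb_to_target_iou",
]


@dataclass(frozen=True)
class PoseSequenceSpec:
    """Random-walk pose sequence parameters."""

    n_frames: int = 1
    step_scale: float = 0.08  # radians per frame and component
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.step_scale < 0:
            raise ParameterError("step_scale must be >= 0")


# ---------------------------------------------------------------------------
# backgrounds


def generate_background(
    rng: np.random.Generator,
    size: tuple[int, int] = (640, 480),
    n_distractors: int = 3,
    min_bed_fraction: float = 0.08,
) -> BackgroundAsset:
    """Flat-shaded ward-like scene with an exactly known bed box.

    Wall and floor bands, a bed rectangle with a darker frame and a pillow
    blob near its head end, plus a few distractor rectangles (cabinets,
    monitors). Deterministic for a fixed generator state.
    """
    w, h = size
    if w <= 0 or h <= 0:
        raise ParameterError("size must be positive")
    img = np.zeros((h, w, 3), dtype=np.uint8)
    wall = rng.integers(170, 220, size=3)
    floor = rng.integers(90, 140, size=3)
    horizon = int(h * rng.uniform(0.35, 0.55))
    img[:horizon] = wall
    img[horizon:] = floor

    for _ in range(n_distractors):
        dw = int(rng.uniform(0.05, 0.18) * w)
        dh = int(rng.uniform(0.08, 0.30) * h)
        dx = int(rng.uniform(0, w - dw))
        dy = int(rng.uniform(0, h - dh))
        img[dy : dy + dh, dx : dx + dw] = rng.integers(40, 200, size=3)

    # bed rectangle resting on the floor band
    min_area = min_bed_fraction * w * h
    for _ in range(100):
        bw = int(rng.uniform(0.30, 0.60) * w)
        bh = int(rng.uniform(0.22, 0.45) * h)
        if bw * bh >= min_area:
            break
    bx = int(rng.uniform(0.02 * w, w - bw - 0.02 * w))
    by = int(rng.uniform(max(horizon - bh // 3, 0), h - bh - 1))
    frame = rng.integers(60, 110, size=3)
    sheet = rng.integers(200, 245, size=3)
    img[by : by + bh, bx : bx + bw] = frame
    inset = max(2, min(bw, bh) // 12)
    img[by + inset : by + bh - inset, bx + inset : bx + bw - inset] = sheet
    # pillow blob at the head end
    pw, ph = max(4, bw // 5), max(4, bh // 3)
    py = by + (bh - ph) // 2
    img[py : py + ph, bx + inset : bx + inset + pw] = np.clip(
        sheet.astype(int) + 8, 0, 255
    )
    identifier = f"ward-{rng.integers(1 << 31):08x}"
    return BackgroundAsset(img, [float(bx), float(by), float(bw), float(bh)], identifier)


# ---------------------------------------------------------------------------
# poses


def generate_pose_sequence(
    spec: PoseSequenceSpec,
    tree: KinematicTree | None = None,
    rng: np.random.Generator | None = None,
    limits: np.ndarray | None = None,
) -> list[PoseAA]:
    """Joint-limited reflected random walk starting from the supine rest pose.

    Every component of every joint's axis-angle vector performs an
    independent Gaussian random walk reflected into [-limit, +limit]; every
    returned frame satisfies the limits exactly.
    """
    tree = tree or default_tree()
    if limits is None:
        limits = load_joint_limits(tree)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lim = np.repeat(limits[:, None], 3, axis=1)
    state = np.zeros((tree.n_joints, 3))
    frames: list[PoseAA] = []
    for _ in range(spec.n_frames):
        state = state + rng.normal(0.0, spec.step_scale, state.shape) * (lim > 0)
        state = _reflect(state, lim)
        # keep the rotation norm representable as axis-angle
        norms = np.linalg.norm(state, axis=1, keepdims=True)
        over = norms > np.pi - 1e-6
        if over.any():
            state = np.where(over, state * (np.pi - 1e-6) / norms, state)
        frames.append(PoseAA(np.zeros(3), state.copy()))
    return frames


def _reflect(x: np.ndarray, lim: np.ndarray) -> np.ndarray:
    """Reflect values into [-lim, lim] (billiard reflection, exact at 0 limits)."""
    out = x.copy()
    pos = lim > 0
    period = 4.0 * lim[pos]
    y = np.mod(x[pos] + lim[pos], period)
    y = np.where(y > 2.0 * lim[pos], period - y, y)
    out[pos] = y - lim[pos]
    out[~pos] = 0.0
    return out


# ---------------------------------------------------------------------------
# controlled-error detections


def perturb_to_target_iou(
    gt_bbox: list[float],
    target_iou: float,
    rng: np.random.Generator,
    image_id: int = 0,
    tol: float = 0.01,
) -> Detection:
    """A shifted copy of the ground-truth box at a prescribed IoU.

    The box is translated along a random diagonal direction; the shift
    magnitude is solved by bisection (IoU is continuous and monotone
    decreasing in the shift), to within ``tol`` of the target. Confidence is
    sampled in [0.5, 1).
    """
    if not (0.0 < target_iou <= 1.0):
        raise ParameterError("target_iou must lie in (0, 1]")
    x, y, w, h = gt_bbox
    conf = float(rng.uniform(0.5, 1.0))
    if target_iou == 1.0:
        return Detection(image_id, [x, y, w, h], conf)
    ux, uy = (1.0, 1.0) if rng.random() < 0.5 else (1.0, -1.0)

    def shifted(t: float) -> list[float]:
        return [x + t * ux * w, y + t * uy * h, w, h]

    lo, hi = 0.0, 1.0  # t=1 shifts by a full box: IoU 0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if iou(gt_bbox, shifted(mid)) > target_iou:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    achieved = iou(gt_bbox, shifted(t))
    if abs(achieved - target_iou) > tol:
        raise ParameterError(
            f"bisection failed to reach IoU {target_iou} (got {achieved:.4f})"
        )
    return Detection(image_id, shifted(t), conf)
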