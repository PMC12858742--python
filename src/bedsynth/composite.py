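"""Embedding rendered human layers into backgrounds, annotation-exactly.

A rendered RGBA layer is scaled so the human's long axis is a sampled
fraction of the bed box's long axis, translated so its box overlaps the
(dilated) bed region, and alpha-composited.  Keypoints and boxes ride through
the very same similarity transform, so annotations stay exact; the applied
transform is stored in the provenance and is sufficient to regenerate or
invert the placement.

The rotation augmentation mimics adapting an upright-person dataset to
lying-down scenes: angles are drawn uniformly from [70, 110] or
[-110, -70] degrees (equal mass), the canvas is expanded to keep every source
pixel, and boxes are recomputed from the rotated corners.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .cocoio import AnnotationRecord
from .errors import FormatError, ParameterError, PlacementError
from .render import RenderedLayer

__all__ = [
    "BackgroundAsset",
    "CompositeImage",
    "place_and_composite",
    "sample_rotation_angle",
    "rotate_augment",
    "load_bed_sidecar",
    "save_background",
]


@dataclass
class BackgroundAsset:
    image: np.ndarray  # (H, W, 3) uint8
    bed_bbox: list[float]  # [x, y, w, h] pixels
    identifier: str

    def __post_init__(self) -> None:
        h, w = self.image.shape[:2]
        x, y, bw, bh = self.bed_bbox
        if bw <= 0 or bh <= 0 or x < 0 or y < 0 or x + bw > w or y + bh > h:
            raise FormatError(
                f"background {self.identifier!r}: bed_bbox {self.bed_bbox} "
                f"outside {w}x{h} image"
            )


@dataclass
class CompositeImage:
    image: np.ndarray  # (H, W, 3) uint8
    annotations: list[AnnotationRecord]
    provenance: dict


def _scale_nearest(rgba: np.ndarray, s: float) -> np.ndarray:
    """Nearest-neighbour uniform scale with the exact map x_out = s * x_in."""
    h, w = rgba.shape[:2]
    out_w, out_h = max(1, int(np.ceil(w * s))), max(1, int(np.ceil(h * s)))
    xs = np.clip(((np.arange(out_w) + 0.5) / s - 0.5).round().astype(int), 0, w - 1)
    ys = np.clip(((np.arange(out_h) + 0.5) / s - 0.5).round().astype(int), 0, h - 1)
    return rgba[ys[:, None], xs[None, :]]


def place_and_composite(
    layer: RenderedLayer,
    bg: BackgroundAsset,
    rng: np.random.Generator,
    scale_frac_range: tuple[float, float] = (0.5, 0.9),
    min_overlap: float = 0.3,
    bed_dilation: float = 0.2,
    max_tries: int = 200,
    transform: tuple[float, float, float] | None = None,
    image_id: int = 0,
    ann_id: int = 0,
    config_id: str | None = None,
    render_index: int = 0,
) -> CompositeImage:
    """Alpha-over the layer onto the background, anchored to the bed region.

    The similarity (scale s, integer translation tx, ty) is sampled so that
    the placed human box's overlap fraction with the bed box dilated by
    ``bed_dilation`` is at least ``min_overlap``; pass ``transform`` to force
    a specific placement. Out-of-frame keypoints get visibility 0.
    """
    if layer.bbox is None:
        raise ParameterError("cannot place an empty (fully transparent) layer")
    bx, by, bw, bh = layer.bbox
    bed_x, bed_y, bed_w, bed_h = bg.bed_bbox
    H, W = bg.image.shape[:2]
    dil_x = bed_x - bed_dilation * bed_w / 2
    dil_y = bed_y - bed_dilation * bed_h / 2
    dil_w = bed_w * (1 + bed_dilation)
    dil_h = bed_h * (1 + bed_dilation)

    if transform is not None:
        s, tx, ty = transform
    else:
        s = tx = ty = None
        for _ in range(max_tries):
            frac = rng.uniform(*scale_frac_range)
            s_try = frac * max(bed_w, bed_h) / max(bw, bh)
            cx = rng.uniform(dil_x, dil_x + dil_w)
            cy = rng.uniform(dil_y, dil_y + dil_h)
            tx_try = round(cx - s_try * (bx + bw / 2))
            ty_try = round(cy - s_try * (by + bh / 2))
            pb = [s_try * bx + tx_try, s_try * by + ty_try, s_try * bw, s_try * bh]
            ix = max(0.0, min(pb[0] + pb[2], dil_x + dil_w) - max(pb[0], dil_x))
            iy = max(0.0, min(pb[1] + pb[3], dil_y + dil_h) - max(pb[1], dil_y))
            if pb[2] * pb[3] > 0 and ix * iy / (pb[2] * pb[3]) >= min_overlap:
                s, tx, ty = s_try, float(tx_try), float(ty_try)
                break
        if s is None:
            raise PlacementError(
                f"no feasible placement in {max_tries} tries "
                f"(bed={bg.bed_bbox}, layer bbox={layer.bbox}, "
                f"min_overlap={min_overlap})"
            )

    sprite = layer.rgba if s == 1.0 else _scale_nearest(layer.rgba, s)
    sh, sw = sprite.shape[:2]
    out = bg.image.astype(np.float64).copy()
    x0, y0 = int(tx), int(ty)
    sx0, sy0 = max(0, -x0), max(0, -y0)
    dx0, dy0 = max(0, x0), max(0, y0)
    sx1 = min(sw, W - x0)
    sy1 = min(sh, H - y0)
    if sx1 > sx0 and sy1 > sy0:
        fg = sprite[sy0:sy1, sx0:sx1].astype(np.float64)
        a = fg[..., 3:4] / 255.0
        region = out[dy0 : dy0 + (sy1 - sy0), dx0 : dx0 + (sx1 - sx0)]
        out[dy0 : dy0 + (sy1 - sy0), dx0 : dx0 + (sx1 - sx0)] = (
            fg[..., :3] * a + region * (1.0 - a)
        )
    image = np.clip(np.round(out), 0, 255).astype(np.uint8)

    kps = layer.keypoints2d.copy()
    kps[:, 0] = s * kps[:, 0] + tx
    kps[:, 1] = s * kps[:, 1] + ty
    oob = (
        (kps[:, 0] < 0) | (kps[:, 0] >= W) | (kps[:, 1] < 0) | (kps[:, 1] >= H)
    )
    kps[oob, 2] = 0
    nbx, nby = s * bx + tx, s * by + ty
    nbw, nbh = s * bw, s * bh
    cx0, cy0 = max(0.0, nbx), max(0.0, nby)
    cx1, cy1 = min(float(W), nbx + nbw), min(float(H), nby + nbh)
    ann = AnnotationRecord(
        id=ann_id,
        image_id=image_id,
        bbox=[cx0, cy0, max(0.0, cx1 - cx0), max(0.0, cy1 - cy0)],
        keypoints=kps,
        joints3d=layer.joints3d_cam,
    )
    return CompositeImage(
        image=image,
        annotations=[ann],
        provenance={
            "config_id": config_id,
            "render_index": render_index,
            "background": bg.identifier,
            "transform": {"scale": float(s), "tx": float(tx), "ty": float(ty)},
        },
    )


def sample_rotation_angle(
    rng: np.random.Generator,
    intervals: tuple[tuple[float, float], tuple[float, float]] = (
        (70.0, 110.0),
        (-110.0, -70.0),
    ),
) -> float:
    """Uniform draw from the two-interval union, equal mass per interval."""
    lo, hi = intervals[int(rng.random() < 0.5)]
    return float(rng.uniform(lo, hi))


def rotate_augment(
    image: np.ndarray,
    annotations: list[AnnotationRecord],
    rng: np.random.Generator,
    angle_deg: float | None = None,
    intervals: tuple[tuple[float, float], tuple[float, float]] = (
        (70.0, 110.0),
        (-110.0, -70.0),
    ),
    bbox_from_keypoints: bool = False,
) -> tuple[np.ndarray, list[AnnotationRecord], float]:
    """Rotate image + annotations about the centre, expanding the canvas.

    The angle is drawn uniformly from one of the two intervals (equal mass)
    unless forced via ``angle_deg``. Pixels are resampled by exact
    nearest-neighbour inverse mapping (exact at multiples of 90 degrees);
    exposed canvas is black. Boxes become the tight box of the rotated
    source-box corners, or of the rotated labelled keypoints when
    ``bbox_from_keypoints`` is set.
    """
    if angle_deg is None:
        angle_deg = sample_rotation_angle(rng, intervals)
    h, w = image.shape[:2]
    th = np.deg2rad(angle_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    c = np.array([w / 2.0, h / 2.0])
    corners = np.array([[0, 0], [w, 0], [0, h], [w, h]], float)
    rc = (corners - c) @ R.T + c
    mins = rc.min(axis=0)
    maxs = rc.max(axis=0)
    out_w = int(np.ceil(maxs[0] - mins[0] - 1e-9))
    out_h = int(np.ceil(maxs[1] - mins[1] - 1e-9))
    offset = -mins

    def fwd(pts: np.ndarray) -> np.ndarray:
        return (pts - c) @ R.T + c + offset

    # inverse nearest-neighbour resampling
    xs = np.arange(out_w) + 0.5
    ys = np.arange(out_h) + 0.5
    X, Y = np.meshgrid(xs, ys)
    src = (np.stack([X, Y], axis=-1) - c - offset) @ R + c
    sx = np.floor(src[..., 0]).astype(int)
    sy = np.floor(src[..., 1]).astype(int)
    valid = (sx >= 0) & (sx < w) & (sy >= 0) & (sy < h)
    rotated = np.zeros((out_h, out_w) + image.shape[2:], dtype=image.dtype)
    rotated[valid] = image[sy[valid], sx[valid]]

    new_anns: list[AnnotationRecord] = []
    for ann in annotations:
        kps = None
        if ann.keypoints is not None:
            kps = ann.keypoints.copy()
            kps[:, :2] = fwd(kps[:, :2])
        if bbox_from_keypoints and kps is not None and (kps[:, 2] > 0).any():
            pts = kps[kps[:, 2] > 0, :2]
        else:
            x, y, bw, bh = ann.bbox
            pts = fwd(
                np.array([[x, y], [x + bw, y], [x, y + bh], [x + bw, y + bh]])
            )
        lo_ = pts.min(axis=0)
        hi_ = pts.max(axis=0)
        new_anns.append(
            AnnotationRecord(
                id=ann.id,
                image_id=ann.image_id,
                bbox=[lo_[0], lo_[1], hi_[0] - lo_[0], hi_[1] - lo_[1]],
                keypoints=kps,
                joints3d=ann.joints3d,
            )
        )
    return rotated, new_anns, float(angle_deg)


# ---------------------------------------------------------------------------
# background sidecar I/O


def save_background(
    asset: BackgroundAsset, image_path: str | Path, sidecar_path: str | Path
) -> None:
    """PNG plus a one-record JSON sidecar naming the bed box."""
    Image.fromarray(asset.image).save(image_path)
    Path(sidecar_path).write_text(
        json.dumps(
            {
                "id": asset.identifier,
                "image": Path(image_path).name,
                "bed_bbox": [float(v) for v in asset.bed_bbox],
            },
            sort_keys=True,
        )
        + "\n"
    )


def load_bed_sidecar(sidecar_path: str | Path) -> BackgroundAsset:
    """Load a background + validated bed box from its sidecar annotation."""
    sidecar_path = Path(sidecar_path)
    try:
        meta = json.loads(sidecar_path.read_text())
        bed = [float(v) for v in meta["bed_bbox"]]
        name = meta["image"]
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{sidecar_path}: malformed sidecar ({exc})") from exc
    image = np.asarray(Image.open(sidecar_path.parent / name).convert("RGB"))
    return BackgroundAsset(image, bed, str(meta.get("id", name)))
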