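"""COCO-style annotation / detection-result files and dataset splitting.

Files follow the standard COCO object-keypoint layout (``images`` /
``annotations`` / ``categories`` for ground truth; a bare list of scored
records for detector results).  Two namespaced extension keys keep the files
valid standard COCO while carrying extra ground truth: ``x_joints3d`` (3D
joints per annotation, metres, camera frame) and ``x_config_id`` (scene
configuration provenance per image, used by the leakage-guarded split).

Serialisation is canonical (sorted keys, fixed separators, records ordered by
id), so a fixed dataset always produces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, ParameterError
from .humanoid import COCO_KEYPOINT_NAMES

__all__ = [
    "ImageRecord",
    "AnnotationRecord",
    "Detection",
    "CocoDataset",
    "COCO_SKELETON",
    "write_coco",
    "read_coco",
    "write_detections",
    "read_detections",
    "split_dataset",
]

#: 1-based limb connectivity of the 17-point person skeleton.
COCO_SKELETON = [
    [16, 14], [14, 12], [17, 15], [15, 13], [12, 13], [6, 12], [7, 13],
    [6, 7], [6, 8], [7, 9], [8, 10], [9, 11], [2, 3], [1, 2], [1, 3],
    [2, 4], [3, 5], [4, 6], [5, 7],
]


@dataclass
class ImageRecord:
    id: int
    width: int
    height: int
    file_name: str
    config_id: str | None = None


@dataclass
class AnnotationRecord:
    """Ground truth for one person instance."""

    id: int
    image_id: int
    bbox: list[float]  # [x, y, w, h]
    keypoints: np.ndarray | None = None  # (17, 3) x, y, v
    joints3d: np.ndarray | None = None  # (J, 3) metres
    category_id: int = 1

    def __post_init__(self) -> None:
        if len(self.bbox) != 4 or self.bbox[2] < 0 or self.bbox[3] < 0:
            raise FormatError(f"annotation {self.id}: malformed bbox {self.bbox}")
        if self.keypoints is not None:
            self.keypoints = np.asarray(self.keypoints, float).reshape(17, 3)

    @property
    def area(self) -> float:
        return float(self.bbox[2] * self.bbox[3])

    @property
    def num_keypoints(self) -> int:
        if self.keypoints is None:
            return 0
        return int(np.count_nonzero(self.keypoints[:, 2] > 0))


@dataclass
class Detection:
    """One predicted box, optionally with predicted keypoints."""

    image_id: int
    bbox: list[float]
    confidence: float
    keypoints: np.ndarray | None = None  # (17, 2) or (17, 3) with scores
    category_id: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise FormatError(
                f"detection on image {self.image_id}: confidence "
                f"{self.confidence} outside [0, 1]"
            )


@dataclass
class CocoDataset:
    images: list[ImageRecord] = field(default_factory=list)
    annotations: list[AnnotationRecord] = field(default_factory=list)

    def validate(self) -> None:
        ids = [im.id for im in self.images]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate image ids")
        known = set(ids)
        for ann in self.annotations:
            if ann.image_id not in known:
                raise FormatError(
                    f"annotation {ann.id} references unknown image {ann.image_id}"
                )


# ---------------------------------------------------------------------------
# serialisation


def _round6(values) -> list[float]:
    return [round(float(v), 6) for v in values]


def _dataset_to_dict(ds: CocoDataset) -> dict:
    images = [
        {
            "id": im.id,
            "width": im.width,
            "height": im.height,
            "file_name": im.file_name,
            **({"x_config_id": im.config_id} if im.config_id is not None else {}),
        }
        for im in sorted(ds.images, key=lambda im: im.id)
    ]
    annotations = []
    for ann in sorted(ds.annotations, key=lambda a: a.id):
        rec = {
            "id": ann.id,
            "image_id": ann.image_id,
            "category_id": ann.category_id,
            "bbox": _round6(ann.bbox),
            "area": round(ann.area, 6),
            "iscrowd": 0,
        }
        if ann.keypoints is not None:
            rec["keypoints"] = _round6(ann.keypoints.ravel())
            rec["num_keypoints"] = ann.num_keypoints
        if ann.joints3d is not None:
            rec["x_joints3d"] = [_round6(j) for j in np.asarray(ann.joints3d)]
        annotations.append(rec)
    return {
        "images": images,
        "annotations": annotations,
        "categories": [
            {
                "id": 1,
                "name": "person",
                "supercategory": "person",
                "keypoints": list(COCO_KEYPOINT_NAMES),
                "skeleton": COCO_SKELETON,
            }
        ],
    }


def write_coco(ds: CocoDataset, path: str | Path) -> None:
    """Canonical COCO JSON; byte-stable for a fixed dataset."""
    ds.validate()
    Path(path).write_text(
        json.dumps(_dataset_to_dict(ds), sort_keys=True, separators=(",", ":"))
        + "\n"
    )


def read_coco(path: str | Path) -> CocoDataset:
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("images", "annotations"):
        if key not in raw:
            raise FormatError(f"{path}: missing required key {key!r}")
    images = [
        ImageRecord(
            id=int(im["id"]),
            width=int(im["width"]),
            height=int(im["height"]),
            file_name=str(im["file_name"]),
            config_id=im.get("x_config_id"),
        )
        for im in raw["images"]
    ]
    annotations = []
    for rec in raw["annotations"]:
        try:
            kps = rec.get("keypoints")
            annotations.append(
                AnnotationRecord(
                    id=int(rec["id"]),
                    image_id=int(rec["image_id"]),
                    bbox=[float(v) for v in rec["bbox"]],
                    keypoints=np.array(kps, float).reshape(17, 3) if kps else None,
                    joints3d=(
                        np.array(rec["x_joints3d"], float)
                        if "x_joints3d" in rec
                        else None
                    ),
                    category_id=int(rec.get("category_id", 1)),
                )
            )
        except (KeyError, ValueError) as exc:
            raise FormatError(
                f"{path}: malformed annotation record {rec.get('id')} ({exc})"
            ) from exc
    ds = CocoDataset(images, annotations)
    ds.validate()
    return ds


def write_detections(dets: list[Detection], path: str | Path) -> None:
    """COCO results dialect: a bare list of scored records."""
    out = []
    for d in dets:
        rec = {
            "image_id": d.image_id,
            "category_id": d.category_id,
            "bbox": _round6(d.bbox),
            "score": round(float(d.confidence), 6),
        }
        if d.keypoints is not None:
            rec["keypoints"] = _round6(np.asarray(d.keypoints).ravel())
        out.append(rec)
    Path(path).write_text(
        json.dumps(out, sort_keys=True, separators=(",", ":")) + "\n"
    )


def read_detections(path: str | Path) -> list[Detection]:
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, list):
        raise FormatError(f"{path}: results file must be a JSON list")
    dets = []
    for rec in raw:
        kps = rec.get("keypoints")
        dets.append(
            Detection(
                image_id=int(rec["image_id"]),
                bbox=[float(v) for v in rec["bbox"]],
                confidence=float(rec["score"]),
                keypoints=(
                    np.array(kps, float).reshape(17, -1) if kps else None
                ),
                category_id=int(rec.get("category_id", 1)),
            )
        )
    return dets


# ---------------------------------------------------------------------------
# splitting


def split_dataset(
    ds: CocoDataset,
    train_n: int = 10_000,
    val_n: int = 800,
    rng: np.random.Generator | None = None,
) -> tuple[CocoDataset, CocoDataset]:
    """Disjoint seeded-random train/validation partition of the images.

    All renders sharing a ``config_id`` land on the same side (leakage
    guard); images without a config_id form singleton groups. Raises when the
    requested sizes are unreachable at group granularity.
    """
    if train_n + val_n > len(ds.images):
        raise ParameterError(
            f"requested {train_n}+{val_n} images from only {len(ds.images)}"
        )
    rng = rng or np.random.default_rng()
    groups: dict[str, list[ImageRecord]] = {}
    for im in ds.images:
        key = im.config_id if im.config_id is not None else f"__solo_{im.id}"
        groups.setdefault(key, []).append(im)
    keys = sorted(groups)
    order = rng.permutation(len(keys))

    train_imgs: list[ImageRecord] = []
    val_imgs: list[ImageRecord] = []
    for k in (keys[i] for i in order):
        g = groups[k]
        if len(train_imgs) + len(g) <= train_n:
            train_imgs.extend(g)
        elif len(val_imgs) + len(g) <= val_n:
            val_imgs.extend(g)
    if len(train_imgs) != train_n or len(val_imgs) != val_n:
        raise ParameterError(
            "split sizes unreachable at configuration granularity "
            f"(got {len(train_imgs)}/{len(val_imgs)}, "
            f"wanted {train_n}/{val_n})"
        )

    def subset(images: list[ImageRecord]) -> CocoDataset:
        ids = {im.id for im in images}
        return CocoDataset(
            images=list(images),
            annotations=[a for a in ds.annotations if a.image_id in ids],
        )

    return subset(train_imgs), subset(val_imgs)
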