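from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bedsynth.cocoio import AnnotationRecord, CocoDataset, Detection, ImageRecord
from bedsynth.fixtures import PoseSequenceSpec, generate_pose_sequence
from bedsynth.humanoid import default_tree, load_joint_limits
from bedsynth.render import RenderedLayer

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tree():
    return default_tree()


@pytest.fixture(scope="session")
def joint_limits(tree):
    return load_joint_limits(tree)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_pose(tree, rng, n_steps: int = 6):
    """A plausible joint-limit-respecting pose from the random-walk generator."""
    return generate_pose_sequence(
        PoseSequenceSpec(n_frames=n_steps, step_scale=0.12), tree, rng
    )[-1]


def make_layer(width=64, height=48, box=(10, 8, 20, 30), n_kp_inside=17):
    """A minimal opaque-rectangle RenderedLayer for compositing tests."""
    rgba = np.zeros((height, width, 4), dtype=np.uint8)
    x, y, w, h = box
    rgba[y : y + h, x : x + w] = (180, 120, 90, 255)
    kps = np.zeros((17, 3))
    gx = np.linspace(x + 1, x + w - 1, 17)
    gy = np.linspace(y + 1, y + h - 1, 17)
    kps[:, 0], kps[:, 1] = gx, gy
    kps[:, 2] = 2
    kps[n_kp_inside:, 2] = 0
    return RenderedLayer(
        rgba=rgba,
        keypoints2d=kps,
        joints3d_cam=np.zeros((27, 3)),
        bbox=[float(x), float(y), float(w), float(h)],
    )


def toy_dataset(boxes_per_image: dict[int, list[list[float]]]) -> CocoDataset:
    """Ground-truth dataset with one annotation per listed box."""
    images = [
        ImageRecord(id=i, width=640, height=480, file_name=f"{i}.png")
        for i in boxes_per_image
    ]
    anns = []
    k = 0
    for i, boxes in boxes_per_image.items():
        for box in boxes:
            anns.append(AnnotationRecord(id=k, image_id=i, bbox=list(box)))
            k += 1
    return CocoDataset(images, anns)


def detections_from(boxes_per_image: dict[int, list[tuple[list[float], float]]]):
    return [
        Detection(image_id=i, bbox=list(box), confidence=conf)
        for i, items in boxes_per_image.items()
        for box, conf in items
    ]
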