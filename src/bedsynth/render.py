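"""Renderer-agnostic interface plus the built-in software rasterizer.

The contract of this module is geometric and annotation *exactness*, not
photorealism: a pinhole camera, z-buffered flat Lambertian shading under the
five directional lights, RGBA output with a fully transparent background, and
keypoint visibility resolved against the z-buffer.  Any higher-fidelity
backend that consumes a :class:`~bedsynth.scene.SceneConfig` and returns a
:class:`RenderedLayer` is a drop-in replacement.

Image conventions: origin top-left, x right, y down, 0-based pixel indices,
pixel centres at (x + 0.5, y + 0.5); bounding boxes are COCO-style
``[x, y, w, h]`` with half-open width/height.  Keypoint visibility follows
COCO: 0 = not labelled (outside the image / behind the camera), 1 = labelled
but occluded, 2 = visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ParameterError
from .humanoid import HumanMesh, default_tree
from .scene import AZIMUTH_REFERENCES, BlanketMesh, CameraSpec, LightSpec, SceneConfig

__all__ = [
    "RenderedLayer",
    "camera_pose",
    "world_to_camera_matrix",
    "project_points",
    "rasterize",
    "bbox_from_alpha",
]

_NEAR = 0.05  # metres; geometry closer than this to the camera plane is culled
_BLANKET_RGB = (228, 228, 235)
_HAIR_RGB = (45, 32, 24)
_EYEWEAR_RGB = (20, 20, 20)
#: depth slack (m) when testing whether a joint is on the visible body surface
_VIS_DEPTH_TOL = 0.18


@dataclass
class RenderedLayer:
    """One rendered human layer with exact ground truth."""

    rgba: np.ndarray  # (H, W, 4) uint8
    keypoints2d: np.ndarray  # (17, 3): x, y, visibility in {0, 1, 2}
    joints3d_cam: np.ndarray  # (J, 3) camera-frame metres
    bbox: list[float] | None  # [x, y, w, h] or None when nothing projects


# ---------------------------------------------------------------------------
# camera model


def camera_pose(camera: CameraSpec) -> tuple[np.ndarray, np.ndarray]:
    """(position, R) with R the world->camera rotation (rows right/down/fwd).

    The camera sits on a sphere of radius ``distance_m`` about the target at
    the spherical angles (azimuth about +z from the preset's zero-reference
    axis, elevation above the horizontal), looks at the target, and is then
    rolled about its optical axis by ``roll_deg``.
    """
    ref = np.asarray(AZIMUTH_REFERENCES[camera.azimuth_reference], float)
    ez = np.array([0.0, 0.0, 1.0])
    perp = np.cross(ez, ref)
    a = np.deg2rad(camera.azimuth_deg)
    e = np.deg2rad(camera.elevation_deg)
    direction = np.cos(e) * (np.cos(a) * ref + np.sin(a) * perp) + np.sin(e) * ez
    target = np.asarray(camera.target, float)
    pos = target + camera.distance_m * direction

    fwd = target - pos
    fwd = fwd / np.linalg.norm(fwd)
    up = ez if abs(float(np.dot(fwd, ez))) < 0.999 else np.array([1.0, 0.0, 0.0])
    right = np.cross(fwd, up)
    right = right / np.linalg.norm(right)
    down = np.cross(fwd, right)
    phi = np.deg2rad(camera.roll_deg)
    right_r = np.cos(phi) * right + np.sin(phi) * down
    down_r = -np.sin(phi) * right + np.cos(phi) * down
    R = np.vstack([right_r, down_r, fwd])
    return pos, R


def world_to_camera_matrix(camera: CameraSpec) -> np.ndarray:
    """The full 4x4 homogeneous world->camera transform."""
    pos, R = camera_pose(camera)
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = -R @ pos
    return M


def project_points(points3d: np.ndarray, camera: CameraSpec) -> np.ndarray:
    """Pinhole projection: (N, 3) world points -> (N, 3) of (x_px, y_px, depth).

    Depth is the camera-frame distance along the optical axis (may be <= 0 for
    points behind the camera; callers must cull).  The principal point is the
    image centre; raises for a point coincident with the camera centre.
    """
    pts = np.atleast_2d(np.asarray(points3d, float))
    pos, R = camera_pose(camera)
    cam = (pts - pos) @ R.T
    r = np.linalg.norm(pts - pos, axis=1)
    if np.any(r < 1e-12):
        raise GeometryError("point coincides with the camera centre")
    w, h = camera.image_size
    f = camera.focal
    z = cam[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        x = f * cam[:, 0] / z + w / 2.0
        y = f * cam[:, 1] / z + h / 2.0
    return np.column_stack([x, y, z])


# ---------------------------------------------------------------------------
# shading


def face_radiance(
    normal: np.ndarray, lights: tuple[LightSpec, ...], albedo_rgb: np.ndarray
) -> np.ndarray:
    """Pre-clamp linear radiance of a face: albedo * sum_l I_l |cos theta_l|.

    Two-sided Lambertian (absolute cosine) so that capsule interiors created
    with either winding shade identically; exactly linear in the intensities.
    """
    n = normal / np.linalg.norm(normal)
    s = sum(
        light.intensity * abs(float(np.dot(n, np.asarray(light.direction))))
        for light in lights
    )
    return albedo_rgb / 255.0 * s * 0.30


def _part_albedo(part: str, config: SceneConfig) -> np.ndarray:
    app = config.appearance
    if part == "blanket":
        return np.array(_BLANKET_RGB, float)
    if part == "hair":
        return np.array(_HAIR_RGB, float)
    if part == "eyewear":
        return np.array(_EYEWEAR_RGB, float)
    clothed_parts = {
        "torso",
        "left_upper_arm",
        "right_upper_arm",
        "left_upper_leg",
        "right_upper_leg",
        "left_lower_leg",
        "right_lower_leg",
    }
    if app.clothed and part in clothed_parts:
        return np.array(app.clothing_rgb, float)
    return np.array(app.skin_rgb, float)


def _head_accessory_labels(
    mesh: HumanMesh, config: SceneConfig
) -> np.ndarray:
    """Relabel head faces to hair / eyewear bands when those flags are set."""
    labels = mesh.part_label.copy()
    tree = default_tree()
    head = mesh.joints3d[tree.index("head")]
    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    is_head = labels == "head"
    if config.appearance.hair:
        crown = centroids[:, 2] > head[2] + 0.055
        labels[is_head & crown] = "hair"
    if config.appearance.eyewear:
        eye_z = head[2] + 0.085
        band = (np.abs(centroids[:, 2] - eye_z) < 0.02) & (
            centroids[:, 0] > head[0]
        )
        labels[is_head & band] = "eyewear"
    return labels


# ---------------------------------------------------------------------------
# rasterisation


def rasterize(
    config: SceneConfig,
    mesh: HumanMesh,
    blanket: BlanketMesh | None = None,
) -> RenderedLayer:
    """Z-buffer triangle rasterisation of one scene; fully deterministic.

    Alpha is 255 exactly where geometry projects. Keypoint visibility is 2
    when the joint's projection lands on body surface within a depth slack,
    1 when z-occluded (by the body itself or the blanket), 0 outside the
    image or behind the camera.
    """
    w, h = config.camera.image_size
    if w <= 0 or h <= 0:
        raise ParameterError("image must have positive area")
    verts = mesh.vertices
    faces = mesh.faces
    labels = _head_accessory_labels(mesh, config)
    owner = np.zeros(len(faces), dtype=np.uint8)  # 0 = body
    if blanket is not None and len(blanket.faces):
        faces = np.vstack([faces, blanket.faces + len(verts)])
        verts = np.vstack([verts, blanket.vertices])
        labels = np.concatenate(
            [labels, np.full(len(blanket.faces), "blanket", dtype=object)]
        )
        owner = np.concatenate(
            [owner, np.ones(len(blanket.faces), dtype=np.uint8)]
        )

    proj = project_points(verts, config.camera)
    zbuf = np.full((h, w), np.inf)
    who = np.zeros((h, w), dtype=np.uint8)
    rgb = np.zeros((h, w, 3), dtype=np.float64)
    alpha = np.zeros((h, w), dtype=bool)

    # world-frame face normals for shading
    tri_world = verts[faces]
    normals = np.cross(
        tri_world[:, 1] - tri_world[:, 0], tri_world[:, 2] - tri_world[:, 0]
    )

    for fidx in range(len(faces)):
        tri = proj[faces[fidx]]
        if np.any(tri[:, 2] <= _NEAR):
            continue
        colour = np.clip(
            face_radiance(
                normals[fidx], config.lights, _part_albedo(labels[fidx], config)
            ),
            0.0,
            1.0,
        )
        _draw_triangle(
            tri, colour, fidx, owner[fidx], zbuf, who, rgb, alpha, w, h
        )

    rgba = np.zeros((h, w, 4), dtype=np.uint8)
    rgba[..., :3] = np.round(rgb * 255.0).astype(np.uint8)
    rgba[..., 3] = np.where(alpha, 255, 0)

    pos, R = camera_pose(config.camera)
    joints_cam = (mesh.joints3d - pos) @ R.T
    kp_idx = default_tree().coco17_indices
    kp_proj = project_points(mesh.joints3d[kp_idx], config.camera)
    keypoints = np.zeros((17, 3))
    for i, (x, y, z) in enumerate(kp_proj):
        keypoints[i, :2] = (x, y)
        px, py = int(np.floor(x)), int(np.floor(y))
        if z <= _NEAR or not (0 <= px < w and 0 <= py < h):
            keypoints[i, 2] = 0
        elif (
            np.isfinite(zbuf[py, px])
            and who[py, px] == 0
            and z <= zbuf[py, px] + _VIS_DEPTH_TOL
        ):
            keypoints[i, 2] = 2
        else:
            keypoints[i, 2] = 1
    return RenderedLayer(rgba, keypoints, joints_cam, bbox_from_alpha(rgba))


def _draw_triangle(tri, colour, fidx, own, zbuf, who, rgb, alpha, w, h):
    (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = tri
    minx = max(int(np.floor(min(x0, x1, x2))), 0)
    maxx = min(int(np.ceil(max(x0, x1, x2))), w - 1)
    miny = max(int(np.floor(min(y0, y1, y2))), 0)
    maxy = min(int(np.ceil(max(y0, y1, y2))), h - 1)
    if minx > maxx or miny > maxy:
        return
    area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
    if area == 0.0:
        return
    xs = np.arange(minx, maxx + 1) + 0.5
    ys = np.arange(miny, maxy + 1) + 0.5
    X, Y = np.meshgrid(xs, ys)
    a = ((x1 - x0) * (Y - y0) - (X - x0) * (y1 - y0)) / area  # weight of v2
    b = ((X - x0) * (y2 - y0) - (x2 - x0) * (Y - y0)) / area  # weight of v1
    c = 1.0 - a - b  # weight of v0
    inside = (a >= 0) & (b >= 0) & (c >= 0)
    if not inside.any():
        return
    # perspective-correct depth via linear interpolation of 1/z
    invz = c / z0 + b / z1 + a / z2
    depth = 1.0 / invz
    sub_z = zbuf[miny : maxy + 1, minx : maxx + 1]
    upd = inside & (depth < sub_z)
    if not upd.any():
        return
    sub_z[upd] = depth[upd]
    who[miny : maxy + 1, minx : maxx + 1][upd] = own
    rgb[miny : maxy + 1, minx : maxx + 1][upd] = colour
    alpha[miny : maxy + 1, minx : maxx + 1][upd] = True


def bbox_from_alpha(rgba: np.ndarray) -> list[float] | None:
    """Tight [x, y, w, h] over alpha > 0 pixels; None when fully transparent."""
    mask = rgba[..., 3] > 0
    if not mask.any():
        return None
    ys, xs = np.nonzero(mask)
    x0, x1 = int(xs.min()), int(xs.max())
    y0, y1 = int(ys.min()), int(ys.max())
    return [float(x0), float(y0), float(x1 - x0 + 1), float(y1 - y0 + 1)]
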