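"""Per-scene sampling: appearance, blanket occlusion, camera, lights, plans.

A *scenario preset* bundles the camera sampling ranges that target one
deployment viewpoint.  The shipped presets mirror the three synthetic training
scenarios: ``B`` (oblique, azimuth -35..35 degrees about the bed's right
side), ``C`` (front-right, 15..35 degrees about the bed front) and ``D``
(directly in front of the bed).  Elevation is sampled in [-54, 18] degrees,
camera roll in [-115, -30] degrees and distance in [0.3, 0.6] scene units for
every preset; each configuration is rendered 4 times (2,700 configurations
-> 10,800 images) with lights and background redrawn per render.

Scene units: camera distance is expressed in the dimensionless units of the
ranges above and converted to metres by ``distance_scale`` (default 3.0, so
0.3-0.6 units -> 0.9-1.8 m, which keeps the body at roughly 40-90 % of frame
height at the default focal length).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, GeometryError, ParameterError
from .humanoid import (
    BodyShape,
    HumanMesh,
    KinematicTree,
    PoseAA,
    default_tree,
    load_joint_limits,
    sample_body_shape,
)

__all__ = [
    "Appearance",
    "BlanketParams",
    "BlanketMesh",
    "CameraSpec",
    "LightSpec",
    "ScenarioPreset",
    "SceneConfig",
    "DEFAULT_SKIN_PALETTE",
    "LIGHT_DIRECTIONS",
    "PRESETS",
    "sample_appearance",
    "smooth_heightfield",
    "generate_blanket",
    "sample_camera",
    "sample_lights",
    "build_generation_plan",
]

#: A small span of skin tones (RGB), dark to light.
DEFAULT_SKIN_PALETTE: tuple[tuple[int, int, int], ...] = (
    (84, 53, 36),
    (114, 74, 50),
    (141, 93, 61),
    (168, 117, 80),
    (198, 144, 105),
    (222, 171, 131),
    (236, 192, 156),
    (247, 215, 185),
)

#: Propagation direction (towards the mesh) of the five canonical lights.
#: Bed axis = +x (head end), bed front = the foot end (-x), left side = +y.
LIGHT_DIRECTIONS: dict[str, tuple[float, float, float]] = {
    "front": (1.0, 0.0, 0.0),
    "back": (-1.0, 0.0, 0.0),
    "left": (0.0, -1.0, 0.0),
    "right": (0.0, 1.0, 0.0),
    "above": (0.0, 0.0, -1.0),
}

#: Azimuth zero-reference axes in the horizontal plane.
AZIMUTH_REFERENCES: dict[str, tuple[float, float, float]] = {
    "bed_right": (0.0, -1.0, 0.0),
    "bed_front": (-1.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class Appearance:
    skin_rgb: tuple[int, int, int]
    clothed: bool
    clothing_rgb: tuple[int, int, int]
    hair: bool
    eyewear: bool


@dataclass(frozen=True)
class BlanketParams:
    """Heightfield-drape blanket parameters (metres / cells)."""

    coverage_fraction: float = 0.6
    offset: float = 0.03
    noise_amplitude: float = 0.01
    smoothing_iters: int = 2
    grid_resolution: float = 40.0  # cells per metre

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage_fraction <= 1.0):
            raise ParameterError("coverage_fraction must lie in (0, 1]")
        if min(self.offset, self.noise_amplitude, self.grid_resolution) < 0:
            raise ParameterError("blanket parameters must be non-negative")
        if self.smoothing_iters < 0:
            raise ParameterError("smoothing_iters must be >= 0")


@dataclass
class BlanketMesh:
    """Triangulated drape heightfield."""

    vertices: np.ndarray  # (V, 3)
    faces: np.ndarray  # (F, 3)


@dataclass(frozen=True)
class CameraSpec:
    distance: float  # scene units
    azimuth_deg: float
    elevation_deg: float
    roll_deg: float
    target: tuple[float, float, float] = (0.0, 0.0, 0.1)
    image_size: tuple[int, int] = (640, 480)  # (width, height)
    focal_px: float | None = None  # default 0.45 * height
    azimuth_reference: str = "bed_right"
    distance_scale: float = 3.0  # scene units -> metres

    def __post_init__(self) -> None:
        if self.distance <= 0 or self.distance_scale <= 0:
            raise ParameterError("camera distance must be positive")
        if min(self.image_size) <= 0:
            raise ParameterError("image size must be positive")

    @property
    def focal(self) -> float:
        return self.focal_px if self.focal_px is not None else 0.45 * self.image_size[1]

    @property
    def distance_m(self) -> float:
        return self.distance * self.distance_scale


@dataclass(frozen=True)
class LightSpec:
    direction_label: str
    direction: tuple[float, float, float]  # unit, towards the mesh
    intensity: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        if abs(float(np.linalg.norm(d)) - 1.0) > 1e-9:
            raise ParameterError("light direction must be a unit vector")


@dataclass(frozen=True)
class ScenarioPreset:
    """Named bundle of per-scenario sampling ranges."""

    name: str
    azimuth_range_deg: tuple[float, float]
    azimuth_zero_reference: str = "bed_right"
    elevation_range_deg: tuple[float, float] = (-54.0, 18.0)
    roll_range_deg: tuple[float, float] = (-115.0, -30.0)
    distance_range: tuple[float, float] = (0.3, 0.6)
    renders_per_config: int = 4
    n_configs: int = 2700
    intensity_range: tuple[float, float] = (0.3, 3.0)
    blanket_probability: float = 0.7
    flip_elevation: bool = False
    image_size: tuple[int, int] = (640, 480)
    distance_scale: float = 3.0

    def __post_init__(self) -> None:
        for lo, hi in (
            self.azimuth_range_deg,
            self.elevation_range_deg,
            self.roll_range_deg,
            self.distance_range,
            self.intensity_range,
        ):
            if lo > hi:
                raise ConfigurationError(f"empty interval ({lo}, {hi}) in preset")
        if self.renders_per_config < 1 or self.n_configs < 1:
            raise ConfigurationError("renders_per_config and n_configs must be >= 1")
        if self.azimuth_zero_reference not in AZIMUTH_REFERENCES:
            raise ConfigurationError(
                f"unknown azimuth reference {self.azimuth_zero_reference!r}"
            )


#: Shipped presets with the scenario-targeted azimuth ranges.
PRESETS: dict[str, ScenarioPreset] = {
    "B": ScenarioPreset("B", (-35.0, 35.0), "bed_right"),
    "C": ScenarioPreset("C", (15.0, 35.0), "bed_front"),
    "D": ScenarioPreset("D", (0.0, 0.0), "bed_front"),
}


@dataclass(frozen=True)
class SceneConfig:
    """One renderable scene, fully specified and traceable."""

    config_id: str
    shape: BodyShape
    pose: PoseAA
    appearance: Appearance
    blanket: BlanketParams | None
    camera: CameraSpec
    lights: tuple[LightSpec, ...]
    background_ref: str | None = None
    render_index: int = 0

    def __post_init__(self) -> None:
        if len(self.lights) != 5:
            raise ParameterError("a scene carries exactly 5 lights")


# ---------------------------------------------------------------------------
# sampling operations


def sample_appearance(
    rng: np.random.Generator,
    palette: Sequence[tuple[int, int, int]] = DEFAULT_SKIN_PALETTE,
    p_clothed: float = 0.5,
    p_hair: float = 0.5,
    p_eyewear: float = 0.5,
) -> Appearance:
    """Uniform skin-palette draw plus independent clothing/hair/eyewear flips."""
    if len(palette) == 0:
        raise ConfigurationError("skin palette must be non-empty")
    skin = tuple(int(c) for c in palette[int(rng.integers(len(palette)))])
    clothed = bool(rng.random() < p_clothed)
    clothing = tuple(int(v) for v in rng.integers(0, 256, size=3))
    return Appearance(
        skin_rgb=skin,
        clothed=clothed,
        clothing_rgb=clothing,
        hair=bool(rng.random() < p_hair),
        eyewear=bool(rng.random() < p_eyewear),
    )


def generate_blanket(
    mesh: HumanMesh,
    params: BlanketParams,
    rng: np.random.Generator,
    side_margin: float = 0.06,
) -> BlanketMesh:
    """Drape a planar grid over part of the body as a heightfield.

    The covered span starts at an anchor sampled uniformly along the body's
    long (+x) axis and extends ``coverage_fraction`` of the body length. Grid
    heights take the maximum body-surface height under each cell plus
    ``offset``, then i.i.d. Gaussian noise, then ``smoothing_iters`` rounds of
    zero-flux Laplacian diffusion (step 0.2, variance-non-increasing).
    """
    if params.grid_resolution <= 0:
        raise ParameterError("grid_resolution must be positive")
    verts = mesh.vertices
    xmin, xmax = float(verts[:, 0].min()), float(verts[:, 0].max())
    length = xmax - xmin
    if length <= 0:
        raise GeometryError("body mesh has zero length")
    anchor = float(rng.uniform(0.0, 1.0 - params.coverage_fraction))
    x0 = xmin + anchor * length
    x1 = x0 + params.coverage_fraction * length
    inside = (verts[:, 0] >= x0) & (verts[:, 0] <= x1)
    if not np.any(inside):
        raise GeometryError("blanket coverage region has no body underneath")
    sub = verts[inside]
    y0 = float(sub[:, 1].min()) - side_margin
    y1 = float(sub[:, 1].max()) + side_margin

    h = 1.0 / params.grid_resolution
    nx = max(2, int(np.ceil((x1 - x0) / h)) + 1)
    ny = max(2, int(np.ceil((y1 - y0) / h)) + 1)
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(y0, y1, ny)

    drape = np.zeros((nx, ny))
    ix = np.clip(((sub[:, 0] - x0) / (x1 - x0) * (nx - 1)).round().astype(int), 0, nx - 1)
    iy = np.clip(((sub[:, 1] - y0) / (y1 - y0) * (ny - 1)).round().astype(int), 0, ny - 1)
    np.maximum.at(drape, (ix, iy), sub[:, 2])
    heights = drape + params.offset
    if params.noise_amplitude > 0:
        heights = heights + rng.normal(0.0, params.noise_amplitude, heights.shape)
    for _ in range(params.smoothing_iters):
        heights = smooth_heightfield(heights, 0.2)
    # cloth cannot pass through the body: clamp back to the draped surface
    heights = np.maximum(heights, drape)

    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    vertices = np.column_stack([gx.ravel(), gy.ravel(), heights.ravel()])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = a + ny
            faces.append([a, b, a + 1])
            faces.append([a + 1, b, b + 1])
    return BlanketMesh(vertices, np.array(faces))


def smooth_heightfield(h: np.ndarray, lam: float = 0.2) -> np.ndarray:
    """One step of h <- h + lam * graph-Laplacian flow (zero-flux boundary).

    The update matrix is symmetric with unit row sums and non-negative entries
    for lam <= 0.25, hence doubly stochastic: grid-height variance never
    increases and the mean is conserved exactly.
    """
    flux = np.zeros_like(h)
    flux[1:, :] += h[:-1, :] - h[1:, :]
    flux[:-1, :] += h[1:, :] - h[:-1, :]
    flux[:, 1:] += h[:, :-1] - h[:, 1:]
    flux[:, :-1] += h[:, 1:] - h[:, :-1]
    return h + lam * flux


def sample_camera(preset: ScenarioPreset, rng: np.random.Generator) -> CameraSpec:
    """Independent uniform draws of distance/azimuth/elevation/roll."""
    lo, hi = preset.elevation_range_deg
    elevation = float(rng.uniform(lo, hi))
    if preset.flip_elevation:
        elevation = -elevation
    return CameraSpec(
        distance=float(rng.uniform(*preset.distance_range)),
        azimuth_deg=float(rng.uniform(*preset.azimuth_range_deg)),
        elevation_deg=elevation,
        roll_deg=float(rng.uniform(*preset.roll_range_deg)),
        image_size=preset.image_size,
        azimuth_reference=preset.azimuth_zero_reference,
        distance_scale=preset.distance_scale,
    )


def sample_lights(
    rng: np.random.Generator, intensity_range: tuple[float, float] = (0.3, 3.0)
) -> tuple[LightSpec, ...]:
    """The five canonical directional lights with i.i.d. uniform intensities."""
    lo, hi = intensity_range
    if lo > hi:
        raise ConfigurationError(f"empty intensity interval ({lo}, {hi})")
    return tuple(
        LightSpec(label, direction, float(rng.uniform(lo, hi)))
        for label, direction in LIGHT_DIRECTIONS.items()
    )


def _default_pose_sampler(
    tree: KinematicTree, limits: np.ndarray
) -> Callable[[np.random.Generator], PoseAA]:
    """Single-frame joint-limited pose draw (lying poses around rest)."""

    def draw(rng: np.random.Generator) -> PoseAA:
        rot = rng.uniform(-0.6, 0.6, size=(tree.n_joints, 3)) * limits[:, None]
        return PoseAA(np.zeros(3), rot)

    return draw


def build_generation_plan(
    preset: ScenarioPreset,
    rng: np.random.Generator,
    n_backgrounds: int | None = None,
    pose_sampler: Callable[[np.random.Generator], PoseAA] | None = None,
    palette: Sequence[tuple[int, int, int]] = DEFAULT_SKIN_PALETTE,
) -> list[SceneConfig]:
    """Sample ``n_configs`` base scenes, duplicated ``renders_per_config`` times.

    Shape, pose, appearance, blanket and camera are drawn once per
    configuration; lights and background reference are redrawn per render.
    Output length is ``n_configs * renders_per_config`` and every config_id /
    render_index pair is unique.
    """
    tree = default_tree()
    if pose_sampler is None:
        pose_sampler = _default_pose_sampler(tree, load_joint_limits(tree))
    plan: list[SceneConfig] = []
    for i in range(preset.n_configs):
        base = SceneConfig(
            config_id=f"{preset.name}-{i:05d}",
            shape=sample_body_shape(rng),
            pose=pose_sampler(rng),
            appearance=sample_appearance(rng, palette),
            blanket=(
                BlanketParams(coverage_fraction=float(rng.uniform(0.3, 0.9)))
                if rng.random() < preset.blanket_probability
                else None
            ),
            camera=sample_camera(preset, rng),
            lights=sample_lights(rng, preset.intensity_range),
            render_index=0,
        )
        for r in range(preset.renders_per_config):
            bg = (
                f"bg-{int(rng.integers(n_backgrounds)):04d}"
                if n_backgrounds
                else None
            )
            plan.append(
                replace(
                    base,
                    render_index=r,
                    lights=sample_lights(rng, preset.intensity_range),
                    background_ref=bg,
                )
            )
    return plan
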