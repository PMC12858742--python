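"""Scene sampling: appearance, blanket drape, camera/lights, generation plans."""

import dataclasses
import json

import numpy as np
import pytest
from scipy import stats as sps

from bedsynth.errors import ConfigurationError, GeometryError
from bedsynth.humanoid import BodyShape, build_surface_mesh, default_tree
from bedsynth.scene import (
    PRESETS,
    BlanketParams,
    ScenarioPreset,
    build_generation_plan,
    generate_blanket,
    sample_appearance,
    sample_camera,
    sample_lights,
    smooth_heightfield,
)


class TestAppearance:
    def test_single_entry_palette_is_deterministic(self, rng):
        for _ in range(20):
            app = sample_appearance(rng, palette=[(10, 20, 30)])
            assert app.skin_rgb == (10, 20, 30)

    def test_skin_always_from_palette(self, rng):
        palette = [(1, 2, 3), (4, 5, 6), (7, 8, 9)]
        assert all(
            sample_appearance(rng, palette).skin_rgb in palette for _ in range(500)
        )

    def test_palette_draw_frequencies_uniform(self):
        rng = np.random.default_rng(5)
        palette = [(i, i, i) for i in range(8)]
        n = 10_000
        counts = np.zeros(8)
        for _ in range(n):
            counts[sample_appearance(rng, palette).skin_rgb[0]] += 1
        p = 1 / 8
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 3.5 * sigma)

    def test_empty_palette_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            sample_appearance(rng, palette=[])


@pytest.fixture(scope="module")
def rest_mesh():
    tree = default_tree()
    return build_surface_mesh(tree.rest_joints(), BodyShape.zeros(), tree)


class TestBlanket:
    def test_degenerate_params_sit_exactly_offset_above_drape(self, rest_mesh):
        params = BlanketParams(
            coverage_fraction=1.0, offset=0.05, noise_amplitude=0.0, smoothing_iters=0
        )
        blanket = generate_blanket(rest_mesh, params, np.random.default_rng(0))
        z = blanket.vertices[:, 2]
        body_top = rest_mesh.vertices[:, 2].max()
        assert np.isclose(z.max(), body_top + 0.05, atol=1e-9)
        assert np.isclose(z.min(), 0.05, atol=1e-9)  # bed-level cells

    def test_no_penetration_below_body_surface(self, rest_mesh):
        params = BlanketParams()  # defaults: noise + smoothing + clamp
        blanket = generate_blanket(rest_mesh, params, np.random.default_rng(1))
        # oracle: per grid cell, the blanket must stay above the tallest body
        # vertex binned to that cell; cells are half-open around grid nodes
        xs = np.unique(blanket.vertices[:, 0])
        ys = np.unique(blanket.vertices[:, 1])
        dx, dy = xs[1] - xs[0], ys[1] - ys[0]
        bv = rest_mesh.vertices
        bv = bv[(bv[:, 0] >= xs[0]) & (bv[:, 0] <= xs[-1])]  # covered span only
        for v in blanket.vertices[::7]:
            near = bv[
                (np.abs(bv[:, 0] - v[0]) < dx / 2 * 0.999)
                & (np.abs(bv[:, 1] - v[1]) < dy / 2 * 0.999)
            ]
            if len(near):
                assert v[2] >= near[:, 2].max() - 1e-9

    def test_covered_fraction_tracks_parameter(self, rest_mesh):
        rng = np.random.default_rng(2)
        length = np.ptp(rest_mesh.vertices[:, 0])
        for _ in range(25):
            frac = rng.uniform(0.3, 0.9)
            blanket = generate_blanket(
                rest_mesh, BlanketParams(coverage_fraction=frac), rng
            )
            span = np.ptp(blanket.vertices[:, 0])
            assert span / length == pytest.approx(frac, abs=0.05)

    def test_smoothing_variance_non_increasing(self):
        rng = np.random.default_rng(3)
        h = rng.normal(0, 1, size=(30, 20))
        for _ in range(10):
            h2 = smooth_heightfield(h, 0.2)
            assert h2.var() <= h.var() + 1e-12
            assert np.isclose(h2.mean(), h.mean(), atol=1e-12)
            h = h2

    def test_empty_region_error(self, rest_mesh):
        # shift the mesh far from its own bounding range is impossible by
        # construction, so force an empty footprint with a tiny coverage of a
        # mesh whose x-span region holds no vertices between anchor bounds
        mesh = dataclasses.replace(rest_mesh)
        mesh.vertices = rest_mesh.vertices.copy()
        # make a gap: remove mid-body vertices is not possible on ndarray view;
        # instead check the validation path via zero-length mesh
        mesh.vertices[:, 0] = 0.0
        with pytest.raises(GeometryError):
            generate_blanket(mesh, BlanketParams(), np.random.default_rng(0))


class TestCameraAndLights:
    def test_preset_b_ranges_respected(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            cam = sample_camera(PRESETS["B"], rng)
            assert -35 <= cam.azimuth_deg <= 35
            assert -54 <= cam.elevation_deg <= 18
            assert -115 <= cam.roll_deg <= -30
            assert 0.3 <= cam.distance <= 0.6

    def test_collapsed_preset_is_deterministic(self):
        preset = ScenarioPreset(
            "pt",
            (10.0, 10.0),
            elevation_range_deg=(-20.0, -20.0),
            roll_range_deg=(-90.0, -90.0),
            distance_range=(0.5, 0.5),
        )
        rng = np.random.default_rng(0)
        cams = {sample_camera(preset, rng) for _ in range(10)}
        assert len(cams) == 1

    def test_camera_draws_uniform_by_ks(self):
        rng = np.random.default_rng(21)
        n = 2_000
        draws = np.array(
            [
                (c.distance, c.azimuth_deg, c.elevation_deg, c.roll_deg)
                for c in (sample_camera(PRESETS["B"], rng) for _ in range(n))
            ]
        )
        ranges = [(0.3, 0.6), (-35, 35), (-54, 18), (-115, -30)]
        for col, (lo, hi) in enumerate(ranges):
            p = sps.kstest(draws[:, col], "uniform", args=(lo, hi - lo)).pvalue
            assert p > 0.01

    def test_five_canonical_lights(self, rng):
        lights = sample_lights(rng)
        assert len(lights) == 5
        assert {l.direction_label for l in lights} == {
            "front", "back", "left", "right", "above",
        }
        assert all(0.3 <= l.intensity <= 3.0 for l in lights)

    def test_collapsed_intensity_interval(self, rng):
        assert all(l.intensity == 1.0 for l in sample_lights(rng, (1.0, 1.0)))

    def test_intensity_mean_matches_uniform(self):
        rng = np.random.default_rng(8)
        vals = [l.intensity for _ in range(2_000) for l in sample_lights(rng)]
        assert np.mean(vals) == pytest.approx((0.3 + 3.0) / 2, abs=0.02)

    def test_dataset_d_is_degenerate_frontal(self):
        rng = np.random.default_rng(1)
        cams = [sample_camera(PRESETS["D"], rng) for _ in range(10)]
        assert all(c.azimuth_deg == 0.0 for c in cams)
        assert all(c.azimuth_reference == "bed_front" for c in cams)


def _plan_fingerprint(plan):
    def enc(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return json.dumps([enc(c) for c in plan], sort_keys=True)


class TestGenerationPlan:
    def test_default_scenario_counts(self):
        preset = dataclasses.replace(PRESETS["B"], n_configs=30, renders_per_config=4)
        plan = build_generation_plan(preset, np.random.default_rng(0))
        assert len(plan) == 120

    def test_single_config_single_render(self):
        preset = dataclasses.replace(PRESETS["C"], n_configs=1, renders_per_config=1)
        plan = build_generation_plan(preset, np.random.default_rng(0))
        assert len(plan) == 1

    def test_config_ids_traceable(self):
        preset = dataclasses.replace(PRESETS["B"], n_configs=7, renders_per_config=3)
        plan = build_generation_plan(preset, np.random.default_rng(4))
        ids = {}
        for cfg in plan:
            ids.setdefault(cfg.config_id, []).append(cfg.render_index)
        assert len(ids) == 7
        assert all(sorted(v) == [0, 1, 2] for v in ids.values())

    def test_renders_share_config_but_vary_lights(self):
        preset = dataclasses.replace(PRESETS["B"], n_configs=2, renders_per_config=4)
        plan = build_generation_plan(preset, np.random.default_rng(5))
        first = [c for c in plan if c.config_id == plan[0].config_id]
        assert all(np.allclose(c.pose.joint_rotation, first[0].pose.joint_rotation) for c in first)
        assert all(c.camera == first[0].camera for c in first)
        intensities = {tuple(l.intensity for l in c.lights) for c in first}
        assert len(intensities) == 4

    def test_identical_seeds_identical_plans(self):
        preset = dataclasses.replace(PRESETS["B"], n_configs=5, renders_per_config=2)
        p1 = build_generation_plan(preset, np.random.default_rng(42), n_backgrounds=4)
        p2 = build_generation_plan(preset, np.random.default_rng(42), n_backgrounds=4)
        assert _plan_fingerprint(p1) == _plan_fingerprint(p2)

    def test_samples_inside_preset_intervals_never_clipped(self):
        preset = dataclasses.replace(PRESETS["C"], n_configs=40, renders_per_config=1)
        plan = build_generation_plan(preset, np.random.default_rng(6))
        for c in plan:
            assert 15 <= c.camera.azimuth_deg <= 35
            for l in c.lights:
                assert 0.3 <= l.intensity <= 3.0
            if c.blanket is not None:
                assert 0.3 <= c.blanket.coverage_fraction <= 0.9
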