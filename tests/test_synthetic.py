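"""Synthetic MR-image generator: determinism, exact labels, camera semantics."""

import math

import numpy as np
import pytest

import rhizolen as rl
from rhizolen.synthetic import _draw_polyline, _sample_polyline_mm


def brute_force_length(points):
    return sum(
        math.hypot(x1 - x0, y1 - y0)
        for (x0, y0), (x1, y1) in zip(points[:-1], points[1:])
    )


SMALL_AUTO = rl.CameraProfile("small_auto", (25.0, 19.0), (246, 162), 18.75)
SMALL_MANUAL = rl.CameraProfile("small_manual", (18.0, 13.5), (208, 156), 13.5,
                                crop_px=(208, 150))


class TestSampleRootPolyline:
    def test_deterministic_under_fixed_seed(self):
        spec = rl.automated_scene_spec()
        a = rl.sample_root_polyline(spec, np.random.default_rng(9))
        b = rl.sample_root_polyline(spec, np.random.default_rng(9))
        np.testing.assert_array_equal(a.points, b.points)

    def test_length_matches_brute_force(self, rng):
        spec = rl.automated_scene_spec()
        for _ in range(50):
            poly = rl.sample_root_polyline(spec, rng)
            assert rl.polyline_length_px(poly) == pytest.approx(
                brute_force_length(poly.points), abs=1e-9
            )

    def test_zero_curvature_gives_straight_segment(self, rng):
        spec = rl.automated_scene_spec(heading_sigma_rad=0.0)
        ww, wh = spec.world_mm
        pitch = spec.camera.pixel_pitch_mm
        checked = 0
        for _ in range(200):
            poly = rl.sample_root_polyline(spec, rng)
            pts = poly.points
            mm = pts * pitch
            inside = (
                mm[:, 0].min() > 1e-9 and mm[:, 1].min() > 1e-9
                and mm[:, 0].max() < ww - 1e-9 and mm[:, 1].max() < wh - 1e-9
            )
            if not inside:
                continue  # walks clamped at the world border bend there
            endpoint = math.hypot(*(pts[-1] - pts[0]))
            assert rl.polyline_length_px(poly) == pytest.approx(endpoint, rel=1e-9)
            checked += 1
        assert checked >= 10

    def test_point_count_in_configured_range(self, rng):
        spec = rl.automated_scene_spec()
        for _ in range(50):
            n = len(rl.sample_root_polyline(spec, rng).points)
            assert spec.n_points_range[0] <= n <= spec.n_points_range[1]


class TestSharedWorldGeometry:
    def test_same_seed_same_mm_geometry_across_cameras(self):
        manual = rl.manual_scene_spec(camera=SMALL_MANUAL)
        auto = rl.automated_scene_spec(camera=SMALL_AUTO)
        assert manual.world_mm == auto.world_mm
        a = _sample_polyline_mm(manual, np.random.default_rng(4))
        b = _sample_polyline_mm(auto, np.random.default_rng(4))
        np.testing.assert_array_equal(a, b)

    def test_projected_lengths_agree_in_mm_away_from_borders(self):
        # the same world polyline, viewed by both cameras, has the same mm
        # length whenever it lies inside both stored frames
        manual = rl.manual_scene_spec(camera=SMALL_MANUAL)
        auto = rl.automated_scene_spec(camera=SMALL_AUTO)
        rng_m, rng_a = np.random.default_rng(21), np.random.default_rng(21)
        found = 0
        for _ in range(50):
            pm = rl.sample_root_polyline(manual, rng_m)
            pa = rl.sample_root_polyline(auto, rng_a)
            mm_m = pm.points * manual.camera.pixel_pitch_mm
            mm_a = pa.points * auto.camera.pixel_pitch_mm
            wm, hm = SMALL_MANUAL.image_size_px
            if pm.points[:, 0].max() < wm - 1 and pm.points[:, 1].max() < hm - 1:
                np.testing.assert_allclose(mm_m, mm_a, atol=1e-9)
                found += 1
        assert found >= 5


class TestRenderImage:
    def test_same_seed_byte_identical(self):
        spec = rl.automated_scene_spec(camera=SMALL_AUTO)
        polys = [rl.sample_root_polyline(spec, np.random.default_rng(3))]
        img1, _ = rl.render_image(polys, spec, np.random.default_rng(5))
        img2, _ = rl.render_image(polys, spec, np.random.default_rng(5))
        assert img1.dtype == np.uint8
        np.testing.assert_array_equal(img1, img2)

    def test_zero_roots_means_no_root_strokes_and_zero_trl(self):
        # with no polylines the root-contrast term cannot touch the image:
        # frames rendered under wildly different contrast are identical
        lo = rl.automated_scene_spec(camera=SMALL_AUTO, contrast=0.05)
        hi = rl.automated_scene_spec(camera=SMALL_AUTO, contrast=0.9)
        img_lo, ann = rl.render_image([], lo, np.random.default_rng(8))
        img_hi, _ = rl.render_image([], hi, np.random.default_rng(8))
        assert ann.trl_mm == 0.0
        # scratches scale with contrast, so compare only scratch-free renders
        lo2 = rl.automated_scene_spec(camera=SMALL_AUTO, contrast=0.05, scratch_rate=0.0)
        hi2 = rl.automated_scene_spec(camera=SMALL_AUTO, contrast=0.9, scratch_rate=0.0)
        img_lo, _ = rl.render_image([], lo2, np.random.default_rng(8))
        img_hi, _ = rl.render_image([], hi2, np.random.default_rng(8))
        np.testing.assert_array_equal(img_lo, img_hi)

    def test_zero_contrast_roots_vanish_into_soil(self):
        spec = rl.automated_scene_spec(
            camera=SMALL_AUTO, contrast=0.0, scratch_rate=0.0, bubble_rate=0.0
        )
        rng = np.random.default_rng(13)
        poly = rl.sample_root_polyline(spec, rng)
        img, _ = rl.render_image([poly], spec, np.random.default_rng(14))
        w, h = SMALL_AUTO.image_size_px
        mask = np.zeros((h, w))
        _draw_polyline(mask, poly.points, radius=3.0)
        # compare against a ring of nearby soil so the illumination gradient
        # and texture blotches do not confound the contrast estimate
        from scipy.ndimage import binary_dilation

        on = mask > 0.5
        ring = binary_dilation(on, iterations=6) & ~on
        diff = abs(img[on].mean() - img[ring].mean()) / 255.0
        assert diff < spec.noise_std

    def test_nonzero_contrast_roots_are_visible(self):
        spec = rl.automated_scene_spec(
            camera=SMALL_AUTO, scratch_rate=0.0, bubble_rate=0.0
        )
        rng = np.random.default_rng(13)
        poly = rl.sample_root_polyline(spec, rng)
        img, _ = rl.render_image([poly], spec, np.random.default_rng(14))
        w, h = SMALL_AUTO.image_size_px
        mask = np.zeros((h, w))
        _draw_polyline(mask, poly.points, radius=3.0)
        from scipy.ndimage import binary_dilation

        on = mask > 0.5
        ring = binary_dilation(on, iterations=6) & ~on
        diff = (img[on].mean() - img[ring].mean()) / 255.0
        assert diff > 3 * spec.noise_std

    def test_annotation_carries_exactly_the_generating_polylines(self):
        spec = rl.automated_scene_spec(camera=SMALL_AUTO)
        rng = np.random.default_rng(2)
        polys = [rl.sample_root_polyline(spec, rng) for _ in range(3)]
        _, ann = rl.render_image(polys, spec, rng)
        assert len(ann.roots) == 3
        for given, stored in zip(polys, ann.roots):
            np.testing.assert_array_equal(given.points, stored.points)


class TestGenerateDataset:
    def test_round_trip_trl_matches_generator_exactly(self, tmp_path):
        spec = rl.automated_scene_spec(camera=SMALL_AUTO)
        index = rl.generate_dataset(12, spec, tmp_path / "ds",
                                    rng=np.random.default_rng(31))
        loaded = rl.load_annotations(tmp_path / "ds")
        assert len(loaded) == 12
        for a, b in zip(index, loaded):
            assert b.annotation.trl_mm == pytest.approx(a.annotation.trl_mm, abs=1e-6)

    def test_zero_root_count_is_reproducible_and_plausible(self, tmp_path):
        spec = rl.automated_scene_spec(camera=SMALL_AUTO, p_empty=0.3)
        i1 = rl.generate_dataset(40, spec, tmp_path / "d1", rng=np.random.default_rng(77))
        i2 = rl.generate_dataset(40, spec, tmp_path / "d2", rng=np.random.default_rng(77))
        empty1 = [r.annotation.image_id for r in i1 if r.annotation.trl_mm == 0]
        empty2 = [r.annotation.image_id for r in i2 if r.annotation.trl_mm == 0]
        assert empty1 == empty2
        # 4-sigma band of Binomial(40, 0.3)
        assert 1 <= len(empty1) <= 24

    def test_manual_profile_yields_624_by_450_images(self, tmp_path):
        from PIL import Image

        spec = rl.manual_scene_spec()
        index = rl.generate_dataset(2, spec, tmp_path / "m",
                                    rng=np.random.default_rng(1))
        for rec in index:
            with Image.open(rec.resolve_path()) as im:
                assert im.size == (624, 450)

    def test_same_seed_regenerates_byte_identical_files(self, tmp_path):
        spec = rl.automated_scene_spec(camera=SMALL_AUTO)
        rl.generate_dataset(4, spec, tmp_path / "a", rng=np.random.default_rng(9))
        rl.generate_dataset(4, spec, tmp_path / "b", rng=np.random.default_rng(9))
        for name in ["images.csv", "points.csv", "images/img_00000.png",
                     "images/img_00003.png"]:
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_tube_and_depth_metadata_assigned(self, tmp_path):
        spec = rl.automated_scene_spec(camera=SMALL_AUTO)
        index = rl.generate_dataset(10, spec, tmp_path / "ds",
                                    rng=np.random.default_rng(3), depths_per_tube=4)
        anns = [r.annotation for r in index]
        assert [a.depth_index for a in anns[:5]] == [0, 1, 2, 3, 0]
        assert anns[0].tube_id != anns[4].tube_id


def test_invalid_scene_spec_rejected():
    with pytest.raises(ValueError):
        rl.automated_scene_spec(p_empty=1.5)
    with pytest.raises(ValueError):
        rl.automated_scene_spec(noise_std=-0.1)
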