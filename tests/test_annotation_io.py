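"""Geometry, camera profiles, serialization and dataset splitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rhizolen as rl
from rhizolen.annotation_io import (
    AnnotationError,
    AnisotropicPitchWarning,
    ConfigurationError,
    _largest_remainder_counts,
)


def brute_force_length(points):
    total = 0.0
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        total += math.hypot(x1 - x0, y1 - y0)
    return total


def make_annotation(roots_pts, camera=rl.MANUAL_CAMERA, **meta):
    return rl.ImageAnnotation(
        image_id=meta.pop("image_id", "img0"),
        roots=[rl.RootPolyline(np.asarray(p, dtype=float)) for p in roots_pts],
        camera=camera,
        **meta,
    )


class TestPolylineLength:
    def test_three_four_five(self):
        assert rl.polyline_length_px(rl.RootPolyline(np.array([[0, 0], [3, 4]]))) == 5.0

    def test_single_point_has_zero_length(self):
        assert rl.polyline_length_px(rl.RootPolyline(np.array([[10, 10]]))) == 0.0

    def test_matches_brute_force_on_1000_random_polylines(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            pts = rng.uniform(0, 400, size=(n, 2))
            poly = rl.RootPolyline(pts)
            assert rl.polyline_length_px(poly) == pytest.approx(
                brute_force_length(pts), abs=1e-9
            )

    def test_empty_point_list_rejected(self):
        with pytest.raises(AnnotationError):
            rl.RootPolyline(np.empty((0, 2)))


class TestCameraProfile:
    def test_manual_pitch_is_18_over_640(self):
        assert rl.pixel_pitch_mm(rl.MANUAL_CAMERA) == pytest.approx(18 / 640)
        assert rl.pixel_pitch_mm(rl.MANUAL_CAMERA) == pytest.approx(0.028125)

    def test_manual_pitch_is_isotropic(self):
        cam = rl.MANUAL_CAMERA
        assert cam.fov_mm[1] / cam.size_px[1] == pytest.approx(cam.pixel_pitch_mm)

    def test_automated_pitch_is_25_over_2952(self):
        assert rl.pixel_pitch_mm(rl.AUTOMATED_CAMERA) == pytest.approx(25 / 2952)
        assert rl.pixel_pitch_mm(rl.AUTOMATED_CAMERA) == pytest.approx(0.0084688, abs=1e-7)

    def test_crop_does_not_change_pitch_but_sets_image_size(self):
        cam = rl.MANUAL_CAMERA
        assert cam.image_size_px == (624, 450)
        assert cam.pixel_pitch_mm == 18 / 640  # computed from the native 640-px frame

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ConfigurationError):
            rl.CameraProfile("bad", (0, 13.5), (640, 480), 13.5)
        with pytest.raises(ConfigurationError):
            rl.CameraProfile("bad", (18, 13.5), (640, 480), 0.0)
        with pytest.raises(ConfigurationError):
            rl.CameraProfile("bad", (18, 13.5), (640, 480), 13.5, crop_px=(700, 450))

    def test_anisotropic_profile_warns_not_raises(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            with pytest.raises(AnisotropicPitchWarning):
                rl.CameraProfile("aniso", (25.0, 19.0), (100, 100), 18.75)


class TestImageTrl:
    def test_no_roots_is_zero(self):
        assert make_annotation([]).trl_mm == 0.0

    def test_100px_under_manual_pitch(self):
        ann = make_annotation([[(0, 0), (100, 0)]])
        assert rl.image_trl_mm(ann) == pytest.approx(100 * 18 / 640)
        assert rl.image_trl_mm(ann) == pytest.approx(2.8125)

    def test_additivity_over_polylines(self, rng):
        a = rng.uniform(0, 400, size=(5, 2))
        b = rng.uniform(0, 400, size=(7, 2))
        both = make_annotation([a, b])
        only_a = make_annotation([a])
        only_b = make_annotation([b])
        assert both.trl_mm == pytest.approx(only_a.trl_mm + only_b.trl_mm, abs=1e-12)

    def test_single_point_roots_contribute_zero(self):
        ann = make_annotation([[(5, 5)], [(9, 2)]])
        assert ann.trl_mm == 0.0

    @given(st.integers(0, 2**31 - 1))
    def test_reversal_invariance(self, seed):
        pts = np.random.default_rng(seed).uniform(0, 400, size=(6, 2))
        ann_fwd = make_annotation([pts])
        ann_rev = make_annotation([pts[::-1]])
        assert ann_fwd.trl_mm == pytest.approx(ann_rev.trl_mm, abs=1e-12)

    def test_trl_scales_linearly_with_pitch(self, rng):
        pts = rng.uniform(0, 400, size=(6, 2))
        cam1 = rl.CameraProfile("c1", (18, 13.5), (640, 480), 13.5)
        cam2 = rl.CameraProfile("c2", (36, 27.0), (640, 480), 13.5)
        t1 = make_annotation([pts], camera=cam1).trl_mm
        t2 = make_annotation([pts], camera=cam2).trl_mm
        assert t2 == pytest.approx(2 * t1)

    def test_out_of_bounds_point_rejected(self):
        with pytest.raises(AnnotationError, match="bounds"):
            make_annotation([[(0, 0), (624, 10)]])  # stored manual frame is 624 wide
        with pytest.raises(AnnotationError):
            make_annotation([[(-1, 0)]])


class TestSerialization:
    def _index(self):
        anns = [
            make_annotation([[(0, 0), (100.5, 200.25)], [(10, 10)]],
                            image_id="a", tube_id="t1", depth_index=0, date="2021-06-01"),
            make_annotation([], image_id="b", tube_id="t1", depth_index=1,
                            date="2021-06-01"),
            make_annotation([[(5, 5), (6, 7), (8, 2)]], camera=rl.AUTOMATED_SIM_CAMERA,
                            image_id="c"),
        ]
        return rl.DatasetIndex(
            [rl.IndexRecord(path=f"images/{a.image_id}.png", annotation=a, split=s)
             for a, s in zip(anns, ["train", "val", None])]
        )

    @pytest.mark.parametrize("fmt", ["csv_dir", "json"])
    def test_round_trip_is_identity(self, tmp_path, fmt):
        index = self._index()
        target = tmp_path / ("idx" if fmt == "csv_dir" else "idx.json")
        rl.save_annotations(index, target)
        loaded = rl.load_annotations(target)
        assert len(loaded) == len(index)
        for orig, back in zip(index, loaded):
            assert back.path == orig.path
            assert back.split == orig.split
            a, b = orig.annotation, back.annotation
            assert b.image_id == a.image_id
            assert b.camera == a.camera
            assert (b.tube_id, b.depth_index, b.date) == (a.tube_id, a.depth_index, a.date)
            assert len(b.roots) == len(a.roots)
            for pa, pb in zip(a.roots, b.roots):
                np.testing.assert_array_equal(pa.points, pb.points)
            assert b.trl_mm == pytest.approx(a.trl_mm, abs=1e-12)

    def test_zero_root_image_loads_with_trl_zero(self, tmp_path):
        index = self._index()
        rl.save_annotations(index, tmp_path / "idx")
        loaded = rl.load_annotations(tmp_path / "idx")
        b = next(r for r in loaded if r.annotation.image_id == "b")
        assert b.annotation.roots == []
        assert b.annotation.trl_mm == 0.0

    def test_negative_coordinate_names_offending_record(self, tmp_path):
        index = self._index()
        rl.save_annotations(index, tmp_path / "idx")
        pts = (tmp_path / "idx" / "points.csv").read_text().replace("5.0,5.0", "-1.0,5.0")
        (tmp_path / "idx" / "points.csv").write_text(pts)
        with pytest.raises(AnnotationError, match="c"):
            rl.load_annotations(tmp_path / "idx")

    def test_missing_file_is_an_error(self, tmp_path):
        with pytest.raises(AnnotationError):
            rl.load_annotations(tmp_path / "nothing.csv")


class TestSplitDataset:
    def _index(self, n):
        recs = []
        for i in range(n):
            ann = make_annotation([], image_id=f"im{i:04d}")
            recs.append(rl.IndexRecord(path=f"{i}.png", annotation=ann))
        return rl.DatasetIndex(recs)

    def test_exact_fraction_sizes(self):
        out = rl.split_dataset(self._index(100), (0.73, 0.09, 0.18), seed=3)
        sizes = {s: len(out.subset(s)) for s in ("train", "val", "test")}
        assert sizes == {"train": 73, "val": 9, "test": 18}

    def test_split_is_a_partition(self):
        out = rl.split_dataset(self._index(57), (0.73, 0.09, 0.18), seed=0)
        ids = [r.annotation.image_id for r in out]
        by_split = [set(r.annotation.image_id for r in out.subset(s))
                    for s in ("train", "val", "test")]
        assert sum(len(s) for s in by_split) == 57
        assert set().union(*by_split) == set(ids)

    def test_largest_remainder_on_420_images(self):
        # independent recount of the rounding rule
        n, fractions = 420, (0.72, 0.10, 0.18)
        quotas = [n * f for f in fractions]
        floors = [math.floor(q) for q in quotas]
        order = sorted(range(3), key=lambda i: quotas[i] - floors[i], reverse=True)
        expected = list(floors)
        for i in order[: n - sum(floors)]:
            expected[i] += 1
        assert sum(expected) == 420
        assert _largest_remainder_counts(n, fractions) == expected
        out = rl.split_dataset(self._index(n), fractions, seed=11)
        assert [len(out.subset(s)) for s in ("train", "val", "test")] == expected

    def test_same_seed_identical_different_seed_differs(self):
        idx = self._index(100)
        a = rl.split_dataset(idx, seed=5)
        b = rl.split_dataset(idx, seed=5)
        c = rl.split_dataset(idx, seed=6)
        assert [r.split for r in a] == [r.split for r in b]
        n_diff = sum(x.split != y.split for x, y in zip(a, c))
        assert n_diff > 0

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            rl.split_dataset(self._index(10), (0.5, 0.2, 0.2), seed=0)
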