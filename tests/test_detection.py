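"""Rotation estimation, profile thresholding and grid extraction."""

import numpy as np
import pytest

from microplots import (DetectionConfig, DetectionError, FieldLayout,
                        SyntheticFieldSpec, estimate_rotation,
                        extract_microplots, generate_field)
from microplots.detection import (PixelInterval, detect_columns, detect_rows,
                                  erase_below_fraction, profile,
                                  scan_transitions)
from microplots.evaluation import polygon_iou


class TestEstimateRotation:
    def test_axis_aligned_field_has_zero_angle(self):
        scene = generate_field(SyntheticFieldSpec(
            n_columns=3, n_rows=4, rotation_deg=0.0, weed_density=0.0, seed=0))
        rot = estimate_rotation(scene.truth_mask)
        assert abs(rot.angle_deg) <= 0.5

    @pytest.mark.parametrize("angle", [12.0, -12.0, 5.0])
    def test_recovers_generated_tilt(self, angle):
        scene = generate_field(SyntheticFieldSpec(
            n_columns=3, n_rows=6, rotation_deg=angle, weed_density=0.0, seed=1))
        rot = estimate_rotation(scene.truth_mask)
        assert rot.angle_deg == pytest.approx(angle, abs=1.0)

    def test_pixel_map_is_invertible_within_half_pixel(self, small_scene):
        rot = estimate_rotation(small_scene.truth_mask)
        pts = np.array([[10.0, 20.0], [100.0, 50.0], [3.5, 90.25]])
        back = rot.pixel_map.inverse().apply(rot.pixel_map.apply(pts))
        assert np.abs(back - pts).max() < 0.5

    def test_empty_mask_is_an_error(self):
        with pytest.raises(DetectionError):
            estimate_rotation(np.zeros((10, 10), bool))


class TestProfiles:
    def test_all_zero_mask_gives_zero_vector(self):
        assert profile(np.zeros((5, 7), bool), "x").tolist() == [0] * 7

    def test_single_white_column(self):
        mask = np.zeros((6, 9), bool)
        mask[:, 4] = True
        prof = profile(mask, "x")
        assert prof[4] == 6 and prof.sum() == 6

    def test_profile_conserves_total_count(self, rng):
        mask = rng.random((20, 30)) > 0.6
        assert profile(mask, "x").sum() == mask.sum() == profile(mask, "y").sum()

    def test_erase_below_third_of_mean(self):
        out = erase_below_fraction(np.array([9.0, 9.0, 1.0, 9.0]), 1 / 3)
        assert out.tolist() == [9.0, 9.0, 0.0, 9.0]  # mean 7, cutoff 7/3

    def test_erase_keeps_constant_profile(self):
        prof = np.full(10, 4.0)
        assert erase_below_fraction(prof, 0.9).tolist() == prof.tolist()

    def test_erase_keeps_ties_at_the_threshold(self):
        # mean 8, cutoff 4: the entry equal to 4 survives ("less than")
        out = erase_below_fraction(np.array([10.0, 4.0, 10.0]), 0.5)
        assert out.tolist() == [10.0, 4.0, 10.0]

    def test_erase_rejects_all_zero_profile(self):
        with pytest.raises(ValueError):
            erase_below_fraction(np.zeros(5), 0.5)

    def test_erase_never_increases_entries(self, rng):
        prof = rng.random(50) * 10
        out = erase_below_fraction(prof, 0.7)
        assert (out <= prof).all()


class TestScanTransitions:
    def test_definition(self):
        assert scan_transitions(np.array([0, 0, 5, 5, 0, 3, 0])) == \
            [PixelInterval(2, 4), PixelInterval(5, 6)]

    def test_all_positive(self):
        assert scan_transitions(np.ones(7)) == [PixelInterval(0, 7)]

    def test_all_zero_gives_empty_list(self):
        assert scan_transitions(np.zeros(4)) == []

    def test_matches_run_length_encoding_oracle(self, rng):
        for _ in range(100):
            vec = rng.integers(0, 2, size=rng.integers(1, 60))
            runs, start = [], None
            for i, v in enumerate(vec):  # literal run-length scan
                if v and start is None:
                    start = i
                elif not v and start is not None:
                    runs.append((start, i))
                    start = None
            if start is not None:
                runs.append((start, len(vec)))
            assert [tuple(iv) for iv in scan_transitions(vec)] == runs

    def test_intervals_shrink_as_fraction_grows(self, rng):
        prof = rng.random(80) * 10
        lo = scan_transitions(erase_below_fraction(prof, 0.2))
        hi = scan_transitions(erase_below_fraction(prof, 0.8))
        covered_lo = {i for s, e in lo for i in range(s, e)}
        covered_hi = {i for s, e in hi for i in range(s, e)}
        assert covered_hi <= covered_lo


class TestDetectColumnsAndRows:
    def test_columns_contain_truth_centers(self):
        scene = generate_field(SyntheticFieldSpec(
            n_columns=4, n_rows=8, rotation_deg=0.0, weed_density=0.0, seed=5))
        layout = FieldLayout(4, 8)
        intervals = detect_columns(scene.truth_mask, layout)
        assert len(intervals) == 4
        centers = sorted({(r.pixel_bounds[0].start + r.pixel_bounds[0].end) / 2
                          for r in scene.truth_grid})
        for (s, e), c in zip(intervals, centers):
            assert s <= c <= e

    def test_single_solid_block_is_one_column(self):
        mask = np.zeros((60, 40), bool)
        mask[10:50, 8:30] = True
        (iv,) = detect_columns(mask, FieldLayout(1, 1))
        assert iv.start <= 8 and iv.end >= 30

    def test_intercolumn_weeds_do_not_shift_intervals(self):
        clean = generate_field(SyntheticFieldSpec(
            n_columns=4, n_rows=8, rotation_deg=0.0, weed_density=0.0, seed=6))
        weedy = generate_field(SyntheticFieldSpec(
            n_columns=4, n_rows=8, rotation_deg=0.0, weed_density=0.8, seed=6))
        layout = FieldLayout(4, 8)
        a = detect_columns(clean.truth_mask, layout)
        b = detect_columns(weedy.truth_mask, layout)
        for (s0, e0), (s1, e1) in zip(a, b):
            assert abs(s0 - s1) <= 3 and abs(e0 - e1) <= 3

    def test_rows_match_truth_centers(self):
        scene = generate_field(SyntheticFieldSpec(
            n_columns=1, n_rows=34, rotation_deg=0.0, weed_density=0.0, seed=7))
        rows = detect_rows(scene.truth_mask, FieldLayout(1, 34))
        assert len(rows) == 34
        centers = sorted((r.pixel_bounds[1].start + r.pixel_bounds[1].end) / 2
                         for r in scene.truth_grid)
        for (s, e), c in zip(rows, centers):
            assert s <= c <= e

    def test_single_solid_row(self):
        mask = np.zeros((30, 50), bool)
        mask[12:20, :] = True
        (iv,) = detect_rows(mask, FieldLayout(1, 1))
        assert (iv.start, iv.end) == (12, 20)

    def test_missing_columns_raise_with_counts(self):
        scene = generate_field(SyntheticFieldSpec(
            n_columns=2, n_rows=4, rotation_deg=0.0, weed_density=0.0, seed=8))
        with pytest.raises(DetectionError, match="2.*5"):
            detect_columns(scene.truth_mask, FieldLayout(5, 4))

    def test_intervals_are_sorted_and_disjoint(self, small_scene):
        rot = estimate_rotation(small_scene.truth_mask)
        intervals = detect_columns(rot.rotated_mask, FieldLayout(3, 4))
        for (s0, e0), (s1, e1) in zip(intervals, intervals[1:]):
            assert e0 <= s1


class TestExtractMicroplots:
    def test_dataset1_like_grid_has_136_records(self):
        scene = generate_field(SyntheticFieldSpec(
            n_columns=4, n_rows=34, rotation_deg=0.0, seed=9))
        rot = estimate_rotation(scene.truth_mask)
        plots = extract_microplots(scene.truth_mask, FieldLayout(4, 34), rot,
                                   scene.geotransform)
        assert len(plots) == 136

    def test_identity_geotransform_gives_pixel_corners(self):
        scene = generate_field(SyntheticFieldSpec(
            n_columns=2, n_rows=3, rotation_deg=0.0, weed_density=0.0,
            plant_fill=1.0, seed=10))
        rot = estimate_rotation(scene.truth_mask)
        plots = extract_microplots(scene.truth_mask, FieldLayout(2, 3), rot)
        for p in plots:
            (x0, x1), (y0, y1) = p.pixel_bounds
            expected = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], float)
            np.testing.assert_allclose(p.world_polygon, expected, atol=0.51)

    def test_grid_recovery_iou_on_default_scene(self, small_scene):
        rot = estimate_rotation(small_scene.truth_mask)
        plots = extract_microplots(small_scene.truth_mask, FieldLayout(3, 4),
                                   rot, small_scene.geotransform)
        ious = [polygon_iou(p.world_polygon, t.world_polygon)
                for p, t in zip(plots, small_scene.truth_grid)]
        assert np.mean(ious) >= 95.0

    def test_horizontal_orientation_single_code_path(self):
        scene = generate_field(SyntheticFieldSpec(
            n_columns=3, n_rows=5, rotation_deg=4.0, orientation="horizontal",
            weed_density=0.0, seed=11))
        layout = FieldLayout(3, 5, orientation="horizontal")
        rot = estimate_rotation(scene.truth_mask, "horizontal")
        plots = extract_microplots(scene.truth_mask, layout, rot,
                                   scene.geotransform)
        assert len(plots) == 15
        ious = [polygon_iou(p.world_polygon, t.world_polygon)
                for p, t in zip(plots, scene.truth_grid)]
        assert np.mean(ious) >= 95.0

    def test_records_within_a_column_have_disjoint_y_intervals(self, small_scene):
        rot = estimate_rotation(small_scene.truth_mask)
        plots = extract_microplots(small_scene.truth_mask, FieldLayout(3, 4),
                                   rot, small_scene.geotransform)
        by_col = {}
        for p in plots:
            by_col.setdefault(p.column_index, []).append(p.pixel_bounds[1])
        for intervals in by_col.values():
            intervals.sort()
            for (s0, e0), (s1, e1) in zip(intervals, intervals[1:]):
                assert e0 <= s1 + 1  # bounding boxes may abut after unrotation


def test_fraction_config_validation():
    with pytest.raises(ValueError):
        DetectionConfig(column_fraction=1.5)
    with pytest.raises(ValueError):
        FieldLayout(0, 1)
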