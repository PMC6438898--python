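import math

import numpy as np
import pytest

from reachsketch.geometry import (
    CalibrationError,
    PatternOverflowError,
    calibrate_mapping,
    generate_pattern,
    generate_pattern_for_level,
    layout_monitor,
    map_hand_point,
    pattern_from_json,
    pattern_to_json,
)

LEVEL_CASES = [(lvl, hand) for lvl in range(1, 7) for hand in ("right", "left")]


class TestLayout:
    def test_two_to_one_zone_split(self):
        lay = layout_monitor(1600, 900)
        assert lay.zone_rects["BOTTOM"].y0 == 600
        assert lay.zone_rects["BOTTOM"].height == 300

    def test_subzones_tile_working_zone_disjointly(self):
        lay = layout_monitor(800, 450)
        top_h = lay.zone_top_height
        quads = [lay.zone_rects[z] for z in ("NE", "NW", "E", "W")]
        assert sum(r.width * r.height for r in quads) == pytest.approx(
            800 * top_h)
        for i, a in enumerate(quads):
            for b in quads[i + 1:]:
                # rectangles may share edges but not interiors
                overlap_w = min(a.x1, b.x1) - max(a.x0, b.x0)
                overlap_h = min(a.y1, b.y1) - max(a.y0, b.y0)
                assert min(overlap_w, overlap_h) <= 0

    def test_ne_zone_is_upper_right_quadrant(self):
        lay = layout_monitor(1600, 900)
        ne = lay.zone_rects["NE"]
        assert (ne.x0, ne.y0, ne.x1, ne.y1) == (800, 0, 1600, 300)

    @pytest.mark.parametrize("w,h", [(0, 900), (1600, -5), (640, 400)])
    def test_bad_dimensions_rejected(self, w, h):
        with pytest.raises(ValueError):
            layout_monitor(w, h)


class TestPatterns:
    @pytest.mark.parametrize("level,hand", LEVEL_CASES)
    def test_seven_dots_spaced_at_107(self, layout, level, hand):
        pat = generate_pattern_for_level(level, layout, hand)
        assert len(pat.dots) == 7
        d = np.diff(np.asarray(pat.dots), axis=0)
        spacing = np.hypot(d[:, 0], d[:, 1])
        assert np.allclose(spacing, 107.0, atol=0.5)
        assert pat.ideal_length_px == pytest.approx(642.0)

    @pytest.mark.parametrize("level,hand", LEVEL_CASES)
    def test_dots_inside_zone_inflated_by_radius(self, layout, level, hand):
        pat = generate_pattern_for_level(level, layout, hand)
        zone = layout.zone_rects[pat.zone]
        r = pat.dot_radius_px
        for x, y in pat.dots:
            assert zone.x0 + r <= x <= zone.x1 - r
            assert zone.y0 + r <= y <= zone.y1 - r

    @pytest.mark.parametrize("level", range(1, 7))
    def test_left_pattern_mirrors_right(self, layout, level):
        right = generate_pattern_for_level(level, layout, "right")
        left = generate_pattern_for_level(level, layout, "left")
        mirrored = [(layout.width_px - x, y) for x, y in right.dots]
        assert np.allclose(mirrored, left.dots)

    def test_level_zone_and_type_table(self, layout):
        for level in range(1, 7):
            pat = generate_pattern_for_level(level, layout, "right")
            assert pat.zone == ("E" if level <= 3 else "NE")
            expected = {1: "straight", 2: "triangular", 3: "square_wave",
                        4: "straight", 5: "triangular", 6: "square_wave"}
            assert pat.pattern_type == expected[level]

    def test_straight_dots_collinear_horizontal(self, layout):
        pat = generate_pattern_for_level(1, layout)
        ys = {y for _, y in pat.dots}
        assert len(ys) == 1

    def test_triangular_segments_at_sixty_degrees(self, layout):
        pat = generate_pattern_for_level(2, layout)
        d = np.diff(np.asarray(pat.dots), axis=0)
        angles = np.degrees(np.arctan2(-d[:, 1], d[:, 0]))  # y-down screen
        assert np.allclose(np.abs(angles), 60.0, atol=1e-9)
        assert np.all(np.sign(angles[:-1]) != np.sign(angles[1:]))

    def test_square_wave_consecutive_segments_perpendicular(self, layout):
        pat = generate_pattern_for_level(3, layout)
        d = np.diff(np.asarray(pat.dots), axis=0)
        dots = np.einsum("ij,ij->i", d[:-1], d[1:])
        assert np.allclose(dots, 0.0, atol=1e-9)

    def test_mismatched_type_and_level_rejected(self, layout):
        with pytest.raises(ValueError, match="requires pattern type"):
            generate_pattern("triangular", 1, layout)

    def test_overflow_error_names_zone(self, layout):
        with pytest.raises(PatternOverflowError, match="E"):
            generate_pattern("straight", 1, layout, spacing_px=400.0)

    def test_json_round_trip(self, layout):
        pat = generate_pattern_for_level(5, layout, "left")
        again = pattern_from_json(pattern_to_json(pat))
        assert again == pat


class TestCalibration:
    def test_endpoints_map_to_center_and_span(self):
        prof = calibrate_mapping(0.0, 40.0, span_px=700, center_x_px=800,
                                 direction="right")
        assert prof.map_angle(0.0) == pytest.approx(800)
        assert prof.map_angle(40.0) == pytest.approx(1500)
        left = calibrate_mapping(0.0, 40.0, span_px=700, center_x_px=800,
                                 direction="left")
        assert left.map_angle(40.0) == pytest.approx(100)

    def test_affine_midpoint(self):
        prof = calibrate_mapping(0.0, 40.0, span_px=700, center_x_px=800)
        assert prof.map_angle(20.0) == pytest.approx(800 + 350)

    def test_degenerate_range_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_mapping(10.0, 10.1)

    def test_individualized_span_independent_of_angle_magnitude(self):
        for periphery in (15.0, 40.0, 70.0):
            prof = calibrate_mapping(0.0, periphery, span_px=700,
                                     center_x_px=800)
            span = abs(prof.map_angle(periphery) - prof.map_angle(0.0))
            assert span == pytest.approx(700)


class TestHandPointMapping:
    def test_center_posture_maps_to_center(self, layout):
        prof = calibrate_mapping(0.0, 40.0, center_x_px=800)
        x, y = map_hand_point(0.0, 0.5, prof, layout)
        assert x == pytest.approx(800)
        assert y == pytest.approx(layout.zone_top_height / 2)

    def test_out_of_range_azimuth_clamped(self, layout):
        prof = calibrate_mapping(0.0, 40.0, center_x_px=800)
        x, _ = map_hand_point(90.0, 0.5, prof, layout)
        assert x == layout.width_px

    def test_elevation_endpoints(self, layout):
        prof = calibrate_mapping(0.0, 40.0, center_x_px=800)
        _, y_low = map_hand_point(10.0, 0.0, prof, layout)
        _, y_high = map_hand_point(10.0, 1.0, prof, layout)
        assert y_low == pytest.approx(layout.zone_top_height)
        assert y_high == pytest.approx(0.0)

    def test_round_trip_through_inverse_map(self, layout):
        prof = calibrate_mapping(5.0, 38.0, center_x_px=800)
        for x_target in (450.0, 800.0, 1100.0):
            azim = prof.inverse_map(x_target)
            x, _ = map_hand_point(azim, 0.5, prof, layout)
            assert x == pytest.approx(x_target, abs=1.0)
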