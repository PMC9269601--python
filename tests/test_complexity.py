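"""Fixation-gaze complexity: self-intersection counts and fractal dimension."""

import numpy as np
import pytest
import shapely.geometry as sg

from gazedys.complexity import (
    FixationComplexityRecord,
    box_counting_dimension,
    complexity_record,
    count_self_intersections,
    fixation_fractal_dimension,
    fixation_intersection_coefficient,
    fixation_intersection_variability,
)

from conftest import make_trial


def brute_force_intersections(points, eps=1e-9):
    """Independent all-pairs oracle with scalar orientation predicates."""

    def orient(a, b, c):
        d = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(d) <= eps:
            return 0
        return 1 if d > 0 else -1

    def on_segment(a, b, p):
        return (min(a[0], b[0]) - eps <= p[0] <= max(a[0], b[0]) + eps
                and min(a[1], b[1]) - eps <= p[1] <= max(a[1], b[1]) + eps)

    def intersects(p1, p2, p3, p4):
        d1 = orient(p3, p4, p1)
        d2 = orient(p3, p4, p2)
        d3 = orient(p1, p2, p3)
        d4 = orient(p1, p2, p4)
        if d1 * d2 < 0 and d3 * d4 < 0:
            return True
        if d1 == 0 and on_segment(p3, p4, p1):
            return True
        if d2 == 0 and on_segment(p3, p4, p2):
            return True
        if d3 == 0 and on_segment(p1, p2, p3):
            return True
        if d4 == 0 and on_segment(p1, p2, p4):
            return True
        return False

    pts = [tuple(p) for p in points]
    count = 0
    for i in range(len(pts) - 1):
        for j in range(i + 2, len(pts) - 1):
            if intersects(pts[i], pts[i + 1], pts[j], pts[j + 1]):
                count += 1
    return count


class TestCountSelfIntersections:
    def test_simple_open_square_path_has_none(self):
        assert count_self_intersections([(0, 0), (10, 0), (10, 10), (0, 10)]) == 0

    def test_bowtie_path_crosses_once(self):
        # segments 1 and 3 cross at (5, 5)
        assert count_self_intersections([(0, 0), (10, 10), (10, 0), (0, 10)]) == 1

    def test_short_polylines_have_no_pairs(self):
        assert count_self_intersections([]) == 0
        assert count_self_intersections([(0, 0), (1, 1), (2, 0)]) == 0

    def test_collinear_overlap_counts_once(self):
        # segment 0 and segment 2 overlap on the x axis
        path = [(0, 0), (10, 0), (10, 5), (5, 0), (-5, 0)]
        assert count_self_intersections(path) == brute_force_intersections(path)
        assert count_self_intersections(path) >= 1

    def test_shared_vertex_between_non_adjacent_segments_counts(self):
        # segments 0 and 2 touch exactly at (0, 0)
        path = [(0, 0), (10, 0), (5, 5), (0, 0), (-5, -5)]
        assert count_self_intersections(path) >= 1

    def test_matches_brute_force_oracle_on_random_polylines(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            pts = rng.uniform(0, 30, size=(int(rng.integers(4, 40)), 2))
            assert count_self_intersections(pts) == brute_force_intersections(pts)

    def test_matches_shapely_on_generic_position_polylines(self):
        # independent library cross-check; generic position (random floats)
        # avoids boundary-degenerate cases where conventions could differ
        rng = np.random.default_rng(99)
        for _ in range(50):
            pts = rng.uniform(0, 20, size=(25, 2))
            segments = [sg.LineString([pts[k], pts[k + 1]])
                        for k in range(len(pts) - 1)]
            expected = sum(
                segments[i].intersects(segments[j])
                for i in range(len(segments))
                for j in range(i + 2, len(segments)))
            assert count_self_intersections(pts) == expected

    def test_translation_and_reflection_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 50, size=(30, 2))
        base = count_self_intersections(pts)
        assert count_self_intersections(pts + [1000.0, -400.0]) == base
        assert count_self_intersections(pts * [-1.0, 1.0]) == base
        assert count_self_intersections(pts * [1.0, -1.0]) == base


class TestBoxCountingDimension:
    def test_straight_line_is_one_dimensional(self):
        line = np.column_stack([np.linspace(0, 256, 257), np.zeros(257)])
        assert 0.9 <= box_counting_dimension(line) <= 1.1

    def test_diagonal_line_is_one_dimensional(self):
        diag = np.column_stack([np.linspace(0, 200, 101), np.linspace(0, 200, 101)])
        assert 0.9 <= box_counting_dimension(diag) <= 1.1

    def test_single_repeated_point_is_degenerate(self):
        assert box_counting_dimension([(3.0, 4.0), (3.0, 4.0)]) == 0.0
        assert box_counting_dimension([(3.0, 4.0)]) == 0.0

    def test_space_filling_path_approaches_two(self):
        pts = []
        direction = 1
        for row in range(65):  # lines every 2 px over a 128 px square
            y = 2.0 * row
            xs = (0.0, 128.0) if direction > 0 else (128.0, 0.0)
            pts.append((xs[0], y))
            pts.append((xs[1], y))
            direction = -direction
        assert 1.8 <= box_counting_dimension(np.array(pts)) <= 2.05

    def test_translation_invariance(self):
        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 40, size=(50, 2))
        base = box_counting_dimension(pts)
        assert box_counting_dimension(pts + [250.0, -80.0]) == pytest.approx(
            base, abs=1e-9)


class TestComplexityAggregation:
    def test_mean_and_std_conventions(self):
        rec = FixationComplexityRecord(fi=[1, 2, 3], fd=[0.8, 1.2, 1.0], n=3)
        assert fixation_intersection_coefficient(rec) == pytest.approx(2.0)
        assert fixation_fractal_dimension(rec) == pytest.approx(1.0)
        rec2 = FixationComplexityRecord(fi=[0, 2], fd=[1.0, 1.0], n=2)
        assert fixation_intersection_variability(rec2) == pytest.approx(1.0)
        rec3 = FixationComplexityRecord(fi=[5, 5, 5, 5], fd=[1.0] * 4, n=4)
        assert fixation_intersection_variability(rec3) == 0.0

    def test_empty_record_yields_zeros(self):
        rec = FixationComplexityRecord(fi=[], fd=[], n=0)
        assert fixation_intersection_coefficient(rec) == 0.0
        assert fixation_intersection_variability(rec) == 0.0
        assert fixation_fractal_dimension(rec) == 0.0

    def test_random_arrays_match_direct_formulas(self):
        rng = np.random.default_rng(66)
        for _ in range(20):
            n = int(rng.integers(1, 30))
            fi = rng.integers(0, 10, n)
            fd = rng.uniform(0, 2, n)
            rec = FixationComplexityRecord(fi=fi, fd=fd, n=n)
            assert fixation_intersection_coefficient(rec) == pytest.approx(
                fi.sum() / n)
            assert fixation_fractal_dimension(rec) == pytest.approx(fd.sum() / n)
            expected_std = np.sqrt(np.mean((fi - fi.mean()) ** 2)) if n > 1 else 0.0
            assert fixation_intersection_variability(rec) == pytest.approx(expected_std)

    def test_trial_without_fixations(self):
        rec = complexity_record(make_trial("SSBB"))
        assert rec.n == 0 and len(rec.fi) == 0 and len(rec.fd) == 0

    def test_single_crossing_fixation_trial(self):
        trial = make_trial("FFFF", x=[0.0, 10.0, 10.0, 0.0], y=[0.0, 10.0, 0.0, 10.0])
        rec = complexity_record(trial)
        assert list(rec.fi) == [1]

    def test_validation_of_record_ranges(self):
        with pytest.raises(ValueError):
            FixationComplexityRecord(fi=[-1], fd=[1.0], n=1)
        with pytest.raises(ValueError):
            FixationComplexityRecord(fi=[0], fd=[2.5], n=1)
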