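import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cdac
from cdac.contour import ContourError

from conftest import has_self_intersection


class TestCumulativeDistance:
    def test_two_unit_edges(self, unit_square):
        assert cdac.cumulative_distance(unit_square, 0, 2) == pytest.approx(2.0)

    def test_same_index_is_zero(self, fine_circle):
        assert cdac.cumulative_distance(fine_circle, 7, 7) == 0.0

    def test_full_loop_is_perimeter(self, unit_square):
        assert cdac.cumulative_distance(unit_square, 0, 4) == pytest.approx(4.0)

    def test_backward_index_wraps_forward(self, unit_square):
        # from vertex 2 forward through the closing edge back to vertex 0
        assert cdac.cumulative_distance(unit_square, 2, 0) == pytest.approx(2.0)

    @given(st.integers(0, 7), st.integers(0, 7), st.integers(0, 7))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_additive_along_forward_traversal(self, i, dj, dk):
        rng = np.random.default_rng(3)
        th = np.sort(rng.uniform(0, 2 * np.pi, 8))
        c = cdac.Contour(np.column_stack([np.cos(th), np.sin(th)]) * 5)
        j, k = i + dj, i + dj + dk
        lhs = cdac.cumulative_distance(c, i, j) + cdac.cumulative_distance(c, j, k)
        assert lhs == pytest.approx(cdac.cumulative_distance(c, i, k), abs=1e-9)


class TestTotalLength:
    def test_unit_square(self, unit_square):
        assert cdac.total_length(unit_square) == pytest.approx(4.0)

    def test_fine_polygon_approximates_circumference(self, fine_circle):
        assert cdac.total_length(fine_circle) == pytest.approx(2 * np.pi * 10, rel=1e-3)

    def test_duplicate_vertex_removed_on_construction(self):
        c = cdac.Contour([(0, 0), (1, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert len(c) == 4
        assert cdac.total_length(c) == pytest.approx(4.0)


class TestOrientation:
    def test_clockwise_input_reversed(self):
        c = cdac.Contour([(0, 0), (0, 1), (1, 1), (1, 0)])  # negative shoelace
        assert c.signed_area > 0
        assert np.array_equal(c.vertices[0], [0, 0])  # first vertex kept first

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ContourError):
            cdac.Contour([(0, 0), (1, 1)])


class TestTangent:
    def test_collinear_points_give_axis_parallel_tangent(self):
        # vertex 9 sits mid-run: the 3-sigma window stays on the x-axis
        pts = [(x, 0) for x in range(20)] + [(19, 1), (0, 1)]
        c = cdac.Contour(pts)
        for x in (1, 2, 3):
            t = cdac.tangent(c, 9, x)
            assert abs(t[1]) < 1e-6 * abs(t[0])

    def test_circle_tangent_perpendicular_to_radius(self, fine_circle):
        for i in (0, 45, 200):
            t = cdac.tangent(fine_circle, i, 2)
            rad = fine_circle.vertices[i] - np.array([50.0, 50.0])
            cos = abs(t @ rad) / (np.linalg.norm(t) * np.linalg.norm(rad))
            assert cos < np.sin(np.radians(1.0))

    def test_mirror_image_flips_mirrored_component(self, fine_circle):
        mirrored = fine_circle.vertices * np.array([-1.0, 1.0])
        cm = cdac.Contour(mirrored, orient=False)  # keep traversal order
        t = cdac.tangent(fine_circle, 10, 3)
        tm = cdac.tangent(cm, 10, 3)
        assert tm[0] == pytest.approx(-t[0], abs=1e-9)
        assert tm[1] == pytest.approx(t[1], abs=1e-9)

    @pytest.mark.parametrize("theta", [0.3, 1.2, 2.8])
    def test_equivariant_under_rotation(self, theta):
        rng = np.random.default_rng(5)
        th = np.sort(rng.uniform(0, 2 * np.pi, 30))
        v = np.column_stack([np.cos(th), np.sin(th)]) * 8
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        c1 = cdac.Contour(v)
        c2 = cdac.Contour(v @ rot.T)
        for i in (0, 7, 19):
            assert np.allclose(rot @ cdac.tangent(c1, i, 2), cdac.tangent(c2, i, 2), atol=1e-6)


class TestNormal:
    def test_unit_length_and_perpendicular(self, fine_circle):
        for i, x in [(0, 1), (100, 3), (250, -2), (42, 0)]:
            n = cdac.normal(fine_circle, i, x)
            t = cdac.tangent(fine_circle, i, x)
            assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-9)
            assert abs(n @ t) / np.linalg.norm(t) < 1e-9

    def test_points_outward_on_ccw_polygon(self, fine_circle):
        center = np.array([50.0, 50.0])
        for i in range(0, 360, 30):
            n = cdac.normal(fine_circle, i, 2)
            rad = fine_circle.vertices[i] - center
            assert n @ rad > 0

    def test_vectorized_normals_match_scalar(self, fine_circle):
        nv = cdac.vertex_normals(fine_circle, 3)
        for i in (0, 11, 333):
            assert np.allclose(nv[i], cdac.normal(fine_circle, i, 3), atol=1e-9)


class TestResample:
    def test_unit_square_fine_spacing(self, unit_square):
        r = cdac.resample(unit_square, 0.1)
        assert len(r) == 40
        assert 3.9 <= cdac.total_length(r) <= 4.0

    def test_idempotent_within_one_spacing(self, fine_circle):
        r1 = cdac.resample(fine_circle, 2.0)
        r2 = cdac.resample(r1, 2.0)
        assert len(r1) == len(r2)
        d = np.linalg.norm(r1.vertices - r2.vertices, axis=1)
        assert d.max() < 2.0

    def test_centroid_nearly_preserved(self, fine_circle):
        r = cdac.resample(fine_circle, 1.5)
        assert np.linalg.norm(r.centroid - fine_circle.centroid) < 1.5

    def test_minimum_three_vertices(self):
        tri = cdac.Contour([(0, 0), (1, 0), (0.5, 1)])
        r = cdac.resample(tri, 100.0)
        assert len(r) == 3

    def test_orientation_preserved(self, fine_circle):
        assert cdac.resample(fine_circle, 2.0).signed_area > 0


class TestRemoveSelfIntersections:
    def test_simple_polygon_unchanged(self, fine_circle):
        out = cdac.remove_self_intersections(fine_circle)
        assert out is fine_circle

    def test_figure_eight_keeps_larger_square(self):
        # 2x2 square (area 4) and 1x1 square (area 1) joined at (0,2)
        v = [(0, 0), (2, 0), (2, 2), (0, 2), (0, 3), (-1, 3), (-1, 2), (0, 2)]
        out = cdac.remove_self_intersections(cdac.Contour(v, orient=False))
        assert out.signed_area == pytest.approx(4.0)
        assert not has_self_intersection(out)

    def test_bowtie_resolved(self):
        c = cdac.Contour([(0, 0), (4, 0), (0, 3), (4, 3)], orient=False)
        out = cdac.remove_self_intersections(c)
        assert not has_self_intersection(out)
        assert out.signed_area > 0

    def test_zero_area_spike_removed(self):
        v = [(0, 0), (4, 0), (4, 4), (2, 4), (2, 6), (2, 4), (0, 4)]
        out = cdac.remove_self_intersections(cdac.Contour(v, orient=False))
        assert out.signed_area == pytest.approx(16.0)
        assert not has_self_intersection(out)

    def test_random_crossing_polygons_cleaned(self):
        rng = np.random.default_rng(11)
        cleaned = 0
        for _ in range(20):
            v = rng.uniform(0, 20, size=(8, 2))
            try:
                c = cdac.Contour(v)
            except ContourError:
                continue
            out = cdac.remove_self_intersections(c)
            assert not has_self_intersection(out)
            cleaned += 1
        assert cleaned >= 15
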