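import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import circle_seed
from gimotion.contouring import (
    average_image,
    build_series,
    contour_frames,
    polygon_area,
    polygon_centroid,
    resample_contour,
)
from gimotion.core import FrameStack, SeedContour, WallContour, signed_area


def _regular_polygon(n, r, center=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(th),
                            center[1] + r * np.sin(th)])


class TestResampleContour:
    def test_circle_radius_and_spacing(self):
        c = resample_contour(circle_seed(n=20, radius=50.0), 100)
        radii = np.linalg.norm(c.points - [80.0, 80.0], axis=1)
        assert np.max(np.abs(radii - 50.0)) / 50.0 < 0.005
        spacing = np.linalg.norm(np.roll(c.points, -1, axis=0) - c.points, axis=1)
        assert np.ptp(spacing) / spacing.mean() < 0.01

    def test_clockwise_seeds_normalized_counterclockwise(self):
        c = resample_contour(circle_seed(clockwise=True), 100)
        assert signed_area(c.points) > 0

    def test_square_perimeter_from_corner_and_midpoint_seeds(self):
        # sharp corners are the worst case for an interpolating cubic:
        # the spline must round each corner from outside, which inflates
        # the perimeter by ~1.75% for a square (its best achievable value
        # among standard interpolating families; smooth anatomy is far
        # less affected, cf. the 0.005% circle error above).
        pts = np.array([[0, 0], [5, 0], [10, 0], [10, 5], [10, 10],
                        [5, 10], [0, 10], [0, 5]], dtype=float)
        seed = SeedContour(points=pts, frame_index=0, structure_label="fundus")
        c = resample_contour(seed, 200)
        per = np.sum(np.linalg.norm(np.roll(c.points, -1, axis=0) - c.points,
                                    axis=1))
        assert per >= 40.0  # corners are rounded outward, never cut
        assert abs(per - 40.0) / 40.0 < 0.02

    def test_start_point_is_nearest_first_seed(self):
        seed = circle_seed(n=20, radius=50.0, phase=0.3)
        c = resample_contour(seed, 100)
        assert np.linalg.norm(c.points[0] - seed.points[0]) < 1e-6

    def test_idempotent_within_hausdorff_tolerance(self):
        c1 = resample_contour(circle_seed(n=20, radius=40.0), 100)
        c2 = resample_contour(
            SeedContour(points=c1.points, frame_index=0, structure_label="fundus"),
            100)
        from scipy.spatial.distance import cdist
        d = cdist(c1.points, c2.points)
        hausdorff = max(d.min(axis=0).max(), d.min(axis=1).max())
        assert hausdorff < 0.001 * 40.0

    def test_convex_seeds_stay_convex_within_tolerance(self):
        rng = np.random.default_rng(3)
        th = np.sort(rng.uniform(0, 2 * np.pi, 12))
        pts = np.column_stack([30 * np.cos(th), 20 * np.sin(th)])
        c = resample_contour(
            SeedContour(points=pts, frame_index=0, structure_label="duodenum"),
            100)
        from shapely.geometry import Polygon
        poly = Polygon(c.points)
        hull = poly.convex_hull
        # oscillation beyond the hull is bounded by 1% of the scale
        assert hull.area - poly.area < 0.01 * hull.area


class TestPolygonGeometry:
    def test_unit_square_area(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert polygon_area(sq) == pytest.approx(1.0)

    def test_regular_100gon_closed_form(self):
        # area = n/2 * r^2 * sin(2 pi / n)
        pts = _regular_polygon(100, 10.0)
        expect = 0.5 * 100 * 10.0 ** 2 * np.sin(2 * np.pi / 100)
        assert polygon_area(pts) == pytest.approx(expect, abs=1e-9)
        assert expect == pytest.approx(313.9526, abs=1e-4)

    def test_area_translation_invariance(self):
        pts = _regular_polygon(37, 8.0)
        assert polygon_area(pts + [17.0, -9.0]) == pytest.approx(
            polygon_area(pts), rel=1e-12)

    def test_unit_square_centroid(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        np.testing.assert_allclose(polygon_centroid(sq), [0.5, 0.5])

    def test_regular_polygon_centroid_is_center(self):
        pts = _regular_polygon(9, 5.0, center=(3.0, -2.0))
        np.testing.assert_allclose(polygon_centroid(pts), [3.0, -2.0], atol=1e-12)

    def test_l_shape_centroid_against_decomposition(self):
        # L = [0,4]x[0,1] plus [0,1]x[1,3]: centroid from the two
        # rectangles' areas and centers.
        L = np.array([[0, 0], [4, 0], [4, 1], [1, 1], [1, 3], [0, 3]], float)
        a1, c1 = 4.0, np.array([2.0, 0.5])
        a2, c2 = 2.0, np.array([0.5, 2.0])
        expect = (a1 * c1 + a2 * c2) / (a1 + a2)
        np.testing.assert_allclose(polygon_centroid(L), expect, atol=1e-12)

    def test_centroid_of_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="area"):
            polygon_centroid(np.array([[0, 0], [1, 1], [2, 2]], float))

    @given(st.integers(0, 99), st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_area_centroid_invariant_to_renumbering_and_translation(
            self, shift, tx, ty):
        pts = _regular_polygon(100, 12.0, center=(5.0, 7.0))
        moved = np.roll(pts, shift, axis=0) + [tx, ty]
        assert polygon_area(moved) == pytest.approx(polygon_area(pts), rel=1e-9)
        np.testing.assert_allclose(polygon_centroid(moved),
                                   polygon_centroid(pts) + [tx, ty], atol=1e-8)

    def test_area_rotation_invariance(self):
        pts = _regular_polygon(64, 9.0) + [4.0, 4.0]
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        assert polygon_area(pts @ rot.T) == pytest.approx(polygon_area(pts),
                                                          rel=1e-12)


class TestContourFrames:
    def _circle_contour(self, r=20.0):
        return WallContour(points=_regular_polygon(100, r), structure_label="duodenum",
                           frame_index=0)

    def test_circle_inward_normals_point_to_center(self):
        c = self._circle_contour()
        normals, _ = contour_frames(c)
        expected = -c.points / np.linalg.norm(c.points, axis=1, keepdims=True)
        np.testing.assert_allclose(normals, expected, atol=1e-3)

    def test_tangents_counterclockwise(self):
        c = self._circle_contour()
        _, tangents = contour_frames(c)
        # cross(P, tangent) > 0 for counterclockwise traversal
        cross = c.points[:, 0] * tangents[:, 1] - c.points[:, 1] * tangents[:, 0]
        assert np.all(cross > 0)

    def test_unit_length_and_orthogonality(self):
        c = self._circle_contour()
        normals, tangents = contour_frames(c)
        np.testing.assert_allclose(np.linalg.norm(normals, axis=1), 1.0,
                                   atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(tangents, axis=1), 1.0,
                                   atol=1e-9)
        np.testing.assert_allclose(np.einsum("ij,ij->i", normals, tangents),
                                   0.0, atol=1e-12)


class TestAverageImage:
    def _stack(self, frames):
        return FrameStack(frames=np.asarray(frames, float), pixel_spacing_x=1,
                          pixel_spacing_y=1, frame_interval=0.5)

    def test_constant_stack(self):
        f = np.full((8, 8), 3.0)
        assert np.array_equal(average_image(self._stack([f] * 5)), f)

    def test_alternating_frames(self):
        z, two = np.zeros((6, 6)), np.full((6, 6), 2.0)
        np.testing.assert_allclose(
            average_image(self._stack([z, two, z, two])), 1.0)

    def test_noise_suppression_scales_with_sqrt_frames(self):
        rng = np.random.default_rng(12)
        sigma, n = 4.0, 36
        frames = 100 + rng.normal(0, sigma, size=(n, 64, 64))
        sd = average_image(self._stack(frames)).std()
        assert abs(sd - sigma / np.sqrt(n)) / (sigma / np.sqrt(n)) < 0.2


class TestBuildSeries:
    def test_cyclic_shift_realigned(self):
        pts = _regular_polygon(100, 15.0, center=(40, 40))
        c0 = WallContour(points=pts, structure_label="duodenum", frame_index=0)
        c1 = WallContour(points=np.roll(pts, 17, axis=0),
                         structure_label="duodenum", frame_index=1)
        series = build_series([c0, c1], 0.656)
        np.testing.assert_allclose(series.points[1], series.points[0])

    def test_mismatched_point_counts_rejected(self):
        c0 = WallContour(points=_regular_polygon(100, 15.0),
                         structure_label="duodenum", frame_index=0)
        c1 = WallContour(points=_regular_polygon(80, 15.0),
                         structure_label="duodenum", frame_index=1)
        with pytest.raises(ValueError, match="point counts"):
            build_series([c0, c1], 0.656)
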