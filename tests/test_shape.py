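"""Shape descriptors against analytic and brute-force oracles."""

import numpy as np
import pytest

from hcmotion.segment import Contour, ContourSeries, SeriesEntry, FLAG_OK
from hcmotion.shape import (
    polygon_second_moments,
    shape_descriptors,
    shape_series_stats,
)

from conftest import circle_contour, ellipse_contour


def rasterized_elongation(vertices: np.ndarray, resolution: int = 1200) -> float:
    """Brute-force elongation oracle: rasterize the polygon on a fine grid
    and take the pixel second-moment equivalent-ellipse diameter ratio."""
    from shapely import contains_xy
    from shapely.geometry import Polygon

    poly = Polygon(vertices)
    minx, miny, maxx, maxy = poly.bounds
    xs = np.linspace(minx, maxx, resolution)
    ys = np.linspace(miny, maxy, resolution)
    xx, yy = np.meshgrid(xs, ys)
    inside = contains_xy(poly, xx.ravel(), yy.ravel())
    px = np.column_stack([xx.ravel()[inside], yy.ravel()[inside]])
    cov = np.cov(px.T)
    lam = np.linalg.eigvalsh(cov)
    return float(np.sqrt(lam[1] / lam[0]))


class TestDescriptors:
    def test_circle_identities(self):
        rec = shape_descriptors(circle_contour(radius_um=10.0, n=360))
        assert rec.perimeter_um == pytest.approx(2 * np.pi * 10.0, rel=1e-3)
        assert rec.sphericity_pct == pytest.approx(100.0, abs=0.1)
        assert rec.elongation_ratio == pytest.approx(1.0, abs=0.01)

    def test_ellipse_elongation_is_axis_ratio(self):
        rec = shape_descriptors(ellipse_contour(20.0, 10.0))
        assert rec.elongation_ratio == pytest.approx(2.0, abs=0.01)

    def test_ellipse_perimeter_matches_dense_arc_length(self):
        # oracle: arc length of a 1e5-vertex polygonal approximation
        theta = np.linspace(0, 2 * np.pi, 100_000, endpoint=False)
        pts = np.column_stack([20 * np.cos(theta), 10 * np.sin(theta)])
        closed = np.vstack([pts, pts[:1]])
        oracle = np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1))
        rec = shape_descriptors(ellipse_contour(20.0, 10.0, n=2000))
        assert rec.perimeter_um == pytest.approx(oracle, rel=0.005)
        assert oracle == pytest.approx(96.88, abs=0.1)

    def test_square_sphericity(self):
        corners = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
        mids = (corners + np.roll(corners, -1, axis=0)) / 2
        verts = np.empty((8, 2))
        verts[0::2], verts[1::2] = corners, mids
        rec = shape_descriptors(Contour(0, verts))
        assert rec.sphericity_pct == pytest.approx(100 * np.pi / 4, abs=0.5)

    def test_degenerate_polygon_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 10), np.zeros(10)])
        with pytest.raises(ValueError):
            Contour(0, line)

    def test_isoperimetric_bound_and_rigid_invariance(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(8, 40)
            ang = np.sort(rng.uniform(0, 2 * np.pi, n))
            r = rng.uniform(5, 15)
            verts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
            rec = shape_descriptors(Contour(0, verts))
            assert rec.perimeter_um**2 >= 4 * np.pi * rec.area_um2 - 1e-9
            assert rec.sphericity_pct <= 100.0 + 1e-9
            # rigid motion: rotate + translate
            phi = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
            moved = verts @ R.T + rng.uniform(-50, 50, 2)
            rec2 = shape_descriptors(Contour(0, moved))
            assert rec2.perimeter_um == pytest.approx(rec.perimeter_um, rel=0.005)
            assert rec2.sphericity_pct == pytest.approx(rec.sphericity_pct, rel=0.005)
            assert rec2.elongation_ratio == pytest.approx(rec.elongation_ratio, rel=0.005)

    def test_sphericity_converges_to_100_with_vertex_density(self):
        values = [
            shape_descriptors(circle_contour(n=n)).sphericity_pct
            for n in (100, 1000, 10_000)
        ]
        assert values[0] < values[1] < values[2] <= 100.0
        assert values[2] == pytest.approx(100.0, abs=1e-3)

    def test_moments_elongation_matches_rasterized_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            # random convex polygon via convex hull of a point cloud
            from scipy.spatial import ConvexHull

            pts = rng.normal(0, 10, (30, 2)) * rng.uniform(0.5, 2, 2)
            hull = ConvexHull(pts)
            verts = pts[hull.vertices]
            if len(verts) < 8:
                continue
            ours = shape_descriptors(Contour(0, verts)).elongation_ratio
            oracle = rasterized_elongation(verts)
            assert ours == pytest.approx(oracle, rel=0.01)

    def test_second_moments_of_rectangle(self):
        # analytic: uniform rectangle w x h has µxx = w²/12, µyy = h²/12
        w, h = 12.0, 4.0
        corners = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)
        mids = (corners + np.roll(corners, -1, axis=0)) / 2
        verts = np.empty((8, 2))
        verts[0::2], verts[1::2] = corners, mids
        mom = polygon_second_moments(verts)
        assert mom[0, 0] == pytest.approx(w**2 / 12, rel=1e-9)
        assert mom[1, 1] == pytest.approx(h**2 / 12, rel=1e-9)
        assert mom[0, 1] == pytest.approx(0.0, abs=1e-9)


class TestScalingProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        scale=st.floats(0.1, 10.0),
        phi=st.floats(0.0, 2 * np.pi),
        a=st.floats(6.0, 25.0),
        b=st.floats(5.0, 20.0),
    )
    def test_similarity_transform_scaling(self, scale, phi, a, b):
        """Perimeter scales as s, area as s^2; sphericity and elongation are
        scale- and rotation-invariant."""
        base = ellipse_contour(max(a, b), min(a, b))
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        moved = Contour(0, (base.vertices @ R.T) * scale)
        r0, r1 = shape_descriptors(base), shape_descriptors(moved)
        assert r1.perimeter_um == pytest.approx(scale * r0.perimeter_um, rel=1e-6)
        assert r1.area_um2 == pytest.approx(scale**2 * r0.area_um2, rel=1e-6)
        assert r1.sphericity_pct == pytest.approx(r0.sphericity_pct, rel=1e-6)
        assert r1.elongation_ratio == pytest.approx(r0.elongation_ratio, rel=1e-6)


class TestSeriesStats:
    def _series(self, contours):
        return ContourSeries([SeriesEntry(c.frame, FLAG_OK, c) for c in contours])

    def test_rounding_frame_detected(self, small_dataset):
        series = self._series(small_dataset.truth_contours)
        _, rounding, _ = shape_series_stats(series)
        assert rounding is not None
        assert abs(rounding - small_dataset.config.rounding_frame) <= 1

    def test_rounding_frame_descriptors_are_circular(self, small_dataset):
        series = self._series(small_dataset.truth_contours)
        df, rounding, _ = shape_series_stats(series)
        row = df[df.frame == rounding].iloc[0]
        assert row.elongation_ratio == pytest.approx(1.0, abs=0.02)
        assert row.sphericity_pct == pytest.approx(100.0, abs=0.5)

    def test_constant_elongated_contour_reports_no_event(self):
        contours = [ellipse_contour(12.0, 6.0, frame=f) for f in range(6)]
        _, rounding, _ = shape_series_stats(self._series(contours))
        assert rounding is None

    def test_too_few_ok_frames_raises(self):
        contours = [circle_contour(frame=0), circle_contour(frame=1)]
        with pytest.raises(ValueError, match="3 ok frames"):
            shape_series_stats(self._series(contours))

    def test_summary_covers_min_max_mean(self, small_dataset):
        series = self._series(small_dataset.truth_contours)
        df, _, summary = shape_series_stats(series)
        assert set(summary.columns) == {"descriptor", "min", "max", "mean"}
        peri = summary[summary.descriptor == "perimeter_um"].iloc[0]
        assert peri["min"] <= peri["mean"] <= peri["max"]
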