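"""Gap filling, edge growing and boundary assembly tests."""

import numpy as np
import pytest

from conftest import circle_segment, simple_geometry
from vsmc3d.edge_blocking import block_edges, cast_ray_fan
from vsmc3d.edge_growing import (
    GapTooWideError,
    UnsegmentableSliceError,
    _cardinal_spline,
    bilateral_spline_interpolate,
    close_boundary,
    curvature_metrics,
    laplace_verify_pca,
    split_merged_edge,
)
from vsmc3d.preprocess import EdgeSegment


class TestCurvatureMetrics:
    def test_straight_line_has_zero_curvature(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10)])
        acc, avg = curvature_metrics(line)
        assert acc == pytest.approx(0.0, abs=1e-12)
        assert avg == pytest.approx(0.0, abs=1e-12)

    def test_dense_circle_approaches_analytic_limits(self):
        r = 20.0
        t = np.linspace(0, 2 * np.pi, 720)
        circle = np.column_stack([r * np.cos(t), r * np.sin(t)])
        acc, avg = curvature_metrics(circle)
        assert acc == pytest.approx(2 * np.pi, rel=0.01)
        assert avg == pytest.approx(1 / r, rel=0.01)

    def test_reversal_invariance(self, rng):
        pts = np.cumsum(rng.normal(0, 1, (30, 2)), axis=0)
        assert curvature_metrics(pts) == pytest.approx(
            curvature_metrics(pts[::-1]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            curvature_metrics(np.zeros((2, 2)))


class TestCardinalSpline:
    def test_passes_through_control_points(self, rng):
        control = np.cumsum(rng.normal(0, 3, (8, 2)), axis=0)
        curve = _cardinal_spline(control, samples_per_span=4)
        for p in control:
            assert np.linalg.norm(curve - p, axis=1).min() < 1e-9


class TestBilateralSpline:
    def _collinear_pair(self):
        e1 = EdgeSegment(points=np.column_stack(
            [np.arange(0.0, 20.0), np.zeros(20)]), segment_id=0)
        e2 = EdgeSegment(points=np.column_stack(
            [np.arange(30.0, 50.0), np.zeros(20)]), segment_id=1)
        return e1, e2

    def test_straight_gap_gets_straight_bridge(self):
        e1, e2 = self._collinear_pair()
        fill = bilateral_spline_interpolate(e1, e2, center=(25.0, -40.0))
        assert np.abs(fill.fill_points[:, 1]).max() < 1e-6
        accs = [m["acc_curv"] for m in fill.metrics.values()]
        assert max(accs) < 1e-6

    def test_mirror_symmetric_directions_agree(self):
        t = np.linspace(0, 1, 15)
        e1 = EdgeSegment(points=np.column_stack(
            [-30 + 20 * t, 5 * t**2]), segment_id=0)
        e2 = EdgeSegment(points=np.column_stack(
            [10 + 20 * t, 5 * (1 - t) ** 2]), segment_id=1)
        fill = bilateral_spline_interpolate(e1, e2, center=(0.0, -30.0))
        m = fill.metrics
        assert m["acc_12"]["sd"] == pytest.approx(m["acc_21"]["sd"],
                                                  rel=1e-6)

    def test_junction_matches_bruteforce_scan(self, rng):
        """Selected junction equals exhaustive minimization."""
        t = np.linspace(0, 1, 12)
        e1 = EdgeSegment(points=np.column_stack(
            [t * 15.0, np.sin(t * 2) * 3]), segment_id=0)
        e2 = EdgeSegment(points=np.column_stack(
            [25 + t * 15.0, 4 - 3 * t + rng.normal(0, 0.4, len(t))]),
            segment_id=1)
        fill = bilateral_spline_interpolate(e1, e2, center=(20.0, -25.0))

        p1, p2 = e1.points, e2.points
        direction = fill.option.split("_")[1]
        metric = fill.option.split("_")[0]
        if direction == "21":
            p1, p2 = p2[::-1], p1[::-1]
        best_j, best_val = None, np.inf
        for j in range(0, len(p2) - 1):
            curve = _cardinal_spline(np.vstack([p1, p2[j:]]), 5)
            acc, avg = curvature_metrics(curve)
            val = acc if metric == "acc" else avg
            if val < best_val - 1e-12:
                best_val, best_j = val, j
        assert fill.junction_index == best_j

    def test_selected_option_has_minimal_sd(self, rng):
        t = np.linspace(0, 1, 10)
        e1 = EdgeSegment(points=np.column_stack(
            [t * 12, rng.normal(0, 0.5, len(t))]), segment_id=0)
        e2 = EdgeSegment(points=np.column_stack(
            [20 + t * 12, 3 + rng.normal(0, 0.5, len(t))]),
            segment_id=1)
        fill = bilateral_spline_interpolate(e1, e2, center=(16.0, -20.0))
        sds = {k: v["sd"] for k, v in fill.metrics.items()}
        assert sds[fill.option] == pytest.approx(min(sds.values()))

    def test_too_wide_gap_rejected(self):
        e1 = EdgeSegment(points=np.column_stack(
            [np.arange(10.0), np.zeros(10)]))
        e2 = EdgeSegment(points=np.column_stack(
            [np.arange(500.0, 510.0), np.zeros(10)]))
        with pytest.raises(GapTooWideError):
            bilateral_spline_interpolate(e1, e2, lc0=30.0,
                                         max_gap_span_factor=4.0)


class TestLaplacePCA:
    def test_straight_step_edge_recovered(self):
        # bright region left of x = 60: rays cross the step
        img = np.zeros((96, 96))
        img[:, :60] = 1.0
        geom = simple_geometry(center=(40.0, 48.0), vector=(0.0, 1.0))
        rays = cast_ray_fan(geom, angular_step=1.0, symmetric=True,
                            segments=[])
        sector = [r for r in rays
                  if not r.extended and 60 <= r.theta <= 120]
        nucleus = np.zeros((96, 96), bool)
        nucleus[44:52, 36:44] = True
        grown = laplace_verify_pca(img, sector, nucleus, None,
                                   window=7)
        assert grown is not None
        err = grown.points[:, 0] - 60.0
        assert np.sqrt(np.mean(err**2)) <= 1.5

    def test_collinear_candidates_give_exact_direction(self):
        pts = np.column_stack([np.full(12, 30.0),
                               np.arange(20.0, 32.0)])
        cov = np.cov((pts - pts.mean(axis=0)).T)
        evals, evecs = np.linalg.eigh(cov)
        v1 = evecs[:, -1]
        assert abs(v1[1]) == pytest.approx(1.0)

    def test_no_candidates_reports_failure(self):
        img = np.ones((64, 64))  # no gradients anywhere
        geom = simple_geometry(center=(32.0, 32.0))
        rays = cast_ray_fan(geom, segments=[])
        nucleus = np.zeros((64, 64), bool)
        assert laplace_verify_pca(img, rays[:10], nucleus, None) is None


class TestSplitMergedEdge:
    def _geoms(self):
        a = simple_geometry(center=(20.0, 40.0), vector=(0.0, 1.0))
        b = simple_geometry(center=(60.0, 40.0), vector=(0.0, 1.0))
        return a, b

    def test_symmetric_edge_splits_at_midpoint(self):
        # two tails pointing at each other, merged edge sagging toward
        # the line between the cell axes
        a = simple_geometry(center=(20.0, 40.0), vector=(1.0, 0.0))
        b = simple_geometry(center=(60.0, 40.0), vector=(-1.0, 0.0))
        t = np.linspace(0.0, 1.0, 21)
        edge = EdgeSegment(points=np.column_stack(
            [20.0 + 40.0 * t, 70.0 - 6.0 * np.sin(np.pi * t)]),
            edge_class="C")
        sa, sb = split_merged_edge(edge, a, b)
        assert len(sa) == pytest.approx(len(sb), abs=1)

    def test_concatenation_reproduces_input(self):
        a, b = self._geoms()
        pts = np.column_stack([np.linspace(20.0, 60.0, 21),
                               70.0 + np.sin(np.linspace(0, 3, 21))])
        edge = EdgeSegment(points=pts, edge_class="C")
        sa, sb = split_merged_edge(edge, a, b)
        np.testing.assert_array_equal(np.vstack([sa.points, sb.points]),
                                      pts)

    def test_split_point_matches_bruteforce_distance_scan(self):
        a, b = self._geoms()
        rng = np.random.default_rng(3)
        pts = np.column_stack([np.linspace(22.0, 58.0, 25),
                               68.0 + rng.normal(0, 1.5, 25)])
        edge = EdgeSegment(points=pts, edge_class="C")
        sa, _sb = split_merged_edge(edge, a, b)
        f = len(sa) - 1

        def foot(point, geom):
            v = geom.cell_vector
            return geom.center + ((point - geom.center) @ v) * v
        B = foot(pts[0], a)
        D = foot(pts[-1], b)
        u = (D - B) / np.linalg.norm(D - B)
        rel = pts - B
        dists = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
        expected = int(np.argmin(dists))
        expected = min(max(expected, 1), len(pts) - 2)
        assert f == expected

    def test_non_class_c_rejected(self):
        a, b = self._geoms()
        edge = EdgeSegment(points=np.zeros((5, 2)), edge_class="A")
        with pytest.raises(ValueError):
            split_merged_edge(edge, a, b)


class TestCloseBoundary:
    def test_no_gaps_returns_retained_contour_verbatim(self):
        geom = simple_geometry()
        contour = circle_segment(radius=15.0, segment_id=0)
        rays = cast_ray_fan(geom, symmetric=True, segments=[])
        blocking = block_edges(rays, [contour])
        boundary = close_boundary(blocking, [], center=geom.center)
        assert len(boundary.contour) == len(contour.points)
        got = {tuple(np.round(p, 6)) for p in boundary.contour}
        want = {tuple(np.round(p, 6)) for p in contour.points}
        assert got == want

    def test_filled_gap_restores_area(self):
        geom = simple_geometry()
        arc = circle_segment(radius=15.0, theta0=12.0, theta1=358.0,
                             n=330, segment_id=0)
        arc.edge_class = "A"
        rays = cast_ray_fan(geom, symmetric=True, segments=[])
        blocking = block_edges(rays, [arc])
        fills = []
        for gap in blocking.gaps:
            fills.append(bilateral_spline_interpolate(
                arc, arc, center=geom.center))
        boundary = close_boundary(blocking, fills, center=geom.center)
        assert boundary.area == pytest.approx(np.pi * 15**2, rel=0.02)

    def test_winding_is_always_clockwise(self):
        geom = simple_geometry()
        for flip in (False, True):
            contour = circle_segment(radius=12.0, segment_id=0)
            if flip:
                contour.points = contour.points[::-1].copy()
            rays = cast_ray_fan(geom, symmetric=True, segments=[])
            blocking = block_edges(rays, [contour])
            b = close_boundary(blocking, [], center=geom.center)
            x, y = b.contour[:, 0], b.contour[:, 1]
            signed = np.dot(x, np.roll(y, -1)) - np.dot(y,
                                                        np.roll(x, -1))
            assert signed < 0

    def test_boundary_encloses_center(self):
        geom = simple_geometry()
        contour = circle_segment(radius=10.0, segment_id=0)
        rays = cast_ray_fan(geom, symmetric=True, segments=[])
        blocking = block_edges(rays, [contour])
        b = close_boundary(blocking, [], center=geom.center)
        assert b.contains(geom.center)

    def test_huge_unfilled_gap_flags_slice(self):
        geom = simple_geometry()
        arc = circle_segment(radius=15.0, theta0=0.0, theta1=90.0,
                             n=90, segment_id=0)
        rays = cast_ray_fan(geom, symmetric=True, segments=[])
        blocking = block_edges(rays, [arc])
        with pytest.raises(UnsegmentableSliceError):
            close_boundary(blocking, [], center=geom.center,
                           max_gap_angle_deg=90.0)
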