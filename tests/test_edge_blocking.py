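"""Ray-fan construction and edge-blocking tests, with an exhaustive
ray-by-segment intersection oracle."""

import numpy as np
import pytest

from conftest import circle_segment, simple_geometry
from vsmc3d.edge_blocking import (
    block_edges,
    cast_ray_fan,
    ray_angle,
    ray_length_bound,
)
from vsmc3d.preprocess import EdgeSegment


class TestRayAngle:
    def test_point_along_cell_vector_is_zero(self):
        assert ray_angle((48, 58), (48, 48), (0, 1)) == pytest.approx(0.0)

    def test_point_against_cell_vector_is_180(self):
        assert ray_angle((48, 38), (48, 48), (0, 1)) == pytest.approx(
            180.0)

    def test_quarter_turn_example(self):
        # cell vector +Y, point on +X: the wrap yields 90 degrees
        assert ray_angle((1, 0), (0, 0), (0, 1)) == pytest.approx(90.0)

    def test_independent_angle_oracle(self, rng):
        """Angle difference computed with complex arguments agrees."""
        center = np.array([10.0, -3.0])
        vec = np.array([0.6, 0.8])
        for _ in range(50):
            p = center + rng.normal(0, 20, 2)
            if np.allclose(p, center):
                continue
            expected = np.degrees(
                (np.angle(vec[0] + 1j * vec[1])
                 - np.angle((p - center)[0] + 1j * (p - center)[1]))
                % (2 * np.pi)) % 360.0
            assert ray_angle(p, center, vec) == pytest.approx(
                expected, abs=1e-9)

    def test_coincident_point_rejected(self):
        with pytest.raises(ValueError):
            ray_angle((5, 5), (5, 5), (0, 1))


class TestRayLengthBound:
    def test_perpendicular_literal_value(self):
        assert ray_length_bound(90.0, clamp=False) == pytest.approx(30.0)

    def test_opposite_direction_clamps_to_minimum(self):
        assert ray_length_bound(180.0, clamp=False) == pytest.approx(
            -120.0)
        assert ray_length_bound(180.0, clamp=True) == pytest.approx(5.0)

    def test_symmetric_form_reaches_both_tails(self):
        assert ray_length_bound(180.0, symmetric=True) == \
            ray_length_bound(0.0, symmetric=True)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ray_length_bound(0.0, lc0=-1.0)


class TestCastRayFan:
    def test_one_degree_step_gives_360_center_rays(self):
        rays = cast_ray_fan(simple_geometry(), angular_step=1.0,
                            segments=[])
        center = [r for r in rays if not r.extended]
        assert len(center) == 360

    def test_extended_rays_cover_both_tail_sectors(self):
        rays = cast_ray_fan(simple_geometry(), angular_step=1.0)
        ext = [r for r in rays if r.extended]
        assert ext
        thetas = np.array([r.theta for r in ext])
        near0 = (np.minimum(thetas, 360 - thetas) <= 30.0 + 1e-9)
        near180 = (np.abs(thetas - 180.0) <= 30.0 + 1e-9)
        assert near0.any() and near180.any()
        origins = {tuple(r.origin) for r in ext}
        assert len(origins) == 2

    def test_far_tail_hit_only_by_extended_rays(self):
        # a short edge beyond every center-ray bound, on the cell axis
        geom = simple_geometry(center=(48.0, 48.0), vector=(0.0, 1.0),
                               half=12.0)
        tail_edge = EdgeSegment(points=np.column_stack(
            [np.arange(44.0, 53.0), np.full(9, 48.0 + 20.0 + 170.0)]),
            segment_id=0)
        rays = cast_ray_fan(geom, angular_step=1.0, lc0=30, lc1=5)
        result = block_edges(rays, [tail_edge])
        ext_hits = [h for h in result.hits
                    if rays[h.ray_index].extended]
        center_hits = [h for h in result.hits
                       if not rays[h.ray_index].extended]
        assert ext_hits and not center_hits

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            cast_ray_fan(simple_geometry(), angular_step=0.0)


class TestBlockEdges:
    def test_closed_convex_contour_fully_retained_no_gaps(self):
        geom = simple_geometry()
        contour = circle_segment(radius=15.0, segment_id=0)
        contour.edge_class = "A"
        rays = cast_ray_fan(geom, symmetric=True, segments=[])
        result = block_edges(rays, [contour])
        assert result.retained == [0]
        assert result.gaps == []
        assert (result.first_hit_segment == 0).all()

    def test_outer_concentric_contour_blocked(self):
        geom = simple_geometry()
        inner = circle_segment(radius=10.0, segment_id=0)
        outer = circle_segment(radius=20.0, segment_id=1)
        rays = cast_ray_fan(geom, segments=[])
        result = block_edges(rays, [inner, outer])
        assert result.retained == [0]
        assert result.blocked == [1]

    def test_gap_typing_follows_flank_classes(self):
        geom = simple_geometry()
        left = circle_segment(radius=15.0, theta0=120.0, theta1=350.0,
                              segment_id=0)
        right = circle_segment(radius=15.0, theta0=10.0, theta1=100.0,
                               segment_id=1)
        for cls, expected in (("A", "I"), ("B", "II")):
            left.edge_class = "A"
            right.edge_class = cls
            rays = cast_ray_fan(geom, segments=[])
            result = block_edges(rays, [left, right])
            assert result.gaps
            assert any(g.gap_type == expected for g in result.gaps)

    def test_empty_segment_list_is_all_gap(self):
        rays = cast_ray_fan(simple_geometry(), segments=[])
        result = block_edges(rays, [])
        assert result.retained == []
        assert len(result.gaps) == 1
        assert result.gaps[0].span_deg > 350.0

    def _random_segments(self, rng, n):
        segs = []
        for i in range(n):
            p0 = rng.uniform(10, 86, 2)
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            length = rng.uniform(3, 12)
            steps = np.linspace(0, length, max(int(length), 2))
            segs.append(EdgeSegment(points=p0 + steps[:, None]
                                    * direction, segment_id=i))
        return segs

    def test_matches_exhaustive_intersection_oracle(self, rng):
        """Retained/blocked sets equal a brute-force recomputation."""
        geom = simple_geometry(center=(48.0, 48.0), vector=(0.6, 0.8))
        for trial in range(3):
            segs = self._random_segments(rng, 50)
            rays = cast_ray_fan(geom, angular_step=1.0, segments=None)
            result = block_edges(rays, segs)

            def seg_min_dist(ray, seg):
                best = np.inf
                pts = seg.points
                for a, b in zip(pts[:-1], pts[1:]):
                    e = b - a
                    denom = (ray.direction[0] * e[1]
                             - ray.direction[1] * e[0])
                    if abs(denom) < 1e-12:
                        continue
                    ao = a - ray.origin
                    t = (ao[0] * e[1] - ao[1] * e[0]) / denom
                    s = (ao[0] * ray.direction[1]
                         - ao[1] * ray.direction[0]) / denom
                    if 1e-9 < t <= ray.l and -1e-9 <= s <= 1 + 1e-9:
                        best = min(best, t)
                return best

            rank1 = set()
            hit_any = set()
            for ray in rays:
                dists = {s.segment_id: seg_min_dist(ray, s)
                         for s in segs}
                dists = {k: v for k, v in dists.items()
                         if np.isfinite(v)}
                hit_any |= set(dists)
                if dists:
                    best = min(dists.items(),
                               key=lambda kv: (kv[1], kv[0]))
                    rank1.add(best[0])
            assert set(result.retained) == rank1
            assert set(result.blocked) == hit_any - rank1

    def test_order_independence(self, rng):
        geom = simple_geometry()
        segs = self._random_segments(rng, 30)
        rays = cast_ray_fan(geom, segments=None)
        ref = block_edges(rays, segs)
        perm = [segs[i] for i in rng.permutation(len(segs))]
        out = block_edges(rays, perm)
        assert out.retained == ref.retained
        assert out.blocked == ref.blocked
        np.testing.assert_array_equal(out.first_hit_segment,
                                      ref.first_hit_segment)

    def test_removing_blocked_segment_leaves_retained_unchanged(self,
                                                                rng):
        geom = simple_geometry()
        segs = self._random_segments(rng, 40)
        rays = cast_ray_fan(geom, segments=None)
        ref = block_edges(rays, segs)
        if not ref.blocked:
            pytest.skip("no blocked segment in this draw")
        keep = [s for s in segs if s.segment_id != ref.blocked[0]]
        out = block_edges(rays, keep)
        assert out.retained == ref.retained
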