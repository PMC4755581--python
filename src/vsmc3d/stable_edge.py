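"""Stable edges: track a cell's boundary across neighboring z-slices.

An edge point's overlap with a seed edge from another slice is
``O = 1 - min_distance / w`` (1 when the point lies on the seed, 0 at
the window width w, negative beyond it — deliberately unclamped so the
average stays informative).  The stability of a point is the mean of O
over the M neighboring seed slices; per ray line the maximal-O point is
a stable point, and an edge whose stable-point ratio exceeds the
threshold (30 % by default) is accepted as the same physical edge seen
on the next slice.  Edges failing the test are treated as unstable
noise and the gap-filling machinery takes over.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import PipelineConfig
from .edge_blocking import block_edges, cast_ray_fan
from .edge_growing import (
    Boundary2D,
    GapTooWideError,
    UnsegmentableSliceError,
    bilateral_spline_interpolate,
    close_boundary,
)
from .geometry import scattering_angle_deg
from .preprocess import EdgeSegment, NucleusGeometry


@dataclass
class FallbackRequest:
    """Raised state: the tracker cannot continue without outside help.

    Mirrors the semi-automatic workflow where a user supplies an initial
    slice or key edges when automatic propagation fails.
    """

    reason: str
    slice_index: int = -1


@dataclass
class StabilityScore:
    """Per-edge stability summary (overlap O, stability S)."""

    S: float                      # mean stability over the edge
    per_point: np.ndarray         # S_i per candidate point
    stable_mask: np.ndarray       # per-point stable-point flags
    stable_ratio: float
    is_stable: bool
    w: float
    M: int


def point_overlap(e_i, seed_edge, w: float):
    """Overlap O = 1 - min distance / w of point(s) with a seed edge.

    ``e_i`` may be one (x, y) point or an (N, 2) array; ``seed_edge``
    an EdgeSegment or point array.  O is 1 exactly when the minimal
    Euclidean distance is 0 and goes negative beyond the window width.
    """
    if w <= 0:
        raise ValueError("window width must be positive")
    seed = seed_edge.points if isinstance(seed_edge, EdgeSegment) \
        else np.atleast_2d(np.asarray(seed_edge, float))
    if len(seed) == 0:
        raise ValueError("empty seed edge")
    pts = np.asarray(e_i, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    d, _ = cKDTree(seed).query(pts)
    out = 1.0 - d / w
    return float(out[0]) if scalar else out


def edge_stability(edge, seed_edges, w: float = 5.0, M: int = None,
                   center=None, cell_vector=(0.0, 1.0),
                   ratio_threshold: float = 0.30,
                   angular_bin_deg: float = 1.0) -> StabilityScore:
    """Stability of an edge against seed edges from M neighboring slices.

    Per candidate point the overlap O is averaged over the M seeds; per
    ray line (angular bin around ``center``) the maximal-O point is a
    stable point when its averaged overlap is positive.  The edge is
    stable when the fraction of its ray bins holding a stable point
    exceeds ``ratio_threshold``; otherwise it is unstable noise.
    Without a center every point is its own ray line.
    """
    pts = edge.points if isinstance(edge, EdgeSegment) \
        else np.atleast_2d(np.asarray(edge, float))
    seed_edges = list(seed_edges)
    if M is None:
        M = len(seed_edges)
    if M < 1 or not seed_edges:
        raise ValueError("at least one seed slice is required")
    seed_edges = seed_edges[-M:]
    M = len(seed_edges)

    O = np.zeros((M, len(pts)))
    for j, seed in enumerate(seed_edges):
        O[j] = point_overlap(pts, seed, w)
    S_i = O.mean(axis=0)

    if center is None:
        bins = np.arange(len(pts))
    else:
        center = np.asarray(center, float)
        ok = ~np.all(np.isclose(pts, center), axis=1)
        theta = np.zeros(len(pts))
        if ok.any():
            theta[ok] = scattering_angle_deg(pts[ok], center, cell_vector)
        bins = np.floor(theta / angular_bin_deg).astype(int)

    stable_mask = np.zeros(len(pts), dtype=bool)
    n_bins = 0
    n_stable_bins = 0
    for b in np.unique(bins):
        sel = np.nonzero(bins == b)[0]
        n_bins += 1
        k = sel[int(np.argmax(S_i[sel]))]
        if S_i[k] > 0:
            stable_mask[k] = True
            n_stable_bins += 1
    ratio = n_stable_bins / n_bins if n_bins else 0.0
    return StabilityScore(S=float(S_i.mean()), per_point=S_i,
                          stable_mask=stable_mask,
                          stable_ratio=float(ratio),
                          is_stable=bool(ratio > ratio_threshold),
                          w=float(w), M=M)


def _displacement_cap(boundary: Boundary2D, prev: Boundary2D,
                      cap: float) -> Boundary2D:
    """Clip boundary points drifting farther than ``cap`` from the
    previous slice's contour (no abrupt position changes)."""
    tree = cKDTree(prev.contour)
    d, idx = tree.query(boundary.contour)
    over = d > cap
    if not over.any():
        return boundary
    contour = boundary.contour.copy()
    nearest = prev.contour[idx[over]]
    vec = contour[over] - nearest
    norms = np.linalg.norm(vec, axis=1, keepdims=True)
    contour[over] = nearest + vec / np.maximum(norms, 1e-12) * cap
    capped = Boundary2D(contour=contour,
                        provenance=list(boundary.provenance),
                        center=boundary.center)
    poly = capped.polygon()
    if poly.is_valid and poly.is_simple:
        return capped
    # clipping can fold the loop; take the cleaned-up largest ring
    repaired = poly.buffer(0)
    best = None
    for g in getattr(repaired, "geoms", [repaired]):
        if g.geom_type == "Polygon" and not g.is_empty:
            if best is None or g.area > best.area:
                best = g
    if best is None:
        return boundary
    pts = np.asarray(best.exterior.coords[:-1], float)
    return Boundary2D(contour=pts, provenance=["edge"] * len(pts),
                      center=boundary.center)


def propagate_boundary(prev, slice_segments, geometry: NucleusGeometry,
                       config: PipelineConfig = None, fills_hook=None):
    """Carry the accepted boundary onto the next slice.

    ``prev`` is the previous slice's Boundary2D or a list of recent ones
    (newest last) used as stability seeds.  Segments of the current
    slice passing the stability test are blocked and linked as usual;
    gaps are bridged by bilateral spline interpolation (``fills_hook``
    may supply extra fills, e.g. Laplace-PCA grown edges).  Returns the
    new Boundary2D, or a FallbackRequest when no stable boundary can be
    assembled.
    """
    config = config or PipelineConfig()
    prev_list = list(prev) if isinstance(prev, (list, tuple)) else [prev]
    if not prev_list:
        raise ValueError("at least one previous boundary is required")
    seeds = [b.contour for b in prev_list[-config.stable_slices:]]

    stable_segments = []
    for seg in slice_segments:
        score = edge_stability(
            seg, seeds, w=config.stable_window_px,
            center=geometry.center, cell_vector=geometry.cell_vector,
            ratio_threshold=config.stability_threshold,
            angular_bin_deg=config.angular_step_deg)
        if score.is_stable:
            stable_segments.append(seg)
    if not stable_segments:
        return FallbackRequest(reason="no stable segments on this slice")

    rays = cast_ray_fan(
        geometry, angular_step=config.angular_step_deg, lc0=config.lc0,
        lc1=config.lc1, clamp=config.clamp_ray_length,
        symmetric=config.ray_bound_symmetric,
        segments=stable_segments,
        tail_half_angle_deg=config.tail_half_angle_deg,
        parallel_tol_deg=config.extended_ray_parallel_tol_deg)
    blocking = block_edges(rays, stable_segments,
                           gap_min_run=config.gap_min_run)
    if not blocking.retained:
        return FallbackRequest(reason="all stable segments blocked")

    by_id = {s.segment_id: s for s in blocking.segments}
    fills = []
    for gap in blocking.gaps:
        fill = fills_hook(blocking, gap) if fills_hook else None
        if fill is None:
            e1 = by_id.get(gap.left_segment)
            e2 = by_id.get(gap.right_segment)
            if e1 is None or e2 is None:
                continue
            try:
                fill = bilateral_spline_interpolate(
                    e1, e2, center=geometry.center, lc0=config.lc0,
                    max_gap_span_factor=config.max_gap_span_factor,
                    max_junctions=12)
            except (GapTooWideError, ValueError):
                continue
            fill.gap_type = gap.gap_type
        fills.append(fill)

    try:
        boundary = close_boundary(
            blocking, fills, center=geometry.center,
            max_gap_angle_deg=config.max_gap_angle_deg,
            smooth_window=config.contour_smooth_window)
    except UnsegmentableSliceError as err:
        return FallbackRequest(reason=str(err))
    return _displacement_cap(boundary, prev_list[-1],
                             config.displacement_cap_px)
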