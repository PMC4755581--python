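"""Ray-fan edge blocking: keep first intersections, find and type gaps.

Rays are emitted from the cell center (the nucleus centroid) at a uniform
angular step; the scattering angle theta of a ray is measured clockwise
from the cell's orientation vector, and its emitting length is bounded
anisotropically — longest along the cell axis, shortest across it — so
that edges of far-away cells are never even reachable.  Per ray only the
nearest edge intersection survives ("blocking"); edge segments that are
never nearest anywhere are attributed to other cells or noise and
dropped.  Angular runs of rays with no hit are boundary gaps: Type I
between broken edges of the same cell, Type II where another cell
overlaps or adheres.  Slender cells additionally get extended rays from
the two nucleus-skeleton endpoints so that the tapering tails, nearly
parallel to center rays, are still sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import scattering_angle_deg
from .preprocess import NucleusGeometry


@dataclass
class Ray:
    """One ray of the fan."""

    origin: np.ndarray        # (x, y)
    theta: float              # scattering angle, degrees in [0, 360)
    l: float                  # emitting-length bound, px
    direction: np.ndarray     # unit (dx, dy)
    extended: bool = False    # emitted from a skeleton endpoint
    index: int = -1

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if not (0.0 <= self.theta < 360.0):
            raise ValueError("theta must lie in [0, 360)")
        if self.l <= 0:
            raise ValueError("emitting length must be positive")


@dataclass
class Hit:
    ray_index: int
    distance: float
    segment_id: int
    rank: int
    point: np.ndarray


@dataclass
class Gap:
    """A maximal angular run of hitless center rays."""

    theta_start: float
    theta_end: float
    gap_type: str = "II"              # "I" or "II"
    left_segment: int = -1            # retained segment before the gap
    right_segment: int = -1           # retained segment after the gap
    left_point: np.ndarray = None     # their adjoining hit points
    right_point: np.ndarray = None

    @property
    def span_deg(self) -> float:
        return (self.theta_end - self.theta_start) % 360.0


@dataclass
class BlockingResult:
    rays: list
    segments: list
    hits: list                        # Hit records with rank <= 2
    retained: list                    # segment ids with a rank-1 hit
    blocked: list                     # hit somewhere, never at rank 1
    unhit: list                       # never intersected by any ray
    gaps: list
    theta_grid: np.ndarray            # center-ray thetas in fan order
    first_hit_segment: np.ndarray     # per center ray, seg id or -1
    first_hit_distance: np.ndarray
    first_hit_point: np.ndarray       # (n, 2), nan where no hit

    def retained_segments(self) -> list:
        by_id = {s.segment_id: s for s in self.segments}
        return [by_id[i] for i in self.retained]


# ---------------------------------------------------------------------------
# ray construction
# ---------------------------------------------------------------------------

def ray_angle(point, center, cell_vector) -> float:
    """Scattering angle of a point seen from the center, degrees [0, 360).

    Defined as the cell vector's direction angle minus the direction
    angle of (point - center), wrapped modulo 2*pi.
    """
    out = scattering_angle_deg(np.atleast_2d(point), center, cell_vector)
    return float(out[0])


def ray_length_bound(theta, lc0: float = 30.0, lc1: float = 5.0,
                     clamp: bool = True, symmetric: bool = False):
    """Anisotropic emitting-length bound l = lc0 * (1 + lc1 cos theta).

    The bound is largest along the cell vector (theta = 0) and smallest
    across it.  The literal formula goes negative near theta = 180 when
    lc1 > 1, while lc1 and lc0 are the minimal and maximal emitting
    lengths; with ``clamp`` (the default) the value is clamped into
    [lc1, lc0 * (1 + lc1)].  ``clamp=False`` keeps the literal formula
    for fidelity experiments.  ``symmetric`` replaces cos theta by its
    absolute value so both tails of a fusiform cell — which is symmetric
    about its center — are equally reachable; the full pipeline uses
    this form.
    """
    if lc0 <= 0 or lc1 <= 0:
        raise ValueError("length bounds must be positive")
    theta = np.asarray(theta, dtype=float)
    c = np.cos(np.radians(theta))
    if symmetric:
        c = np.abs(c)
    l = lc0 * (1.0 + lc1 * c)
    if clamp:
        l = np.clip(l, lc1, lc0 * (1.0 + lc1))
    if l.ndim == 0:
        return float(l)
    return l


def _direction(cell_vector, theta_deg):
    phi = np.arctan2(cell_vector[1], cell_vector[0])
    ang = phi - np.radians(theta_deg)
    return np.stack([np.cos(ang), np.sin(ang)], axis=-1)


def _axis_offset(theta):
    """Angular distance of theta from the cell axis (0 or 180 deg)."""
    theta = np.asarray(theta, dtype=float) % 360.0
    return np.minimum(np.minimum(theta, 360.0 - theta),
                      np.abs(theta - 180.0))


def _tail_parallel_trigger(geometry, segments, dirs, thetas,
                           tail_half_angle_deg, parallel_tol_deg):
    """True if a tail-sector ray runs nearly parallel to a tail edge."""
    tail_limit = 90.0 - tail_half_angle_deg
    tail_dirs = dirs[_axis_offset(thetas) <= tail_limit]
    if len(tail_dirs) == 0:
        return False
    for seg in segments:
        pts = seg.points
        if len(pts) < 2:
            continue
        mids = 0.5 * (pts[:-1] + pts[1:])
        ok = ~np.all(np.isclose(mids, geometry.center), axis=1)
        if not ok.any():
            continue
        th = scattering_angle_deg(mids[ok], geometry.center,
                                  geometry.cell_vector)
        sel = _axis_offset(th) <= tail_limit
        if not sel.any():
            continue
        chords = np.diff(pts, axis=0)[ok][sel]
        norms = np.linalg.norm(chords, axis=1)
        chords = chords[norms > 0] / norms[norms > 0, None]
        if len(chords) == 0:
            continue
        cosang = np.abs(tail_dirs @ chords.T)
        if (cosang >= np.cos(np.radians(parallel_tol_deg))).any():
            return True
    return False


def cast_ray_fan(geometry: NucleusGeometry, angular_step: float = 1.0,
                 lc0: float = 30.0, lc1: float = 5.0, clamp: bool = True,
                 symmetric: bool = False, segments=None,
                 tail_half_angle_deg: float = 60.0,
                 parallel_tol_deg: float = 15.0) -> list:
    """Uniform center-ray fan, plus extended rays from skeleton endpoints.

    Center rays cover [0, 360) at ``angular_step`` from the cell center.
    When a tail-sector ray runs within ``parallel_tol_deg`` of parallel
    to a local tail edge direction (always assumed if ``segments`` is
    None), extended rays covering the tail sectors are emitted from each
    skeleton endpoint to increase the scattering area there.
    """
    if angular_step <= 0:
        raise ValueError("angular_step must be positive")
    thetas = np.arange(0.0, 360.0, angular_step)
    dirs = _direction(geometry.cell_vector, thetas)
    bounds = ray_length_bound(thetas, lc0, lc1, clamp, symmetric)
    rays = [Ray(origin=geometry.center, theta=float(t), l=float(b),
                direction=d, extended=False, index=i)
            for i, (t, b, d) in enumerate(zip(thetas, bounds, dirs))]

    emit_extended = (segments is None or _tail_parallel_trigger(
        geometry, segments, dirs, thetas, tail_half_angle_deg,
        parallel_tol_deg))
    if emit_extended:
        half = 90.0 - tail_half_angle_deg
        tail_thetas = np.arange(-half, half + 1e-9, angular_step)
        idx = len(rays)
        for endpoint in geometry.endpoints:
            towards = (np.asarray(endpoint, float) - geometry.center) \
                @ geometry.cell_vector
            offset = 0.0 if towards >= 0 else 180.0
            for t in np.sort((tail_thetas + offset) % 360.0):
                b = float(ray_length_bound(t, lc0, lc1, clamp,
                                           symmetric))
                rays.append(Ray(origin=np.asarray(endpoint, float),
                                theta=float(t), l=b,
                                direction=_direction(
                                    geometry.cell_vector, t),
                                extended=True, index=idx))
                idx += 1
    return rays


# ---------------------------------------------------------------------------
# blocking
# ---------------------------------------------------------------------------

def _polyline_arrays(segments):
    P, E, sid = [], [], []
    for seg in segments:
        pts = seg.points
        if len(pts) < 2:
            continue
        P.append(pts[:-1])
        E.append(np.diff(pts, axis=0))
        sid.append(np.full(len(pts) - 1, seg.segment_id, dtype=int))
    if not P:
        return (np.zeros((0, 2)), np.zeros((0, 2)),
                np.zeros(0, dtype=int))
    return np.vstack(P), np.vstack(E), np.concatenate(sid)


def block_edges(rays, segments, gap_min_run: int = 3) -> BlockingResult:
    """Intersect the ray fan with edge segments and keep first hits.

    Per ray, intersections with all segments are ordered by distance
    from the origin; the nearest (rank-1) is kept, rank-2 recorded, and
    deeper hits treated as noise.  A segment that is never anyone's
    rank-1 hit is blocked.  Runs of at least ``gap_min_run`` consecutive
    hitless center rays become gaps, Type I when both flanking retained
    segments are class A of the current cell, else Type II.  Ties at
    equal distance break toward the lower segment id, so the result is
    independent of input segment order.
    """
    segments = list(segments)
    used = set()
    for i, seg in enumerate(segments):
        if seg.segment_id < 0 or seg.segment_id in used:
            seg.segment_id = (max(used) + 1) if used else 0
        used.add(seg.segment_id)
    id_map = {seg.segment_id: seg for seg in segments}
    seg_ids = sorted(id_map)

    P, E, sid = _polyline_arrays(segments)
    center_rays = [r for r in rays if not r.extended]
    theta_grid = np.array([r.theta for r in center_rays])

    hits_all = []
    hit_counts = {s: 0 for s in seg_ids}
    rank1_counts = {s: 0 for s in seg_ids}
    n_center = len(center_rays)
    fh_seg = np.full(n_center, -1, dtype=int)
    fh_dist = np.full(n_center, np.inf)
    fh_point = np.full((n_center, 2), np.nan)

    center_pos = {id(r): i for i, r in enumerate(center_rays)}
    for ray in rays:
        if len(P) == 0:
            continue
        o, d = ray.origin, ray.direction
        po = P - o
        denom = d[0] * E[:, 1] - d[1] * E[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (po[:, 0] * E[:, 1] - po[:, 1] * E[:, 0]) / denom
            s = (po[:, 0] * d[1] - po[:, 1] * d[0]) / denom
        valid = (np.abs(denom) > 1e-12) & (t > 1e-9) & (t <= ray.l) \
            & (s >= -1e-9) & (s <= 1 + 1e-9)
        if not valid.any():
            continue
        per_seg = {}
        for dist, seg_id in zip(t[valid], sid[valid]):
            if seg_id not in per_seg or dist < per_seg[seg_id]:
                per_seg[int(seg_id)] = float(dist)
        ordered = sorted(per_seg.items(), key=lambda kv: (kv[1], kv[0]))
        for rank, (seg_id, dist) in enumerate(ordered, start=1):
            hit_counts[seg_id] += 1
            if rank == 1:
                rank1_counts[seg_id] += 1
            if rank <= 2:
                hits_all.append(Hit(ray_index=ray.index, distance=dist,
                                    segment_id=seg_id, rank=rank,
                                    point=o + dist * d))
        if not ray.extended:
            ci = center_pos[id(ray)]
            best_id, best_dist = ordered[0]
            fh_seg[ci] = best_id
            fh_dist[ci] = best_dist
            fh_point[ci] = o + best_dist * d

    retained = sorted(s for s in seg_ids if rank1_counts[s] > 0)
    blocked = sorted(s for s in seg_ids
                     if hit_counts[s] > 0 and rank1_counts[s] == 0)
    unhit = sorted(s for s in seg_ids if hit_counts[s] == 0)

    gaps = _find_gaps(theta_grid, fh_seg, fh_point, id_map, gap_min_run)
    return BlockingResult(rays=list(rays), segments=segments,
                          hits=hits_all, retained=retained,
                          blocked=blocked, unhit=unhit, gaps=gaps,
                          theta_grid=theta_grid,
                          first_hit_segment=fh_seg,
                          first_hit_distance=fh_dist,
                          first_hit_point=fh_point)


def _find_gaps(theta_grid, fh_seg, fh_point, id_map, gap_min_run):
    n = len(theta_grid)
    if n == 0:
        return []
    hitless = fh_seg < 0
    if hitless.all():
        return [Gap(theta_start=float(theta_grid[0]),
                    theta_end=float(theta_grid[-1]), gap_type="II")]
    if not hitless.any():
        return []
    gaps = []
    first_hit_idx = int(np.argmax(~hitless))
    order = [(i + first_hit_idx) % n for i in range(n + 1)]
    run = []
    for k in order:
        if hitless[k]:
            run.append(k)
            continue
        if len(run) >= gap_min_run:
            left = (run[0] - 1) % n
            right = k
            lseg = id_map.get(int(fh_seg[left]))
            rseg = id_map.get(int(fh_seg[right]))
            gtype = "I" if (lseg is not None and rseg is not None
                            and lseg.edge_class == "A"
                            and rseg.edge_class == "A") else "II"
            gaps.append(Gap(theta_start=float(theta_grid[run[0]]),
                            theta_end=float(theta_grid[run[-1]]),
                            gap_type=gtype,
                            left_segment=int(fh_seg[left]),
                            right_segment=int(fh_seg[right]),
                            left_point=fh_point[left].copy(),
                            right_point=fh_point[right].copy()))
        run = []
    return gaps
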