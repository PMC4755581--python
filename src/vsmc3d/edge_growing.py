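"""Edge growing: fill boundary gaps and assemble closed 2D contours.

Three recovery mechanisms, in the order the pipeline tries them:

* bilateral spline interpolation for gaps between broken edges of the
  same cell — a zero-tension (Catmull-Rom) spline is swept over every
  admissible junction point in both directions across the gap, the
  junction minimizing a curvature objective is kept per direction and
  metric (accumulated vs length-averaged curvature), and the final fill
  among the four options is the one whose intersection-point lengths
  have the smallest standard deviation;
* Laplace-verification PCA for edges the Canny detector missed — the
  second derivative of the intensity profile along small groups of rays
  marks candidate edge coordinates, and a sliding-window principal
  component walk grows a new edge piece through them;
* a splitting rule for edges merged with a touching cell: the shared
  chain is cut at the point nearest an auxiliary line built from both
  cells' orientation vectors and the halves assigned to their cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon

from .edge_blocking import BlockingResult, Gap
from .geometry import scattering_angle_deg, unit
from .preprocess import EdgeSegment, NucleusGeometry


class GapTooWideError(ValueError):
    """Gap wider than the configured multiple of the ray-length scale."""


class UnsegmentableSliceError(RuntimeError):
    """No closed boundary could be assembled on this slice."""


@dataclass
class GapFill:
    """A curve bridging one boundary gap, with selection metrics.

    ``option`` records which of the four interpolation variants won
    (direction 12/21 crossed with accumulated/average curvature);
    ``metrics`` maps every option to its (acc_curv, avg_curv, sd)
    triple so the selection is auditable.
    """

    gap_type: str
    fill_points: np.ndarray
    option: str = ""
    metrics: dict = field(default_factory=dict)
    junction_index: int = -1
    provenance: str = "interpolated"


@dataclass
class Boundary2D:
    """One cell's closed contour on one slice.

    ``contour`` is (N, 2) in (x, y) pixels, not repeating the first
    point; ``provenance`` tags each point's source (detected edge,
    interpolated, pca-grown, split).
    """

    contour: np.ndarray
    provenance: list
    center: np.ndarray = None

    def __post_init__(self):
        self.contour = np.atleast_2d(np.asarray(self.contour, float))

    def polygon(self) -> Polygon:
        return Polygon(self.contour)

    @property
    def area(self) -> float:
        x, y = self.contour[:, 0], self.contour[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1))
                         - np.dot(y, np.roll(x, -1))) / 2.0)

    def contains(self, point) -> bool:
        return self.polygon().buffer(1e-9).contains(Point(*point))


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def curvature_metrics(curve) -> tuple:
    """Accumulated and length-averaged curvature of a discrete curve.

    The accumulated curvature is the total absolute turning angle in
    radians (for a closed circle it approaches 2*pi); the average is the
    total divided by the curve's arc length in pixels (for a circle of
    radius r it approaches 1/r).
    """
    pts = np.atleast_2d(np.asarray(curve, dtype=float))
    if len(pts) < 3:
        raise ValueError("curvature needs at least 3 points")
    seg = np.diff(pts, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    keep = lens > 1e-12
    seg, lens = seg[keep], lens[keep]
    if len(seg) < 2:
        return 0.0, 0.0
    ang = np.arctan2(seg[:, 1], seg[:, 0])
    turn = np.abs((np.diff(ang) + np.pi) % (2 * np.pi) - np.pi)
    acc = float(turn.sum())
    total_len = float(lens.sum())
    return acc, acc / total_len if total_len > 0 else 0.0


# ---------------------------------------------------------------------------
# zero-tension (Catmull-Rom) spline
# ---------------------------------------------------------------------------

def _cardinal_spline(control: np.ndarray, samples_per_span: int = 5
                     ) -> np.ndarray:
    """Chord-length Catmull-Rom spline through all control points.

    A cardinal spline with tension zero: tangents are central
    differences of neighboring control points; each span is a cubic
    Hermite.  Returns a dense polyline through every control point.
    """
    p = np.asarray(control, dtype=float)
    n = len(p)
    if n < 2:
        return p.copy()
    if n == 2:
        t = np.linspace(0, 1, samples_per_span + 1)[:, None]
        return p[0] * (1 - t) + p[1] * t
    d = np.linalg.norm(np.diff(p, axis=0), axis=1)
    d[d == 0] = 1e-9
    t = np.r_[0.0, np.cumsum(d)]
    m = np.zeros_like(p)
    m[0] = (p[1] - p[0]) / (t[1] - t[0])
    m[-1] = (p[-1] - p[-2]) / (t[-1] - t[-2])
    m[1:-1] = ((p[2:] - p[:-2]) / (t[2:] - t[:-2])[:, None])
    out = [p[:1]]
    for i in range(n - 1):
        h = t[i + 1] - t[i]
        u = np.linspace(0, 1, samples_per_span + 1)[1:, None]
        h00 = 2 * u**3 - 3 * u**2 + 1
        h10 = u**3 - 2 * u**2 + u
        h01 = -2 * u**3 + 3 * u**2
        h11 = u**3 - u**2
        out.append(h00 * p[i] + h10 * h * m[i]
                   + h01 * p[i + 1] + h11 * h * m[i + 1])
    return np.vstack(out)


# ---------------------------------------------------------------------------
# bilateral spline interpolation
# ---------------------------------------------------------------------------

def _orient_for_gap(E1: np.ndarray, E2: np.ndarray):
    """Flip the chains so E1 ends and E2 begins at the gap."""
    best = None
    for f1 in (False, True):
        for f2 in (False, True):
            a = E1[::-1] if f1 else E1
            b = E2[::-1] if f2 else E2
            d = np.linalg.norm(a[-1] - b[0])
            if best is None or d < best[0]:
                best = (d, a, b)
    return best[1].copy(), best[2].copy()


def _sweep_junction(E1, E2, samples_per_span, max_junctions):
    """All junction candidates for interpolation from E1 toward E2.

    For junction index j the support points are the whole of E1 plus E2
    from j on; returns per-candidate (j, linked dense curve, bridge
    slice, acc, avg).
    """
    results = []
    n = len(E2)
    j_max = n - 2 if n > 2 else n - 1
    candidates = range(0, j_max + 1)
    if max_junctions is not None:
        candidates = range(0, min(j_max, max_junctions - 1) + 1)
    for j in candidates:
        control = np.vstack([E1, E2[j:]])
        curve = _cardinal_spline(control, samples_per_span)
        acc, avg = curvature_metrics(curve)
        results.append((j, curve, acc, avg))
    return results


def bilateral_spline_interpolate(E1: EdgeSegment, E2: EdgeSegment,
                                 center=None,
                                 lc0: float = 30.0,
                                 max_gap_span_factor: float = 4.0,
                                 samples_per_span: int = 5,
                                 max_junctions: int = None) -> GapFill:
    """Fill the gap between two retained edges by bilateral interpolation.

    Interpolates twice — from E1 toward E2 with a floating junction on
    E2, and from E2 toward E1 with the junction on E1.  Per direction
    the junction minimizing accumulated curvature and the one minimizing
    average curvature are kept (four options in total); the final fill
    is the option whose linked-edge intersection-point lengths (point
    distances to the cell center) have the smallest standard deviation,
    ties resolved in fixed option order.  Junction argmin ties break to
    the smallest index.
    """
    p1 = E1.points if isinstance(E1, EdgeSegment) else np.asarray(E1, float)
    p2 = E2.points if isinstance(E2, EdgeSegment) else np.asarray(E2, float)
    p1, p2 = _orient_for_gap(p1, p2)
    gap_width = float(np.linalg.norm(p1[-1] - p2[0]))
    if gap_width > max_gap_span_factor * lc0:
        raise GapTooWideError(
            f"gap of {gap_width:.1f} px exceeds "
            f"{max_gap_span_factor} * lc0 = {max_gap_span_factor * lc0}")

    def bridge(curve, a_end, b_start):
        d_a = np.linalg.norm(curve - a_end, axis=1)
        d_b = np.linalg.norm(curve - b_start, axis=1)
        i0, i1 = int(np.argmin(d_a)), int(np.argmin(d_b))
        if i0 <= i1:
            return curve[i0:i1 + 1]
        return curve[i1:i0 + 1][::-1]

    sweeps = {
        "12": _sweep_junction(p1, p2, samples_per_span, max_junctions),
        "21": _sweep_junction(p2[::-1], p1[::-1], samples_per_span,
                              max_junctions),
    }
    options = {}
    for direction, cands in sweeps.items():
        if not cands:
            continue
        accs = np.array([c[2] for c in cands])
        avgs = np.array([c[3] for c in cands])
        for metric, values in (("acc", accs), ("avg", avgs)):
            k = int(np.argmin(values))
            j, curve, acc, avg = cands[k]
            if center is not None:
                le = np.linalg.norm(curve - np.asarray(center, float),
                                    axis=1)
                sd = float(np.std(le))
            else:
                sd = float(values[k])
            if direction == "12":
                fill = bridge(curve, p1[-1], p2[j])
            else:
                fill = bridge(curve, p2[0], p1[::-1][j])[::-1]
            options[f"{metric}_{direction}"] = (j, fill, acc, avg, sd)

    if not options:
        raise ValueError("no admissible junction candidates")
    order = ["acc_12", "avg_12", "acc_21", "avg_21"]
    best_name = min((name for name in order if name in options),
                    key=lambda name: options[name][4])
    j, fill, acc, avg, sd = options[best_name]
    return GapFill(gap_type="I", fill_points=np.asarray(fill, float),
                   option=best_name,
                   metrics={name: {"acc_curv": v[2], "avg_curv": v[3],
                                   "sd": v[4]}
                            for name, v in options.items()},
                   junction_index=j, provenance="interpolated")


# ---------------------------------------------------------------------------
# Laplace verification PCA
# ---------------------------------------------------------------------------

def _ray_candidates(image, ray, r_start, r_stop, smooth_sigma,
                    response_floor):
    """Best one-signed second-derivative coordinate along one ray."""
    if r_stop - r_start < 3:
        return None
    r = np.arange(r_start, r_stop, 1.0)
    pts = ray.origin + r[:, None] * ray.direction
    prof = ndimage.map_coordinates(image, [pts[:, 1], pts[:, 0]],
                                   order=1, mode="nearest")
    if smooth_sigma > 0:
        prof = ndimage.gaussian_filter1d(prof, smooth_sigma)
    lap = np.zeros_like(prof)
    lap[1:-1] = prof[2:] - 2 * prof[1:-1] + prof[:-2]
    # outer intensity falloff: keep the positive-response extreme
    resp = lap.copy()
    resp[resp < 0] = 0.0
    if resp.max() <= response_floor:
        return None
    k = int(np.argmax(resp))
    return pts[k]


def laplace_verify_pca(image, rays, nucleus_mask,
                       blocking: BlockingResult = None,
                       window: int = 5, gap: Gap = None,
                       group_deg: float = 7.0,
                       smooth_sigma: float = 0.8,
                       response_floor: float = 1e-6,
                       max_steps: int = 200) -> EdgeSegment:
    """Grow a missed edge from second-derivative extremes along rays.

    For each ray in the group the intensity profile between the nucleus
    edge and the first far (rank-2 / Type B) hit is differentiated
    twice; the coordinate with the strongest one-signed response is an
    edge candidate p_i.  A ``window`` x ``window`` box starting at the
    candidate nearest the gap's left flank is then walked: principal
    component analysis of the in-window candidates gives the local edge
    direction, a piece is drawn from their centroid along it with length
    equal to the farthest in-window candidate, and the window translates
    to the piece's end until candidates are exhausted.  Returns None
    when no qualifying candidates exist (caller falls back to
    interpolation).
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(nucleus_mask, dtype=bool)
    use = []
    for ray in rays:
        if ray.extended:
            continue
        if gap is not None:
            span = (gap.theta_end - gap.theta_start) % 360.0
            off = (ray.theta - gap.theta_start) % 360.0
            if off > span + group_deg:
                continue
        use.append(ray)
    if not use:
        return None

    cands = []
    for ray in use:
        # start outside the nucleus region
        r_start = 1.0
        for r in np.arange(1.0, ray.l, 1.0):
            p = ray.origin + r * ray.direction
            xi, yi = int(round(p[0])), int(round(p[1]))
            if not (0 <= yi < mask.shape[0] and 0 <= xi < mask.shape[1]) \
                    or not mask[yi, xi]:
                r_start = r
                break
        r_stop = ray.l
        if blocking is not None:
            far = [h.distance for h in blocking.hits
                   if h.ray_index == ray.index and h.rank == 2]
            if far:
                r_stop = min(r_stop, min(far))
        p = _ray_candidates(image, ray, r_start, r_stop, smooth_sigma,
                            response_floor)
        if p is not None:
            cands.append(p)
    if len(cands) < 2:
        return None
    cands = np.array(cands)

    if gap is not None and gap.left_point is not None \
            and np.isfinite(gap.left_point).all():
        start = cands[np.argmin(np.linalg.norm(
            cands - gap.left_point, axis=1))]
        goal = gap.right_point
    else:
        start = cands[0]
        goal = cands[-1]

    half = window / 2.0
    pos = start.astype(float)
    remaining = cands.copy()
    grown = []
    prev_dir = None
    for _ in range(max_steps):
        inside = np.all(np.abs(remaining - pos) <= half, axis=1)
        pts = remaining[inside]
        if len(pts) < 2:
            break
        centroid = pts.mean(axis=0)
        cov = np.cov((pts - centroid).T)
        evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
        v1 = evecs[:, -1]
        if prev_dir is not None and v1 @ prev_dir < 0:
            v1 = -v1
        elif prev_dir is None and goal is not None \
                and np.isfinite(goal).all() \
                and v1 @ (goal - centroid) < 0:
            v1 = -v1
        length = float(np.max(np.linalg.norm(pts - centroid, axis=1)))
        if length < 1e-9:
            break
        n_samples = max(int(np.ceil(length)), 1)
        piece = centroid + np.linspace(0, length, n_samples + 1)[:, None] \
            * v1
        grown.append(piece)
        prev_dir = v1
        pos = piece[-1]
        remaining = remaining[~inside]
        if len(remaining) == 0:
            break
    if not grown:
        return None
    points = np.vstack(grown)
    seg = EdgeSegment(points=points, edge_class="A")
    return seg


# ---------------------------------------------------------------------------
# splitting of merged (Type C) edges
# ---------------------------------------------------------------------------

def split_merged_edge(edge: EdgeSegment, geom_a: NucleusGeometry,
                      geom_b: NucleusGeometry) -> tuple:
    """Split an edge shared by two touching cells and assign the halves.

    The edge's endpoint nearer cell a is dropped perpendicularly onto
    a's long axis (auxiliary point B), the endpoint nearer cell b onto
    b's axis (auxiliary point D); the edge is split at its point of
    shortest distance to line BD, the first half (containing the
    a-side endpoint) going to cell a.  Concatenating the halves
    reproduces the input chain exactly.
    """
    if edge.edge_class != "C":
        raise ValueError("splitting applies to class C (shared) edges")
    pts = edge.points
    if len(pts) < 3:
        raise ValueError("shared edge too short to split")

    d_a = np.linalg.norm(pts[0] - geom_a.center)
    d_a2 = np.linalg.norm(pts[-1] - geom_a.center)
    a_first = d_a <= d_a2
    end_a = pts[0] if a_first else pts[-1]
    end_b = pts[-1] if a_first else pts[0]

    def foot(point, geom):
        v = unit(geom.cell_vector)
        return geom.center + ((point - geom.center) @ v) * v

    B = foot(end_a, geom_a)
    D = foot(end_b, geom_b)
    bd = D - B
    nrm = np.linalg.norm(bd)
    if nrm < 1e-9:
        dists = np.linalg.norm(pts - B, axis=1)
    else:
        u = bd / nrm
        rel = pts - B
        dists = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
    f = int(np.argmin(dists))
    f = min(max(f, 1), len(pts) - 2)

    first = EdgeSegment(points=pts[:f + 1].copy(), edge_class="A",
                        side=edge.side, part=edge.part)
    second = EdgeSegment(points=pts[f + 1:].copy(), edge_class="A",
                         side=edge.side, part=edge.part)
    if a_first:
        return first, second
    return second, first


# ---------------------------------------------------------------------------
# boundary assembly
# ---------------------------------------------------------------------------

def _circular_mean_theta(thetas):
    return float(np.degrees(np.angle(np.mean(
        np.exp(1j * np.radians(np.asarray(thetas))))))) % 360.0


def _star_assembly(points, tags, center, bin_deg=0.5):
    """Fallback: simple star-shaped polygon sorted by ray angle."""
    pts = np.asarray(points, float)
    th = scattering_angle_deg(pts, center, (0.0, 1.0))
    order = np.argsort(th)
    pts, th = pts[order], th[order]
    tags = [tags[i] for i in order]
    keep_pts, keep_tags = [], []
    i = 0
    while i < len(pts):
        j = i
        while j + 1 < len(pts) and th[j + 1] - th[i] < bin_deg:
            j += 1
        grp = pts[i:j + 1]
        radii = np.linalg.norm(grp - center, axis=1)
        k = i + int(np.argsort(radii)[len(radii) // 2])
        keep_pts.append(pts[k])
        keep_tags.append(tags[k])
        i = j + 1
    return np.array(keep_pts), keep_tags


def close_boundary(blocking: BlockingResult, fills,
                   center=None, max_gap_angle_deg: float = 90.0,
                   smooth_window: int = 0) -> Boundary2D:
    """Assemble retained edges and gap fills into one closed contour.

    Retained segments are concatenated in clockwise ray order with the
    fills bridging their gaps; the loop is normalized to clockwise
    winding.  A self-crossing loop is repaired (by polygon cleanup,
    falling back to a star-shaped reassembly around the center); a gap
    wider than ``max_gap_angle_deg`` with no usable fill flags the slice
    as unsegmentable.  ``smooth_window`` > 1 applies a circular moving
    average to the closed loop, damping single-pixel detector jitter
    (off by default: with no gaps the boundary is the retained contour
    verbatim).
    """
    if center is None:
        if not blocking.rays:
            raise ValueError("no rays to infer the center from")
        center = np.asarray(
            next(r for r in blocking.rays if not r.extended).origin,
            float)
    else:
        center = np.asarray(center, float)

    fills = list(fills)
    filled_gaps = {id(f): f for f in fills}
    for gap in blocking.gaps:
        if gap.span_deg > max_gap_angle_deg and not fills:
            raise UnsegmentableSliceError(
                f"unfillable gap of {gap.span_deg:.0f} degrees")

    by_id = {s.segment_id: s for s in blocking.segments}
    retained = [by_id[i] for i in blocking.retained if i in by_id]
    if not retained and not fills:
        raise UnsegmentableSliceError("nothing retained on this slice")

    cell_vec = (0.0, 1.0)
    pieces = []
    for seg in retained:
        pts = seg.points
        ok = ~np.all(np.isclose(pts, center), axis=1)
        pts = pts[ok]
        if len(pts) < 2:
            continue
        th = scattering_angle_deg(pts, center, cell_vec)
        unwrapped = np.degrees(np.unwrap(np.radians(th)))
        if unwrapped[-1] < unwrapped[0]:
            pts = pts[::-1]
            th = th[::-1]
        pieces.append({
            "points": pts, "theta": _circular_mean_theta(th),
            "tag": "edge",
        })
    for f in fills:
        pts = np.asarray(f.fill_points, float)
        ok = ~np.all(np.isclose(pts, center), axis=1)
        pts = pts[ok]
        if len(pts) < 2:
            continue
        th = scattering_angle_deg(pts, center, cell_vec)
        pieces.append({
            "points": pts, "theta": _circular_mean_theta(th),
            "tag": f.provenance,
        })
    if not pieces:
        raise UnsegmentableSliceError("no boundary material")

    pieces.sort(key=lambda p: p["theta"])
    loop_pts = [pieces[0]["points"]]
    loop_tags = [[pieces[0]["tag"]] * len(pieces[0]["points"])]
    for piece in pieces[1:]:
        prev_end = loop_pts[-1][-1]
        pts = piece["points"]
        if np.linalg.norm(pts[0] - prev_end) > \
                np.linalg.norm(pts[-1] - prev_end):
            pts = pts[::-1]
        loop_pts.append(pts)
        loop_tags.append([piece["tag"]] * len(pts))
    contour = np.vstack(loop_pts)
    tags = [t for sub in loop_tags for t in sub]

    # drop exact consecutive duplicates
    dup = np.r_[True, np.linalg.norm(np.diff(contour, axis=0),
                                     axis=1) > 1e-9]
    contour, tags = contour[dup], [t for t, k in zip(tags, dup) if k]

    boundary = _normalize_winding(contour, tags)
    poly = boundary.polygon()
    if not (poly.is_valid and poly.is_simple
            and poly.buffer(1e-9).contains(Point(*center))):
        repaired = poly.buffer(0)
        best = None
        geoms = getattr(repaired, "geoms", [repaired])
        for g in geoms:
            if g.is_empty or g.geom_type != "Polygon":
                continue
            if g.buffer(1e-9).contains(Point(*center)):
                if best is None or g.area > best.area:
                    best = g
        if best is not None and best.area > 0:
            pts = np.asarray(best.exterior.coords[:-1], float)
            boundary = _normalize_winding(pts, ["edge"] * len(pts))
        else:
            pts, tg = _star_assembly(contour, tags, center)
            if len(pts) < 3:
                raise UnsegmentableSliceError("degenerate boundary")
            boundary = _normalize_winding(pts, tg)
    if smooth_window and smooth_window > 1 \
            and len(boundary.contour) > smooth_window:
        k = smooth_window
        kernel = np.ones(k) / k
        closed = boundary.contour
        sm = np.column_stack([
            np.convolve(np.r_[closed[-(k // 2):, i], closed[:, i],
                              closed[:k // 2, i]], kernel,
                        mode="valid")[:len(closed)]
            for i in range(2)])
        candidate = Boundary2D(contour=sm,
                               provenance=list(boundary.provenance))
        if candidate.polygon().is_valid and \
                candidate.polygon().buffer(1e-6).contains(Point(*center)):
            boundary = candidate
    if not boundary.polygon().buffer(1e-6).contains(Point(*center)):
        raise UnsegmentableSliceError(
            "assembled boundary does not enclose the cell center")
    boundary.center = center
    return boundary


def _normalize_winding(contour, tags) -> Boundary2D:
    """Clockwise winding in the (x, y) frame: negative shoelace area."""
    x, y = contour[:, 0], contour[:, 1]
    signed = float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if signed > 0:
        contour = contour[::-1].copy()
        tags = tags[::-1]
    return Boundary2D(contour=contour, provenance=list(tags))
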