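"""Per-slice preprocessing: filtering, edge detection and edge bookkeeping.

Order of operations for one slice of the cell channel: coherence-enhancing
anisotropic diffusion (edge-preserving smoothing), Canny edge detection,
then cleanup of the binary edge map into single-pixel chains with exactly
two endpoints (bifurcation removal, spur pruning).  The nucleus channel
yields the seed geometry: the nucleus centroid acts as the cell center and
the pruned skeleton's endpoints define the cell's orientation vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import feature, measure, morphology

from .geometry import scattering_angle_deg, unit


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EdgeSegment:
    """An ordered single-pixel-wide chain of 2D edge points.

    ``points`` is (N, 2) in (x, y) pixel coordinates; interior points have
    exactly two chain neighbors (no bifurcations) and the chain has two
    endpoints.  ``edge_class`` is one of A (real edge of the current
    cell), B (false edge from another cell), C (edge shared with a
    touching cell), inner, or unknown.
    """

    points: np.ndarray
    edge_class: str = "unknown"
    side: str = "unknown"     # left / right / unknown
    part: str = "unknown"     # trunk / tail / unknown
    segment_id: int = -1

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 2:
            raise ValueError("points must be (N, 2)")

    def __len__(self):
        return len(self.points)

    @property
    def endpoints(self) -> np.ndarray:
        return self.points[[0, -1]]

    @property
    def arc_length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0),
                                    axis=1).sum())

    def is_valid_chain(self) -> bool:
        """Chain steps are 8-connected moves with no repeated point."""
        pts = np.round(self.points).astype(int)
        if len(pts) < 2:
            return True
        steps = np.abs(np.diff(pts, axis=0))
        return bool((steps.max(axis=1) <= 1).all()
                    and (steps.sum(axis=1) > 0).all())


@dataclass
class NucleusGeometry:
    """Seed geometry of one nucleus on one slice.

    ``center`` (the nucleus centroid pixel) acts as the cell center c0;
    ``cell_vector`` is the unit vector from the center toward one
    endpoint of the nucleus long axis; the pruned ``skeleton`` has
    exactly two endpoint termini.
    """

    center: np.ndarray                 # (x, y) pixel
    skeleton: np.ndarray               # (K, 2) ordered chain
    endpoints: np.ndarray              # (2, 2)
    cell_vector: np.ndarray            # unit (nx, ny)
    low_anisotropy: bool = False
    mask: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.cell_vector = unit(self.cell_vector)


# ---------------------------------------------------------------------------
# filtering and edge detection
# ---------------------------------------------------------------------------

def coherence_filter(image, iterations: int = 5, dt: float = 0.15,
                     rho: float = 3.0, edge_lambda: float = 1e-3,
                     coherence_scale: float = 1e-4) -> np.ndarray:
    """Coherence-enhancing anisotropic diffusion.

    Smooths along locally coherent (edge-parallel) directions while
    diffusing very little across edges.  The diffusion tensor shares
    eigenvectors with the Gaussian-smoothed structure tensor (scale
    ``rho``); the across-edge conductivity is ``edge_lambda`` and the
    along-edge one approaches 1 where the orientation is coherent.
    Output is clipped to the input range (diffusion maximum principle).
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return img.copy()
    u = img.copy()
    for _ in range(iterations):
        Arr, Arc, Acc = feature.structure_tensor(
            u, sigma=rho, mode="nearest", order="rc")
        tr = 0.5 * (Arr + Acc)
        root = np.sqrt(np.maximum(0.25 * (Arr - Acc) ** 2 + Arc**2, 0.0))
        mu1, mu2 = tr + root, tr - root
        coherence = (mu1 - mu2) ** 2
        lam2 = edge_lambda + (1.0 - edge_lambda) * np.exp(
            -coherence_scale / np.maximum(coherence, 1e-30))
        # dominant eigenvector angle in the (row, col) frame
        angle = 0.5 * np.arctan2(2 * Arc, Arr - Acc)
        c, s = np.cos(angle), np.sin(angle)
        lam1 = edge_lambda
        d11 = lam1 * c * c + lam2 * s * s
        d22 = lam1 * s * s + lam2 * c * c
        d12 = (lam1 - lam2) * c * s
        ur, uc = np.gradient(u)
        jr = d11 * ur + d12 * uc
        jc = d12 * ur + d22 * uc
        div = np.gradient(jr, axis=0) + np.gradient(jc, axis=1)
        u = u + dt * div
    return np.clip(u, lo, hi)


def detect_edges(image, sigma: float = 1.5, low: float = 0.1,
                 high: float = 0.2, intensity_range=None) -> np.ndarray:
    """Thinned binary Canny edge map.

    ``low``/``high`` are hysteresis thresholds as fractions of the
    dynamic range; pass ``intensity_range=(lo, hi)`` to threshold
    relative to a whole-stack range instead of this slice's own.
    """
    img = np.asarray(image, dtype=float)
    if intensity_range is None:
        lo, hi = img.min(), img.max()
    else:
        lo, hi = intensity_range
    if hi <= lo:
        return np.zeros(img.shape, dtype=bool)
    norm = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    return feature.canny(norm, sigma=sigma, low_threshold=low,
                         high_threshold=high)


# ---------------------------------------------------------------------------
# edge-map cleanup
# ---------------------------------------------------------------------------

def _pixel_graph(edge_map: np.ndarray) -> nx.Graph:
    """8-connectivity graph of edge pixels.

    Diagonal links that short-circuit a 4-connected pair (the staircase
    artifact of thin chains) are omitted so that a thin curve really is a
    path in the graph.
    """
    pix = set(zip(*np.nonzero(edge_map)))
    g = nx.Graph()
    g.add_nodes_from(pix)
    for (r, c) in pix:
        for dr, dc in ((0, 1), (1, 0)):
            q = (r + dr, c + dc)
            if q in pix:
                g.add_edge((r, c), q)
        for dr, dc in ((1, 1), (1, -1)):
            q = (r + dr, c + dc)
            if q in pix:
                if ((r, c + dc) in pix) or ((r + dr, c) in pix):
                    continue
                g.add_edge((r, c), q)
    return g


def _prune_spurs(g: nx.Graph, spur_length: int) -> None:
    """Remove short dead-end branches hanging off junctions, in place."""
    changed = True
    while changed:
        changed = False
        for j in [n for n in g if g.degree(n) >= 3]:
            if j not in g or g.degree(j) < 3:
                continue
            for nbr in list(g.neighbors(j)):
                if nbr not in g:
                    continue
                branch = [nbr]
                prev, cur = j, nbr
                while cur in g and g.degree(cur) == 2:
                    nxt = next(n for n in g.neighbors(cur) if n != prev)
                    prev, cur = cur, nxt
                    branch.append(cur)
                    if len(branch) > spur_length:
                        break
                if len(branch) <= spur_length and branch[-1] in g \
                        and g.degree(branch[-1]) == 1:
                    g.remove_nodes_from(branch)
                    changed = True


def _order_component(g: nx.Graph, nodes) -> np.ndarray:
    """Order a path or cycle component into an (N, 2) (x, y) chain."""
    sub = g.subgraph(nodes)
    ends = [n for n in sub if sub.degree(n) <= 1]
    start = min(ends) if ends else min(nodes)
    chain = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [n for n in sub.neighbors(cur) if n not in seen]
        if not nxt:
            break
        cur = min(nxt)
        chain.append(cur)
        seen.add(cur)
    rc = np.array(chain, dtype=float)
    return rc[:, ::-1].copy()   # (row, col) -> (x, y)


def clean_edges(edge_map, spur_length: int = 5, min_length: int = 3,
                center=None, cell_vector=(0.0, 1.0)) -> list:
    """Break a binary edge map into clean single-pixel chains.

    Spur branches shorter than ``spur_length`` are pruned, junction
    pixels removed, and each remaining 8-connected component ordered into
    a chain with two endpoints (cycles are opened).  Chains shorter than
    ``min_length`` are dropped.  When ``center`` is given, segments are
    sorted by the clockwise ray angle of their midpoint and each chain is
    oriented in increasing-angle direction.
    """
    edge_map = np.asarray(edge_map, dtype=bool)
    g = _pixel_graph(edge_map)
    _prune_spurs(g, spur_length)
    g.remove_nodes_from([n for n in list(g) if g.degree(n) >= 3])

    segments = []
    for nodes in nx.connected_components(g):
        if len(nodes) < min_length:
            continue
        pts = _order_component(g, nodes)
        if len(pts) < min_length:
            continue
        segments.append(EdgeSegment(points=pts))

    if center is not None:
        center = np.asarray(center, dtype=float)

        def mid_angle(seg):
            mid = seg.points[len(seg.points) // 2]
            if np.allclose(mid, center):
                mid = seg.points[0]
            return float(scattering_angle_deg(mid[None, :], center,
                                              cell_vector)[0])

        for seg in segments:
            pts = seg.points
            ok = ~np.all(pts == center, axis=1)
            if ok.sum() >= 2:
                th = scattering_angle_deg(pts[ok], center, cell_vector)
                th = np.unwrap(np.radians(th))
                if th[-1] < th[0]:
                    seg.points = pts[::-1].copy()
        segments.sort(key=mid_angle)
    for i, seg in enumerate(segments):
        seg.segment_id = i
    return segments


# ---------------------------------------------------------------------------
# nucleus geometry
# ---------------------------------------------------------------------------

def _longest_path(g: nx.Graph):
    """Approximate longest path in a pixel graph via double BFS."""
    start = next(iter(g))
    far1 = max(nx.single_source_shortest_path_length(g, start).items(),
               key=lambda kv: kv[1])[0]
    lengths = nx.single_source_shortest_path_length(g, far1)
    far2 = max(lengths.items(), key=lambda kv: kv[1])[0]
    return nx.shortest_path(g, far1, far2)


def extract_nucleus_geometry(mask) -> NucleusGeometry:
    """Seed geometry from a single-nucleus binary mask.

    The skeleton comes from morphological thinning pruned to its longest
    endpoint-to-endpoint path; the center is the mask centroid; the cell
    vector points from the center toward the endpoint of the long axis.
    Nearly isotropic masks (axis ratio < 1.2) fall back to the
    image-moment principal axis with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty nucleus mask")
    labels = measure.label(mask, connectivity=2)
    if labels.max() > 1:
        raise ValueError("nucleus mask has multiple components; "
                         "label and pass one component at a time")

    rr, cc = np.nonzero(mask)
    centroid = np.array([cc.mean(), rr.mean()])  # (x, y)

    coords = np.column_stack([cc, rr]).astype(float)
    cov = np.cov((coords - centroid).T) if len(coords) > 1 else np.eye(2)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    major_vec = evecs[:, -1]
    axis_ratio = float(np.sqrt(evals[-1] / max(evals[0], 1e-12)))

    skel_map = morphology.thin(mask)
    g = _pixel_graph(skel_map)
    low_aniso = axis_ratio < 1.2
    skeleton = None
    if len(g) >= 2:
        comp = max(nx.connected_components(g), key=len)
        path = _longest_path(g.subgraph(comp))
        if len(path) >= 2:
            skeleton = np.array(path, dtype=float)[:, ::-1]
    if skeleton is None or low_aniso:
        warnings.warn("nucleus mask is nearly isotropic; using the "
                      "image-moment principal axis", stacklevel=2)
        half = max(np.sqrt(max(evals[-1], 1.0)) * 2.0, 1.0)
        skeleton = np.array([centroid - half * major_vec,
                             centroid + half * major_vec])
        low_aniso = True

    endpoints = skeleton[[0, -1]]
    d = np.linalg.norm(endpoints - centroid, axis=1)
    tip = endpoints[int(np.argmax(d))]
    vec = tip - centroid
    if np.allclose(vec, 0):
        vec = major_vec
    return NucleusGeometry(center=centroid, skeleton=skeleton,
                           endpoints=endpoints, cell_vector=unit(vec),
                           low_anisotropy=bool(low_aniso), mask=mask)


# ---------------------------------------------------------------------------
# edge classification
# ---------------------------------------------------------------------------

def _sample(image, pts):
    """Bilinear sample of (x, y) points from an image indexed [y, x]."""
    return ndimage.map_coordinates(np.asarray(image, float),
                                   [pts[:, 1], pts[:, 0]], order=1,
                                   mode="nearest")


def image_derivatives(image, sigma: float = 1.0):
    """Precomputed (gx, gy, laplacian) for repeated edge classification."""
    sm = ndimage.gaussian_filter(np.asarray(image, float), sigma)
    gy, gx = np.gradient(sm)
    return gx, gy, ndimage.laplace(sm)


def classify_edge(segment: EdgeSegment, image, geometry: NucleusGeometry,
                  derivatives=None, far_offset: float = 3.0,
                  foreground_fraction: float = 0.5,
                  tail_half_angle_deg: float = 60.0) -> str:
    """Classify a segment as A, B, C or unknown relative to one cell.

    A: the intensity gradient along the segment points toward the cell
    interior and the second derivative is consistent with the segment's
    side (more negative just inside than just outside).  B: gradient or
    second-derivative sign inconsistent with the current cell.  C: like A
    but the far side of the segment is also foreground, i.e. the edge is
    shared with a touching cell.  Segments shorter than 3 px are
    ``unknown``.  Also fills in the segment's side (left/right of the
    cell vector) and part (trunk/tail) labels.
    """
    if len(segment) < 3:
        segment.edge_class = "unknown"
        return "unknown"
    img = np.asarray(image, dtype=float)
    if derivatives is None:
        derivatives = image_derivatives(img)
    gx, gy, lap = derivatives

    pts = segment.points
    to_center = geometry.center - pts
    norms = np.linalg.norm(to_center, axis=1)
    keep = norms > 1e-9
    pts, to_center, norms = pts[keep], to_center[keep], norms[keep]
    if len(pts) < 3:
        segment.edge_class = "unknown"
        return "unknown"
    u = to_center / norms[:, None]

    grad = np.column_stack([_sample(gx, pts), _sample(gy, pts)])
    gmag = np.linalg.norm(grad, axis=1)
    ok = gmag > 1e-9
    toward = float(np.mean(np.sum(grad[ok] * u[ok], axis=1) /
                           gmag[ok])) if ok.any() else 0.0

    lap_in = float(np.mean(_sample(lap, pts + 1.5 * u)))
    lap_out = float(np.mean(_sample(lap, pts - 1.5 * u)))

    # side (left/right of the cell vector) and trunk/tail labels
    theta = scattering_angle_deg(pts, geometry.center,
                                 geometry.cell_vector)
    nvec = geometry.cell_vector
    cross = nvec[0] * (-to_center[:, 1]) - nvec[1] * (-to_center[:, 0])
    segment.side = "left" if float(np.mean(cross)) > 0 else "right"
    mean_theta = float(np.degrees(np.angle(
        np.mean(np.exp(1j * np.radians(theta)))))) % 360.0
    off_normal = min(abs((mean_theta - 90 + 180) % 360 - 180),
                     abs((mean_theta - 270 + 180) % 360 - 180))
    segment.part = ("trunk" if off_normal <= tail_half_angle_deg
                    else "tail")

    if toward <= 0.0 or lap_in >= lap_out:
        segment.edge_class = "B"
        return "B"

    inner = float(np.mean(_sample(img, pts + 2.5 * u)))
    far = float(np.mean(_sample(img, pts - far_offset * u)))
    if far > foreground_fraction * max(inner, 1e-12):
        segment.edge_class = "C"
        return "C"
    segment.edge_class = "A"
    return "A"


def remove_inner_edges(segments, nucleus_mask, dilation: int = 2,
                       min_fraction: float = 0.0) -> list:
    """Drop edges reachable from the nucleus region over edge pixels.

    Edge pixels of all segments form one binary map; any 8-connected
    component of that map that touches the dilated nucleus region is an
    inner-edge chain, and every segment contributing pixels to it is
    removed (the whole bridging chain, not just the touching segment).
    ``min_fraction`` additionally requires that at least this fraction
    of a segment's own pixels lie inside the dilated nucleus region —
    for very slender cells the outer boundary can graze the nucleus,
    and a positive fraction keeps such grazing contours alive.
    """
    if not segments:
        return []
    mask = np.asarray(nucleus_mask, dtype=bool)
    shape = mask.shape
    edge_img = np.zeros(shape, dtype=bool)
    clipped = []
    for seg in segments:
        pts = np.round(seg.points).astype(int)
        pts = pts[(pts[:, 0] >= 0) & (pts[:, 0] < shape[1])
                  & (pts[:, 1] >= 0) & (pts[:, 1] < shape[0])]
        edge_img[pts[:, 1], pts[:, 0]] = True
        clipped.append(pts)
    seed = ndimage.binary_dilation(mask, iterations=max(dilation, 1))
    labels = measure.label(edge_img, connectivity=2)
    inner_labels = set(np.unique(labels[seed & edge_img])) - {0}
    kept = []
    for seg, pts in zip(segments, clipped):
        labs = set(labels[pts[:, 1], pts[:, 0]]) - {0} if len(pts) else set()
        inner = bool(labs & inner_labels)
        if inner and min_fraction > 0 and len(pts):
            frac = float(np.mean(seed[pts[:, 1], pts[:, 0]]))
            inner = frac >= min_fraction
        if inner:
            seg.edge_class = "inner"
        else:
            kept.append(seg)
    return kept
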