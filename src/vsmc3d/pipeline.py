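"""End-to-end semi-automatic segmentation of a two-channel z-stack.

For every seed nucleus: build the slice-wise boundary by edge blocking,
classification, gap growing and stable-edge propagation; stack the
boundaries into a 3D binary volume; extract and smooth the surface; and
measure the morphometric parameter vector.  The interactive steps of the
original workflow (ROI drawing, key-edge selection) are replaced by an
ROI polygon, explicit seed coordinates, or a fully automatic mode that
seeds every detected nucleus.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from shapely.geometry import Point, Polygon

from .config import PipelineConfig
from .edge_blocking import block_edges, cast_ray_fan
from .edge_growing import (
    Boundary2D,
    GapFill,
    GapTooWideError,
    UnsegmentableSliceError,
    bilateral_spline_interpolate,
    close_boundary,
    laplace_verify_pca,
)
from .geometry import unit
from .morphometry import (
    Morphometry,
    in_plane_angle,
    length_width_thickness,
    project_and_fit,
    tilt_angle,
)
from .phantom import (
    BinaryVolume,
    PhantomSpec,
    make_ellipsoid_mesh,
    voxelize,
)
from .preprocess import (
    EdgeSegment,
    NucleusGeometry,
    clean_edges,
    coherence_filter,
    detect_edges,
    extract_nucleus_geometry,
    image_derivatives,
    classify_edge,
    remove_inner_edges,
)
from .reconstruction import extract_surface, laplacian_smooth, \
    stack_boundaries
from .stable_edge import FallbackRequest, propagate_boundary

log = logging.getLogger("vsmc3d.pipeline")


@dataclass
class ImageStack:
    """Registered two-channel z-stack with voxel spacing metadata."""

    cell_channel: np.ndarray      # (Z, Y, X)
    nucleus_channel: np.ndarray
    spacing: tuple                # (sx, sy, sz) µm

    def __post_init__(self):
        self.cell_channel = np.asarray(self.cell_channel, dtype=float)
        self.nucleus_channel = np.asarray(self.nucleus_channel,
                                          dtype=float)
        if self.cell_channel.shape != self.nucleus_channel.shape:
            raise ValueError("channels must share one shape")
        if self.cell_channel.ndim != 3:
            raise ValueError("stacks are (Z, Y, X)")

    @classmethod
    def from_tiffs(cls, cell_path, nucleus_path, spacing):
        return cls(tifffile.imread(cell_path),
                   tifffile.imread(nucleus_path), tuple(spacing))

    @classmethod
    def from_synthetic(cls, stack):
        return cls(stack.cell_channel, stack.nucleus_channel,
                   stack.spacing)


@dataclass
class CellRecord:
    """One reconstructed cell: volume, mesh, boundaries, morphometry."""

    cell_id: int
    seed_voxel: tuple                       # (x, y, z)
    boundaries: dict = field(default_factory=dict, repr=False)
    volume: BinaryVolume = None
    mesh: object = None
    morphometry: Morphometry = None
    error: str = None
    flags: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.error is None and self.morphometry is not None


# ---------------------------------------------------------------------------
# per-slice preprocessing cache
# ---------------------------------------------------------------------------

class _SliceCache:
    """Lazily computed per-slice filtered image, edge chains and
    derivatives, shared by all cells."""

    def __init__(self, stack: ImageStack, config: PipelineConfig):
        self.stack = stack
        self.config = config
        lo = float(stack.cell_channel.min())
        hi = float(stack.cell_channel.max())
        self.intensity_range = (lo, hi if hi > lo else lo + 1.0)
        self._cache = {}

    def __call__(self, z: int):
        if z not in self._cache:
            cfg = self.config
            img = self.stack.cell_channel[z]
            if cfg.contrast_normalize:
                p99 = np.percentile(img, 99)
                if p99 > 0:
                    img = np.clip(img / p99, 0, 1) \
                        * self.intensity_range[1]
            filtered = coherence_filter(
                img, iterations=cfg.diffusion_iterations,
                dt=cfg.diffusion_dt)
            edges = detect_edges(filtered, sigma=cfg.canny_sigma,
                                 low=cfg.canny_low, high=cfg.canny_high,
                                 intensity_range=self.intensity_range)
            segments = clean_edges(edges, spur_length=cfg.spur_length,
                                   min_length=cfg.min_segment_length)
            derivs = image_derivatives(filtered)
            self._cache[z] = (filtered, segments, derivs)
        return self._cache[z]


# ---------------------------------------------------------------------------
# nucleus seeding
# ---------------------------------------------------------------------------

@dataclass
class _Seed:
    label: int
    centroid_xyz: np.ndarray        # voxel (x, y, z)
    seed_slice: int
    geometry: NucleusGeometry       # on the seed slice
    voxels: int
    axis_point_um: np.ndarray = None   # 3D axis through the nucleus
    axis_dir_um: np.ndarray = None     # unit direction, µm frame
    half_length_um: float = 0.0        # plausible cell half length


def _detect_nuclei(stack: ImageStack, config: PipelineConfig,
                   min_voxels: int = 40):
    mask = stack.nucleus_channel > \
        config.nucleus_threshold * stack.nucleus_channel.max()
    labels, n = ndimage.label(mask)
    seeds = []
    for lab in range(1, n + 1):
        sel = labels == lab
        count = int(sel.sum())
        if count < min_voxels:
            continue
        zz, yy, xx = np.nonzero(sel)
        areas = np.bincount(zz)
        z0 = int(np.argmax(areas))
        slice_mask = sel[z0]
        try:
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                geom = extract_nucleus_geometry(slice_mask)
        except ValueError:
            continue
        sx, sy, sz = stack.spacing
        pts_um = np.column_stack([xx * sx, yy * sy, zz * sz])
        centroid_um = pts_um.mean(axis=0)
        if len(pts_um) > 3:
            _, vecs = np.linalg.eigh(np.cov((pts_um - centroid_um).T))
            axis_dir = vecs[:, -1]
            nucleus_half = float(np.abs(
                (pts_um - centroid_um) @ axis_dir).max())
        else:
            axis_dir = np.array([0.0, 1.0, 0.0])
            nucleus_half = 1.0
        seeds.append(_Seed(label=lab,
                           centroid_xyz=np.array([xx.mean(), yy.mean(),
                                                  zz.mean()]),
                           seed_slice=z0, geometry=geom,
                           voxels=count,
                           axis_point_um=centroid_um,
                           axis_dir_um=axis_dir,
                           half_length_um=min(
                               nucleus_half * config.nucleus_to_cell_length,
                               config.expected_half_length_px * sx)))
    return seeds, labels


# ---------------------------------------------------------------------------
# geometric segment attribution between neighboring cells
# ---------------------------------------------------------------------------

def _axis_distance(points, center, vector, half_length):
    """2D distance to a finite axis segment of the given half length:
    perpendicular offset plus any axial overshoot beyond the tips."""
    v = unit(vector)
    rel = points - center
    perp = np.abs(rel[:, 0] * v[1] - rel[:, 1] * v[0])
    along = np.abs(rel @ v)
    return perp + np.maximum(0.0, along - half_length)


def _axis_distance_3d(points_um, seed: _Seed):
    """Distance (µm) of 3D points to a cell's finite nucleus axis.

    The axis runs through the 3D nucleus centroid along its principal
    direction with the cell's plausible half length, so a neighbor
    whose (x, y) track coincides but which lies at a different depth is
    correctly far away.
    """
    rel = points_um - seed.axis_point_um
    along = rel @ seed.axis_dir_um
    along_c = np.clip(along, -seed.half_length_um, seed.half_length_um)
    closest = seed.axis_point_um + along_c[:, None] * seed.axis_dir_um
    return np.linalg.norm(points_um - closest, axis=1)


def _filter_segments_for_cell(segments, geom, own_seed, others, z,
                              spacing, image, derivs, config):
    """Classify segments for one cell and resolve neighbors.

    A segment's points are compared, in 3D, against this cell's nucleus
    axis and every neighbor's; points mostly nearer a neighbor mark the
    segment as that cell's edge (dropped, class B), a mixed segment is a
    shared edge (class C) split at the auxiliary-line point with this
    cell's half kept.  The surviving segments keep their intensity-based
    class labels for gap typing.
    """
    sx, sy, sz = spacing
    min_run = 5       # px of consecutive neighbor-won points to cut
    kept = []
    for seg in segments:
        cls = classify_edge(seg, image, geom, derivatives=derivs,
                            tail_half_angle_deg=config.tail_half_angle_deg)
        pts = seg.points
        pts_um = np.column_stack([pts[:, 0] * sx, pts[:, 1] * sy,
                                  np.full(len(pts), z * sz)])
        if own_seed is not None:
            own = _axis_distance_3d(pts_um, own_seed)
        else:
            own = _axis_distance(pts, geom.center, geom.cell_vector,
                                 config.expected_half_length_px) * sx
        win = np.zeros(len(pts), dtype=bool)
        for og in others:
            win |= _axis_distance_3d(pts_um, og) + 0.5 < own
        if not win.any():
            if cls == "B":
                seg.edge_class = "B"
            kept.append(seg)
            continue
        if win.mean() > 0.9:
            seg.edge_class = "B"
            continue
        # point-level splitting: cut out maximal runs the neighbor wins
        # (the cut point is where the attribution flips, the discrete
        # analogue of splitting a shared edge at the auxiliary line);
        # the surviving pieces are touching edges, so their gaps type II
        cut = np.zeros(len(pts), dtype=bool)
        start = None
        for i, w in enumerate(np.r_[win, False]):
            if w and start is None:
                start = i
            elif not w and start is not None:
                if i - start >= min_run:
                    cut[start:i] = True
                start = None
        if not cut.any():
            kept.append(seg)
            continue
        piece_start = None
        for i, c in enumerate(np.r_[cut, True]):
            if not c and piece_start is None:
                piece_start = i
            elif c and piece_start is not None:
                if i - piece_start >= config.min_segment_length:
                    kept.append(EdgeSegment(
                        points=pts[piece_start:i].copy(),
                        edge_class="C", side=seg.side, part=seg.part))
                piece_start = None
    return kept


# ---------------------------------------------------------------------------
# per-cell segmentation
# ---------------------------------------------------------------------------

def _carried_geometry(base: NucleusGeometry, center_xy) -> NucleusGeometry:
    c = np.asarray(center_xy, float)
    v = base.cell_vector
    half = max(np.linalg.norm(base.endpoints[1] - base.endpoints[0]) / 2,
               2.0)
    return NucleusGeometry(center=c,
                           skeleton=np.array([c - half * v, c + half * v]),
                           endpoints=np.array([c - half * v,
                                               c + half * v]),
                           cell_vector=v,
                           low_anisotropy=base.low_anisotropy,
                           mask=None)


def _segments_near(segments, center, radius):
    out = []
    for seg in segments:
        d = np.linalg.norm(seg.points - center, axis=1)
        if d.min() <= radius:
            out.append(seg)
    return out


def _seed_boundary(blocking, geom, nucleus_mask, image, config):
    """Close the boundary on a slice without stability information."""
    by_id = {s.segment_id: s for s in blocking.segments}
    fills = []
    for gap in blocking.gaps:
        fill = None
        if gap.gap_type == "II":
            grown = laplace_verify_pca(
                image, blocking.rays,
                nucleus_mask if nucleus_mask is not None
                else np.zeros(image.shape, bool),
                blocking, window=config.laplace_window_px, gap=gap,
                group_deg=config.laplace_ray_group_deg)
            if grown is not None and len(grown) >= 2:
                fill = GapFill(gap_type="II", fill_points=grown.points,
                               provenance="pca-grown")
        if fill is None:
            e1, e2 = by_id.get(gap.left_segment), by_id.get(
                gap.right_segment)
            if e1 is None or e2 is None:
                continue
            try:
                fill = bilateral_spline_interpolate(
                    e1, e2, center=geom.center, lc0=config.lc0,
                    max_gap_span_factor=config.max_gap_span_factor,
                    max_junctions=12)
            except (GapTooWideError, ValueError):
                continue
            fill.gap_type = gap.gap_type
        fills.append(fill)
    return close_boundary(blocking, fills, center=geom.center,
                          max_gap_angle_deg=config.max_gap_angle_deg,
                          smooth_window=config.contour_smooth_window)


def _segment_cell(stack, cache, seed, nucleus_labels, others_by_slice,
                  config) -> CellRecord:
    record = CellRecord(cell_id=seed.label,
                        seed_voxel=tuple(seed.centroid_xyz))
    nz = stack.cell_channel.shape[0]
    reach = config.lc0 * (1 + config.lc1) + 10.0
    boundaries = {}

    def process(z, geom, prev_deque):
        filtered, segments, derivs = cache(z)
        near = _segments_near(segments, geom.center, reach)
        others = others_by_slice(z, seed.label)
        near = _filter_segments_for_cell(
            list(near), geom, seed, others, z, stack.spacing,
            filtered, derivs, config)
        nuc_mask = None
        if geom.mask is not None:
            nuc_mask = geom.mask
            near = remove_inner_edges(near, nuc_mask, dilation=1,
                                      min_fraction=0.5)
        if not near:
            return None
        if prev_deque:
            result = propagate_boundary(
                list(prev_deque), near, geom, config,
                fills_hook=lambda blocking, gap: _laplace_fill(
                    blocking, gap, filtered, nuc_mask, config))
            if isinstance(result, FallbackRequest):
                log.info("stage=propagate cell=%d slice=%d outcome=%s",
                         seed.label, z, result.reason)
                return None
            return result
        rays = cast_ray_fan(
            geom, angular_step=config.angular_step_deg, lc0=config.lc0,
            lc1=config.lc1, clamp=config.clamp_ray_length,
            symmetric=config.ray_bound_symmetric,
            tail_half_angle_deg=config.tail_half_angle_deg)
        blocking = block_edges(rays, near, gap_min_run=config.gap_min_run)
        if not blocking.retained:
            return None
        return _seed_boundary(blocking, geom, nuc_mask, filtered, config)

    def geometry_for(z, prev_boundary):
        slice_mask = nucleus_labels[z] == seed.label
        if slice_mask.sum() >= 9:
            try:
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    g = extract_nucleus_geometry(slice_mask)
                if not g.low_anisotropy:
                    return g
                g.cell_vector = seed.geometry.cell_vector
                return g
            except ValueError:
                pass
        center = (prev_boundary.contour.mean(axis=0)
                  if prev_boundary is not None
                  else seed.geometry.center)
        return _carried_geometry(seed.geometry, center)

    z0 = seed.seed_slice
    b0 = None
    for dz in (0, 1, -1, 2, -2):
        z_try = z0 + dz
        if not (0 <= z_try < nz):
            continue
        geom_try = seed.geometry if dz == 0 \
            else geometry_for(z_try, None)
        try:
            b0 = process(z_try, geom_try, None)
        except UnsegmentableSliceError as err:
            record.error = f"seed slice unsegmentable: {err}"
            b0 = None
        if b0 is not None:
            z0 = z_try
            record.error = None
            break
    if b0 is None:
        record.error = record.error or "no boundary on the seed slice"
        log.info("stage=seed cell=%d slice=%d outcome=failed",
                 seed.label, z0)
        return record
    boundaries[z0] = b0
    log.info("stage=seed cell=%d slice=%d outcome=ok", seed.label, z0)

    def interior_peak(z, boundary):
        """Mean filtered intensity in a small patch at the boundary
        centroid (a mean is robust to read noise, unlike a patch max)."""
        img = cache(z)[0]
        cx, cy = np.round(boundary.contour.mean(axis=0)).astype(int)
        y0, y1 = max(cy - 1, 0), min(cy + 2, img.shape[0])
        x0, x1 = max(cx - 1, 0), min(cx + 2, img.shape[1])
        patch = img[y0:y1, x0:x1]
        return float(patch.mean()) if patch.size else 0.0

    # axial extent by the half-maximum criterion: stop once the
    # interior peak drops below half the local reference (the brightest
    # of the few nearest accepted slices, which also tracks the
    # depth-dependent intensity falloff), cutting the cap where the
    # fluorophore's edge band crosses its half level
    amp0 = interior_peak(z0, b0)
    min_area = 4.0
    max_misses = 2   # a slice ruined by a touching neighbor is skipped
    for direction in (1, -1):
        prev = deque([b0], maxlen=config.stable_slices)
        ref_peaks = deque([amp0], maxlen=3)
        misses = 0
        z = z0 + direction
        while 0 <= z < nz:
            geom = geometry_for(z, prev[-1])
            try:
                b = process(z, geom, prev)
            except UnsegmentableSliceError:
                b = None
            if b is None or b.area < min_area:
                misses += 1
                if misses > max_misses:
                    break
                z += direction
                continue
            peak = interior_peak(z, b)
            if ref_peaks and peak < \
                    config.half_max_fraction * max(ref_peaks):
                break
            misses = 0
            ref_peaks.append(peak)
            boundaries[z] = b
            prev.append(b)
            log.info("stage=propagate cell=%d slice=%d outcome=ok",
                     seed.label, z)
            z += direction

    record.boundaries = boundaries
    sx, sy, sz = stack.spacing
    try:
        volume = stack_boundaries(boundaries, z_step=sz, xy_pixel=sx,
                                  shape=stack.cell_channel.shape,
                                  closing=True)
        record.volume = volume
        mesh = laplacian_smooth(extract_surface(volume),
                                iterations=config.smooth_iterations,
                                strength=config.smooth_strength)
        record.mesh = mesh
        region = project_and_fit(volume,
                                 min_axis_ratio=config.min_axis_ratio)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            beta = in_plane_angle(region)
        L, W, T = length_width_thickness(
            volume, region, central_fraction=config.central_fraction)
        nuc_sel = nucleus_labels == seed.label
        nuc_vol = BinaryVolume(nuc_sel, stack.spacing)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            alpha_nuc = tilt_angle(nuc_vol.surface_coords())
            alpha_cell = tilt_angle(
                BinaryVolume(volume.voxels,
                             volume.spacing).surface_coords())
        alpha = alpha_nuc if np.isfinite(alpha_nuc) else alpha_cell
        record.morphometry = Morphometry(
            length=L, width=W, thickness=T, beta=beta, alpha=alpha,
            flags={"alpha_cell": alpha_cell, "alpha_nucleus": alpha_nuc,
                   "n_slices": len(boundaries)})
        # plausibility gates: a trustworthy fusiform reconstruction
        # spans several slices, has a coherent column of voxels, and
        # its projected orientation agrees with its own nucleus's axis
        # (VSMC nuclei are co-oriented with their cells); anything else
        # is reported as a failure, not as numbers
        beta_nuc = None
        if seed.axis_dir_um is not None and \
                np.linalg.norm(seed.axis_dir_um[:2]) > 1e-6:
            from .geometry import beta_of_vector
            beta_nuc = beta_of_vector(seed.axis_dir_um[0],
                                      seed.axis_dir_um[1])
        if len(boundaries) < 5 or T < 3 * sz:
            record.error = ("degenerate reconstruction "
                            f"({len(boundaries)} slices, T={T:.2f} µm); "
                            "tracking likely lost the cell")
            log.info("stage=morphometry cell=%d slice=-1 outcome=degenerate",
                     seed.label)
        elif beta_nuc is not None and np.isfinite(beta) and \
                min(abs(beta - beta_nuc),
                    180 - abs(beta - beta_nuc)) > \
                config.beta_consistency_deg:
            record.error = (
                f"cell orientation {beta:.1f} deg disagrees with its "
                f"nucleus axis {beta_nuc:.1f} deg; boundary likely "
                "leaked onto a neighbor")
            log.info("stage=morphometry cell=%d slice=-1 "
                     "outcome=inconsistent", seed.label)
        else:
            log.info("stage=morphometry cell=%d slice=-1 outcome=ok",
                     seed.label)
    except (ValueError, UnsegmentableSliceError) as err:
        record.error = f"reconstruction failed: {err}"
        log.info("stage=reconstruct cell=%d slice=-1 outcome=failed",
                 seed.label)
    return record


def _laplace_fill(blocking, gap, image, nucleus_mask, config):
    if gap.gap_type != "II":
        return None
    grown = laplace_verify_pca(
        image, blocking.rays,
        nucleus_mask if nucleus_mask is not None
        else np.zeros(image.shape, bool),
        blocking, window=config.laplace_window_px, gap=gap,
        group_deg=config.laplace_ray_group_deg)
    if grown is None or len(grown) < 2:
        return None
    return GapFill(gap_type="II", fill_points=grown.points,
                   provenance="pca-grown")


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def segment_stack(stack: ImageStack, roi=None, seed_nuclei=None,
                  config: PipelineConfig = None) -> list:
    """Segment every seeded cell of a two-channel stack.

    ``roi`` is an optional (N, 2) polygon in (x, y) pixels restricting
    which nuclei are seeded; ``seed_nuclei`` an optional list of (x, y)
    or (x, y, z) positions selecting specific nuclei (nearest detected
    nucleus wins); with neither, every detected nucleus is a seed.
    Per-cell failures are recorded on their CellRecord, never fatal.
    """
    config = config or PipelineConfig()
    seeds, labels = _detect_nuclei(stack, config)
    if roi is not None:
        poly = Polygon(np.asarray(roi, float))
        seeds = [s for s in seeds if poly.buffer(1e-9).contains(
            Point(s.centroid_xyz[0], s.centroid_xyz[1]))]
    if seed_nuclei is not None:
        chosen = []
        for p in np.atleast_2d(np.asarray(seed_nuclei, float)):
            if not seeds:
                break
            d = [np.linalg.norm(s.centroid_xyz[:2] - p[:2])
                 for s in seeds]
            chosen.append(seeds[int(np.argmin(d))])
        seeds = list({id(s): s for s in chosen}.values())
    if not seeds:
        log.warning("no seed nuclei selected; returning empty result")
        return []

    cache = _SliceCache(stack, config)

    def others_by_slice(z, own_label):
        return [s for s in seeds if s.label != own_label]

    records = []
    for seed in seeds:
        try:
            records.append(_segment_cell(stack, cache, seed, labels,
                                         others_by_slice, config))
        except Exception as err:   # noqa: BLE001 - batch must survive
            rec = CellRecord(cell_id=seed.label,
                             seed_voxel=tuple(seed.centroid_xyz),
                             error=f"unexpected failure: {err!r}")
            log.exception("stage=cell cell=%d slice=-1 outcome=error",
                          seed.label)
            records.append(rec)
    return records


def phantom_tilt_estimates(semi_axes, tilt_deg, grid_margin: int = 14):
    """Voxel- and mesh-based tilt estimates for one rigid phantom.

    Returns (alpha_cov, alpha_normcov, alpha_mesh): the tilt measured on
    the voxelized solid's surface voxels with the plain and the
    size-normalized covariance estimator, and on the mesh vertices.
    """
    a = semi_axes[0]
    n = int(2 * np.ceil(a)) + grid_margin
    spec = PhantomSpec(semi_axes=tuple(semi_axes), tilt_deg=tilt_deg,
                       grid_shape=(n, n, n))
    mesh = make_ellipsoid_mesh(spec)
    vol = voxelize(mesh, spec.grid_shape)
    coords = vol.surface_coords()
    return (tilt_angle(coords, normalized=False),
            tilt_angle(coords, normalized=True),
            tilt_angle(mesh.vertices, normalized=False))


def validate_tilt(config: PipelineConfig = None, seed: int = 0,
                  tilts=(10, 20, 30, 40, 50, 60),
                  long_axes_px=(70, 40),
                  deformations=(0, 10, 20, 30),
                  deformed_tilt: float = 30.0) -> pd.DataFrame:
    """Phantom validation sweep of the tilt-angle estimator.

    Rigid ellipsoids with 70 px and 40 px long axes are voxelized at
    each predefined tilt and measured with both estimator variants;
    additionally a bent phantom series compares the tilt of the
    deformed mesh with that of its voxelization.  Returns a tidy table
    with one row per case (deterministic; ``seed`` only recorded).
    """
    del config
    rows = []
    for long_axis in long_axes_px:
        semi = (long_axis / 2.0, long_axis / 7.0, long_axis / 7.0)
        for tilt in tilts:
            a_cov, a_norm, a_mesh = phantom_tilt_estimates(semi, tilt)
            for estimator, value in (("cov", a_cov),
                                     ("normcov", a_norm)):
                rows.append({
                    "kind": "rigid", "long_axis_px": long_axis,
                    "predefined_deg": tilt, "estimator": estimator,
                    "measured_deg": value,
                    "relative_error": abs(value - tilt) / tilt,
                    "deformation_deg": 0, "seed": seed,
                })
    for deform in deformations:
        a = long_axes_px[0]
        n = int(2 * np.ceil(a / 2.0)) + 40
        spec = PhantomSpec(semi_axes=(a / 2.0, a / 7.0, a / 7.0),
                           tilt_deg=deformed_tilt,
                           deformation_deg=deform,
                           grid_shape=(n, n, n))
        mesh = make_ellipsoid_mesh(spec)
        vol = voxelize(mesh, spec.grid_shape)
        a_mesh = tilt_angle(mesh.vertices, normalized=False)
        a_vox = tilt_angle(vol.surface_coords(), normalized=False)
        rows.append({
            "kind": "deformed", "long_axis_px": a,
            "predefined_deg": deformed_tilt, "estimator": "cov",
            "measured_deg": a_vox, "mesh_deg": a_mesh,
            "relative_error": abs(a_vox - a_mesh) / max(a_mesh, 1e-9),
            "deformation_deg": deform, "seed": seed,
        })
    return pd.DataFrame(rows)
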