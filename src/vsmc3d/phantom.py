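"""Virtual phantoms and synthetic image stacks.

Two kinds of ground-truth data are produced here:

* an ellipsoid phantom — a triangle-mesh ellipsoid at a predefined tilt,
  optionally bent at one end, voxelized into a solid binary volume — used
  to validate the tilt-angle estimator against a known answer;
* synthetic two-channel z-stacks of fusiform cells with ellipsoidal
  nuclei, bimodal in-plane orientations, small tilts, depth intensity
  falloff and additive read noise, with exact per-cell truth records, so
  the whole segmentation pipeline can be exercised without microscope
  data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import tifffile
import trimesh

from .config import CellPopulation
from .geometry import (
    Ellipsoid,
    central_chord_mean_factor,
    orientation_matrix,
    rot_x,
    unit,
    wrap_beta,
)


# ---------------------------------------------------------------------------
# phantom spec and mesh construction
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of one virtual ellipsoid phantom.

    ``semi_axes`` are (a, b, c) in voxels with a >= b > 0 along the long
    axis / in-plane width / thickness; ``tilt_deg`` rotates the long axis
    out of the XY plane, ``in_plane_deg`` within it; ``deformation_deg``
    bends one end about the X axis (0 = rigid); ``grid_shape`` is the
    (z, y, x) voxel grid the phantom is rendered into.
    """

    semi_axes: tuple = (35.0, 10.0, 10.0)
    tilt_deg: float = 0.0
    in_plane_deg: float = 0.0
    deformation_deg: float = 0.0
    grid_shape: tuple = (96, 96, 96)

    def __post_init__(self):
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValueError("semi-axes must satisfy a >= b >= c > 0")
        if not (0 <= self.tilt_deg < 90):
            raise ValueError("tilt_deg must lie in [0, 90)")
        if not (-90 <= self.in_plane_deg < 90):
            raise ValueError("in_plane_deg must lie in [-90, 90)")
        if not (0 <= self.deformation_deg < 90):
            raise ValueError("deformation_deg must lie in [0, 90)")


def make_ellipsoid_mesh(spec: PhantomSpec,
                        azimuthal: int = 64,
                        polar: int = 32) -> trimesh.Trimesh:
    """Triangle mesh of the rotated phantom ellipsoid, centered at origin.

    The unrotated long axis lies along +Y; the mesh is rotated by
    ``tilt_deg`` out of the XY plane and then by ``in_plane_deg`` within
    it, so its long axis equals the composed rotation applied to +Y.
    """
    a, b, c = spec.semi_axes
    sphere = trimesh.creation.uv_sphere(radius=1.0, count=(polar, azimuthal))
    v = sphere.vertices.copy()
    # place the sphere poles (z = +-1) on the long axis (+-Y) so the tips
    # of the phantom are densely sampled, as a spindle-shaped cell's are
    verts = np.column_stack([b * v[:, 0], a * v[:, 2], c * v[:, 1]])
    R = orientation_matrix(spec.in_plane_deg, spec.tilt_deg)
    mesh = trimesh.Trimesh(vertices=verts @ R.T, faces=sphere.faces,
                           process=False)
    if mesh.volume < 0:
        mesh.invert()
    if spec.deformation_deg:
        mesh = deform_ellipsoid(mesh, spec.deformation_deg)
    return mesh


def deform_ellipsoid(mesh: trimesh.Trimesh, deformation_deg: float,
                     end_fraction: float = 0.8) -> trimesh.Trimesh:
    """Bend one end of the ellipsoid about the X axis through its pole.

    Vertices in the last ``1-end_fraction`` of the long axis are rotated
    rigidly by ``deformation_deg`` about a pole-anchored X axis, the
    opposite end is held fixed, and every interior vertex displacement is
    the harmonic (graph-Laplacian) interpolation of those two boundary
    conditions, i.e. each interior displacement equals the mean of its
    mesh neighbors'.
    """
    if not mesh.is_watertight:
        raise ValueError("deformation requires a watertight mesh")
    if not (0 <= deformation_deg < 90):
        raise ValueError("deformation_deg must lie in [0, 90)")
    if deformation_deg == 0:
        return mesh.copy()

    v = mesh.vertices.copy()
    centroid = v.mean(axis=0)
    centered = v - centroid
    # long axis from the vertex covariance (exact for the ellipsoid)
    _, vecs = np.linalg.eigh(np.cov(centered.T))
    axis = vecs[:, -1]
    t = centered @ axis
    t = t / np.abs(t).max()

    free = t >= end_fraction
    fixed = t <= -end_fraction
    if not free.any() or not fixed.any():
        raise ValueError("end_fraction leaves an empty boundary ring")

    pole = v[np.argmax(t)]
    R = rot_x(deformation_deg)
    disp = np.zeros_like(v)
    disp[free] = (v[free] - pole) @ R.T + pole - v[free]

    n = len(v)
    edges = mesh.edges_unique
    A = sp.coo_matrix(
        (np.ones(2 * len(edges)),
         (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = sp.diags(deg) - A

    boundary = free | fixed
    interior = ~boundary
    Lii = L[interior][:, interior]
    Lib = L[interior][:, boundary]
    rhs = -Lib @ disp[boundary]
    disp_interior = spla.spsolve(Lii.tocsc(), rhs)
    disp[interior] = np.atleast_2d(disp_interior)

    return trimesh.Trimesh(vertices=v + disp, faces=mesh.faces.copy(),
                           process=False)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

@dataclass
class BinaryVolume:
    """A 3D boolean voxel grid with physical spacing.

    ``voxels`` is indexed [z, y, x]; ``spacing`` is (sx, sy, sz) in µm.
    """

    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D grid")

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_um3(self) -> float:
        sx, sy, sz = self.spacing
        return self.count * sx * sy * sz

    def surface_mask(self) -> np.ndarray:
        from scipy import ndimage
        eroded = ndimage.binary_erosion(self.voxels)
        return self.voxels & ~eroded

    def coords(self, mask=None) -> np.ndarray:
        """(N, 3) physical (x, y, z) coordinates of foreground voxels."""
        if mask is None:
            mask = self.voxels
        zz, yy, xx = np.nonzero(mask)
        sx, sy, sz = self.spacing
        return np.column_stack([xx * sx, yy * sy, zz * sz]).astype(float)

    def surface_coords(self) -> np.ndarray:
        return self.coords(self.surface_mask())

    def write_tiff(self, path) -> None:
        tifffile.imwrite(path, self.voxels.astype(np.uint8) * 255)


def voxelize(mesh: trimesh.Trimesh, grid_shape,
             origin=None) -> BinaryVolume:
    """Solid voxelization of a closed mesh by per-column scanline parity.

    For every (x, y) voxel column the z values where a vertical line
    crosses the surface are collected; voxel centers between successive
    crossing pairs are interior. ``grid_shape`` is (nz, ny, nx); by
    default the mesh centroid is placed at the grid center.
    """
    nz, ny, nx = grid_shape
    verts = np.asarray(mesh.vertices, dtype=float)
    if origin is None:
        center = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0])
        verts = verts - verts.mean(axis=0) + center
    else:
        verts = verts - np.asarray(origin, dtype=float)

    lo, hi = verts.min(axis=0), verts.max(axis=0)
    if (lo < -0.5).any() or (hi > np.array([nx, ny, nz]) - 0.5).any():
        raise ValueError(
            f"mesh extent [{lo}, {hi}] exceeds grid (z,y,x)={grid_shape}; "
            "enlarge the grid or supply an origin")

    tris = verts[mesh.faces]  # (F, 3, 3) as (x, y, z)
    # tiny irrational offset of the sampling lattice avoids rays through
    # triangle edges/vertices (degenerate parity)
    ex, ey = 1e-4 * math.sqrt(2), 1e-4 * math.sqrt(3)

    cols, zs = [], []
    for p0, p1, p2 in tris:
        xmin = int(np.ceil(min(p0[0], p1[0], p2[0]) - ex))
        xmax = int(np.floor(max(p0[0], p1[0], p2[0]) - ex))
        ymin = int(np.ceil(min(p0[1], p1[1], p2[1]) - ey))
        ymax = int(np.floor(max(p0[1], p1[1], p2[1]) - ey))
        if xmax < xmin or ymax < ymin:
            continue
        gx, gy = np.meshgrid(np.arange(xmin, xmax + 1),
                             np.arange(ymin, ymax + 1), indexing="ij")
        px = gx.ravel() + ex
        py = gy.ravel() + ey
        # barycentric inside test in the XY projection
        d = (p1[1] - p2[1]) * (p0[0] - p2[0]) + (p2[0] - p1[0]) * (p0[1] - p2[1])
        if abs(d) < 1e-12:
            continue  # vertical triangle: no transversal crossing
        w0 = ((p1[1] - p2[1]) * (px - p2[0]) + (p2[0] - p1[0]) * (py - p2[1])) / d
        w1 = ((p2[1] - p0[1]) * (px - p2[0]) + (p0[0] - p2[0]) * (py - p2[1])) / d
        w2 = 1.0 - w0 - w1
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        z = w0[inside] * p0[2] + w1[inside] * p1[2] + w2[inside] * p2[2]
        cols.append(gx.ravel()[inside] * ny + gy.ravel()[inside])
        zs.append(z)

    vox = np.zeros((nz, ny, nx), dtype=bool)
    if cols:
        col = np.concatenate(cols)
        z = np.concatenate(zs)
        order = np.lexsort((z, col))
        col, z = col[order], z[order]
        starts = np.r_[0, np.nonzero(np.diff(col))[0] + 1, len(col)]
        for s, e in zip(starts[:-1], starts[1:]):
            crossings = z[s:e]
            cx, cy = divmod(int(col[s]), ny)
            for k in range(0, len(crossings) - 1, 2):
                z0 = int(np.ceil(crossings[k]))
                z1 = int(np.floor(crossings[k + 1]))
                if z1 >= z0:
                    vox[z0:z1 + 1, cy, cx] = True
    return BinaryVolume(vox, (1.0, 1.0, 1.0))


# ---------------------------------------------------------------------------
# synthetic multi-cell stacks
# ---------------------------------------------------------------------------

@dataclass
class CellTruth:
    """Exact geometry of one generated cell.

    Lengths are µm; ``length``/``width``/``thickness`` are the values the
    morphometric definitions yield on the continuous solid (projected
    long-axis extent, mean central perpendicular chord, longest vertical
    chord), so recovered measurements are directly comparable.
    """

    cell_id: int
    center_um: tuple
    semi_axes_um: tuple          # (L/2 along axis, W/2 in-plane, T/2)
    beta_deg: float
    alpha_deg: float
    length: float
    width: float
    thickness: float
    amplitude: float
    nucleus_semi_axes_um: tuple
    contours_px: dict = field(default_factory=dict, repr=False)

    def body(self) -> Ellipsoid:
        return Ellipsoid.from_angles(self.center_um, self.semi_axes_um,
                                     self.beta_deg, self.alpha_deg)

    def nucleus(self) -> Ellipsoid:
        return Ellipsoid.from_angles(self.center_um,
                                     self.nucleus_semi_axes_um,
                                     self.beta_deg, self.alpha_deg)


@dataclass
class SyntheticStack:
    """Two-channel synthetic z-stack plus exact per-cell truth records."""

    cell_channel: np.ndarray     # (Z, Y, X) float32
    nucleus_channel: np.ndarray
    truth: list
    seed: int
    spacing: tuple               # (sx, sy, sz) µm

    def write(self, directory) -> None:
        import os
        os.makedirs(directory, exist_ok=True)
        tifffile.imwrite(os.path.join(directory, "cell.tif"),
                         self.cell_channel)
        tifffile.imwrite(os.path.join(directory, "nucleus.tif"),
                         self.nucleus_channel)
        records = []
        for t in self.truth:
            records.append({
                "cell_id": t.cell_id,
                "center_um": list(t.center_um),
                "semi_axes_um": list(t.semi_axes_um),
                "beta_deg": t.beta_deg,
                "alpha_deg": t.alpha_deg,
                "length": t.length,
                "width": t.width,
                "thickness": t.thickness,
                "amplitude": t.amplitude,
                "nucleus_semi_axes_um": list(t.nucleus_semi_axes_um),
                "contours_px": {str(z): np.asarray(c).tolist()
                                for z, c in t.contours_px.items()},
            })
        with open(os.path.join(directory, "truth.json"), "w") as fh:
            json.dump({"seed": self.seed, "spacing": list(self.spacing),
                       "cells": records}, fh)


def sample_inplane_angles(n: int, population: CellPopulation = None,
                          rng=None) -> np.ndarray:
    """Draw n in-plane angles from the two-mode orientation mixture."""
    population = population or CellPopulation()
    rng = np.random.default_rng(rng)
    comp = rng.choice(len(population.beta_means), size=n,
                      p=np.asarray(population.beta_weights, float))
    means = np.asarray(population.beta_means)[comp]
    sds = np.asarray(population.beta_sds)[comp]
    return np.array([wrap_beta(b) for b in rng.normal(means, sds)])


def _sample_cell_geometry(population: CellPopulation, rng,
                          max_z_extent_um: float):
    """One cell's (semi_axes, beta, alpha); alpha redrawn until the tilted
    body's vertical extent fits in the stack."""
    def trunc_normal(mean, sd, lo):
        for _ in range(100):
            v = rng.normal(mean, sd)
            if v > lo:
                return v
        return max(mean, lo * 1.5)

    L = trunc_normal(population.length_mean, population.length_sd,
                     population.length_mean * 0.3)
    W = trunc_normal(population.width_mean, population.width_sd,
                     population.width_mean * 0.4)
    T = trunc_normal(population.thickness_mean, population.thickness_sd,
                     population.thickness_mean * 0.4)
    beta = float(sample_inplane_angles(1, population, rng)[0])
    for _ in range(200):
        alpha = abs(rng.normal(0.0, population.alpha_halfnormal_sd))
        z_extent = L * math.sin(math.radians(alpha)) + T
        if z_extent <= max_z_extent_um and alpha < 89.0:
            break
    else:
        alpha = 0.0
    semi = (L / 2.0, W / 2.0, T / 2.0)
    return semi, beta, alpha


def _render_ellipsoid(channel: np.ndarray, ell: Ellipsoid, amplitude: float,
                      spacing, edge_halfwidth_um: float,
                      depth_decay_per_um: float) -> None:
    """Add a raised-cosine-edged solid ellipsoid into ``channel`` (max)."""
    sx, sy, sz = spacing
    nz, ny, nx = channel.shape
    ext = ell.bounding_extents() + 2.5 * edge_halfwidth_um
    lo = ell.center - ext
    hi = ell.center + ext
    ix0, ix1 = max(0, int(lo[0] / sx)), min(nx - 1, int(np.ceil(hi[0] / sx)))
    iy0, iy1 = max(0, int(lo[1] / sy)), min(ny - 1, int(np.ceil(hi[1] / sy)))
    iz0, iz1 = max(0, int(lo[2] / sz)), min(nz - 1, int(np.ceil(hi[2] / sz)))
    if ix1 < ix0 or iy1 < iy0 or iz1 < iz0:
        return
    zz, yy, xx = np.meshgrid(np.arange(iz0, iz1 + 1) * sz,
                             np.arange(iy0, iy1 + 1) * sy,
                             np.arange(ix0, ix1 + 1) * sx, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    d = ell.signed_distance(pts).reshape(xx.shape)
    h = edge_halfwidth_um
    prof = np.clip((d + h) / (2.0 * h), 0.0, 1.0)
    intensity = amplitude * 0.5 * (1.0 + np.cos(np.pi * prof))
    if depth_decay_per_um:
        intensity = intensity * np.exp(-depth_decay_per_um * zz)
    view = channel[iz0:iz1 + 1, iy0:iy1 + 1, ix0:ix1 + 1]
    np.maximum(view, intensity.astype(channel.dtype), out=view)


def make_cell_stack(n_cells: int,
                    geometry_ranges: CellPopulation = None,
                    noise_sd: float = 0.03,
                    overlap_fraction: float = 0.25,
                    seed: int = 0,
                    shape=(96, 384, 384),
                    spacing=(0.412, 0.412, 0.25),
                    edge_halfwidth_um: float = 0.4,
                    depth_decay_per_um: float = 0.015,
                    contour_points: int = 90,
                    max_tries: int = 2000) -> SyntheticStack:
    """Generate a deterministic synthetic two-channel z-stack.

    ``overlap_fraction`` of the cells are placed as crossing pairs (the
    second cell's center sits on the first cell's long axis with an
    in-plane angle from the opposite orientation mode) so that occlusion
    gaps occur; the rest are placed with disjoint nuclei at random.
    Raises if the requested number of cells cannot be packed.
    """
    population = geometry_ranges or CellPopulation()
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    sx, sy, sz = spacing
    field_um = np.array([nx * sx, ny * sy, nz * sz])

    geoms = []    # (semi, beta, alpha, center)
    n_paired = int(round(overlap_fraction * n_cells / 2.0)) * 2

    # deterministic quasi-uniform directions for surface sampling
    k = np.arange(400)
    phi = np.arccos(1 - 2 * (k + 0.5) / len(k))
    lam = np.pi * (1 + 5**0.5) * k
    sphere_dirs = np.column_stack([np.sin(phi) * np.cos(lam),
                                   np.sin(phi) * np.sin(lam),
                                   np.cos(phi)])

    def nucleus_radius(semi):
        return semi[0] * population.nucleus_length_fraction

    def bodies_disjoint(ell_a, ell_b, clearance=0.3):
        """Solid cells may adhere but not interpenetrate beyond the
        allowance (a negative clearance mimics the slight squeeze of
        touching cells)."""
        for p, q in ((ell_a, ell_b), (ell_b, ell_a)):
            surf = q.center + (sphere_dirs
                               * np.maximum(q.semi + clearance, 0.1)) \
                @ q.axes.T
            if (p.rho(surf) < 1.0).any() or p.rho(q.center[None])[0] < 1:
                return False
        return True

    def fits(center, semi, beta, alpha, clearance=0.3):
        ell = Ellipsoid.from_angles(center, semi, beta, alpha)
        ext = ell.bounding_extents()
        margin = np.array([2.0, 2.0, 1.5 * sz])
        if (center - ext < margin).any() or \
           (center + ext > field_um - margin).any():
            return False
        r_new = nucleus_radius(semi)
        for other_semi, other_beta, other_alpha, other_center in geoms:
            if np.linalg.norm(center - other_center) < \
                    r_new + nucleus_radius(other_semi):
                return False
            other = Ellipsoid.from_angles(other_center, other_semi,
                                          other_beta, other_alpha)
            if not bodies_disjoint(ell, other, clearance):
                return False
        return True

    def random_center(semi, beta, alpha):
        ell = Ellipsoid.from_angles(np.zeros(3), semi, beta, alpha)
        ext = ell.bounding_extents()
        lo = ext + np.array([2.0, 2.0, 1.5 * sz])
        hi = field_um - lo
        if (hi <= lo).any():
            return None
        return rng.uniform(lo, hi)

    tries = 0
    while len(geoms) < n_cells:
        if tries > max_tries:
            raise ValueError(
                f"could not pack {n_cells} cells into a "
                f"{field_um.round(1)} µm field after {max_tries} tries")
        tries += 1
        remaining = n_cells - len(geoms)
        make_pair = len(geoms) < n_paired and remaining >= 2
        semi, beta, alpha = _sample_cell_geometry(
            population, rng, field_um[2] - 4.0 * sz)
        center = random_center(semi, beta, alpha)
        if center is None or not fits(center, semi, beta, alpha):
            continue
        if not make_pair:
            geoms.append((semi, beta, alpha, center))
            continue
        # partner crossing the first cell's tail region
        semi2, _, alpha2 = _sample_cell_geometry(
            population, rng, field_um[2] - 4.0 * sz)
        mode = 0 if beta >= 0 else 1   # opposite orientation mode
        beta2 = wrap_beta(rng.normal(population.beta_means[mode],
                                     population.beta_sds[mode]))
        # crossing partner: its tail slides over this cell's tail, so
        # the thin ends adhere — separated in depth by just past the sum
        # of the LOCAL half-thicknesses — and occlude each other in the
        # slices they share, without the solids interpenetrating
        axis = Ellipsoid.from_angles(center, semi, beta, alpha).long_axis
        axis2 = Ellipsoid.from_angles(np.zeros(3), semi2, beta2,
                                      alpha2).long_axis
        u_a = rng.uniform(0.5, 0.8)
        u_b = rng.uniform(0.4, 0.7)
        side = rng.choice([-1.0, 1.0])
        P = center + side * u_a * semi[0] * axis
        ha = semi[2] * np.sqrt(max(0.0, 1.0 - u_a**2))
        hb = semi2[2] * np.sqrt(max(0.0, 1.0 - u_b**2))
        geoms.append((semi, beta, alpha, center))
        placed_partner = False
        for dz_gap in (-0.5, 0.0, 0.5, 1.5):
            for sgn in (1.0, -1.0):
                for dsgn in (1.0, -1.0):
                    center2 = (P + np.array([0.0, 0.0,
                                             sgn * (ha + hb + dz_gap)])
                               - dsgn * u_b * semi2[0] * axis2)
                    if fits(center2, semi2, beta2, alpha2,
                            clearance=-0.8):
                        geoms.append((semi2, beta2, alpha2, center2))
                        placed_partner = True
                        break
                if placed_partner:
                    break
            if placed_partner:
                break
        if not placed_partner:
            geoms.pop()

    cell_channel = np.zeros(shape, dtype=np.float32)
    nucleus_channel = np.zeros(shape, dtype=np.float32)
    truth = []
    chord_factor = central_chord_mean_factor(0.5)
    for cid, (semi, beta, alpha, center) in enumerate(geoms):
        amplitude = float(rng.uniform(0.85, 1.0))
        body = Ellipsoid.from_angles(center, semi, beta, alpha)
        nuc_semi = (semi[0] * population.nucleus_length_fraction,
                    semi[1] * population.nucleus_width_fraction,
                    semi[2] * population.nucleus_thickness_fraction)
        nucleus = Ellipsoid.from_angles(center, nuc_semi, beta, alpha)
        _render_ellipsoid(cell_channel, body, amplitude, spacing,
                          edge_halfwidth_um, depth_decay_per_um)
        _render_ellipsoid(nucleus_channel, nucleus, 1.0, spacing,
                          min(edge_halfwidth_um, 0.4), depth_decay_per_um)

        _, p, q, major = body.shadow()
        contours = {}
        for iz in range(nz):
            c = body.z_section_contour(iz * sz, contour_points)
            if c is not None:
                contours[iz] = c / np.array([sx, sy])
        truth.append(CellTruth(
            cell_id=cid,
            center_um=tuple(center),
            semi_axes_um=tuple(semi),
            beta_deg=float(wrap_beta(np.degrees(np.arctan2(major[0],
                                                           major[1])))),
            alpha_deg=float(alpha),
            length=float(2 * p),
            width=float(2 * q * chord_factor),
            thickness=float(body.max_z_chord()),
            amplitude=amplitude,
            nucleus_semi_axes_um=nuc_semi,
            contours_px=contours,
        ))

    if noise_sd > 0:
        cell_channel += rng.normal(0.0, noise_sd,
                                   size=shape).astype(np.float32)
        nucleus_channel += rng.normal(0.0, noise_sd,
                                      size=shape).astype(np.float32)
        np.clip(cell_channel, 0.0, None, out=cell_channel)
        np.clip(nucleus_channel, 0.0, None, out=nucleus_channel)

    return SyntheticStack(cell_channel, nucleus_channel, truth,
                          seed=seed, spacing=spacing)
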