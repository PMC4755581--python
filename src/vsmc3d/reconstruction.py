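"""2D-to-3D reconstruction: stack per-slice contours into a volume and
extract a smoothed surface mesh.

The 3D body of a cell is the union of its filled per-slice boundaries
with small holes closed morphologically; the surface is a marching-cubes
iso-surface at 0.5 in physical coordinates, relaxed by iterative
Laplacian (umbrella) smoothing to remove the staircase of the slicing.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import trimesh
from scipy import ndimage
from skimage import draw, measure

from .edge_growing import Boundary2D
from .phantom import BinaryVolume


def stack_boundaries(boundaries, z_step: float, xy_pixel: float,
                     shape=None, closing: bool = True,
                     min_component_voxels: int = 4) -> BinaryVolume:
    """Rasterize and stack per-slice boundaries into a binary volume.

    ``boundaries`` maps slice index -> Boundary2D (a list is treated as
    slices 0..n-1; None entries are skipped).  Each contour is filled on
    its slice; a 3x3x3 morphological closing then bridges small gaps
    between slices and connected components smaller than
    ``min_component_voxels`` are discarded as noise.  Non-simple
    contours are rejected — they should have been repaired upstream.
    """
    if isinstance(boundaries, (list, tuple)):
        boundaries = {i: b for i, b in enumerate(boundaries)
                      if b is not None}
    if not boundaries:
        raise ValueError("no boundaries to stack")
    for z, b in boundaries.items():
        poly = b.polygon()
        if not (poly.is_valid and poly.is_simple):
            raise ValueError(f"non-simple contour on slice {z}")

    zmax = max(boundaries)
    if shape is None:
        xy_max = np.max([b.contour.max(axis=0)
                         for b in boundaries.values()], axis=0)
        shape = (zmax + 1, int(np.ceil(xy_max[1])) + 2,
                 int(np.ceil(xy_max[0])) + 2)
    vox = np.zeros(shape, dtype=bool)
    for z, b in boundaries.items():
        if not (0 <= z < shape[0]):
            raise ValueError(f"slice index {z} outside volume of "
                             f"depth {shape[0]}")
        rr, cc = draw.polygon(b.contour[:, 1], b.contour[:, 0],
                              shape=shape[1:])
        vox[z, rr, cc] = True

    if closing and vox.any():
        pad = np.pad(vox, 1)
        pad = ndimage.binary_closing(pad, structure=np.ones((3, 3, 3)))
        vox = pad[1:-1, 1:-1, 1:-1]
    if min_component_voxels > 1 and vox.any():
        labels, n = ndimage.label(vox)
        counts = np.bincount(labels.ravel())
        small = np.nonzero(counts < min_component_voxels)[0]
        if len(small):
            vox[np.isin(labels, small[small > 0])] = False
    return BinaryVolume(vox, (xy_pixel, xy_pixel, z_step))


def extract_surface(volume: BinaryVolume) -> trimesh.Trimesh:
    """Closed iso-surface mesh of the foreground at the 0.5 level.

    Coordinates are physical (x, y, z) via the volume's spacing.  The
    volume is zero-padded first so the surface is always closed.
    """
    if not volume.voxels.any():
        raise ValueError("empty volume has no surface")
    sx, sy, sz = volume.spacing
    padded = np.pad(volume.voxels.astype(np.float32), 1)
    verts_zyx, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=(sz, sy, sx))
    verts = verts_zyx[:, ::-1].copy()           # (z, y, x) -> (x, y, z)
    verts -= np.array([sx, sy, sz])             # undo padding offset
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _vertex_adjacency(mesh: trimesh.Trimesh) -> sp.csr_matrix:
    e = mesh.edges_unique
    n = len(mesh.vertices)
    return sp.coo_matrix(
        (np.ones(2 * len(e)),
         (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
        shape=(n, n)).tocsr()


def select_high_curvature_vertices(mesh: trimesh.Trimesh,
                                   percentile: float = 80.0) -> np.ndarray:
    """Mask of vertices in the top curvature percentile.

    Curvature is proxied by the norm of the umbrella vector (distance of
    a vertex from its neighbors' centroid); the mask feeds the
    selected-face refinement pass of ``laplacian_smooth``.
    """
    A = _vertex_adjacency(mesh)
    deg = np.maximum(np.asarray(A.sum(axis=1)).ravel(), 1.0)
    centroid = A @ mesh.vertices / deg[:, None]
    umbrella = np.linalg.norm(centroid - mesh.vertices, axis=1)
    return umbrella >= np.percentile(umbrella, percentile)


def laplacian_smooth(mesh: trimesh.Trimesh, iterations: int = 5,
                     strength: float = 0.3,
                     vertex_mask=None) -> trimesh.Trimesh:
    """Iterative Laplacian (umbrella) smoothing of a surface mesh.

    Each iteration moves vertices toward their neighbors' centroid by
    ``strength``; ``vertex_mask`` restricts the move to a subset
    (selected-face refinement).  Vertex count and face topology are
    preserved; 0 iterations is the identity.
    """
    out = mesh.copy()
    if iterations <= 0 or strength == 0:
        return out
    A = _vertex_adjacency(mesh)
    deg = np.maximum(np.asarray(A.sum(axis=1)).ravel(), 1.0)
    v = out.vertices.copy()
    for _ in range(iterations):
        centroid = A @ v / deg[:, None]
        delta = strength * (centroid - v)
        if vertex_mask is not None:
            delta[~np.asarray(vertex_mask, bool)] = 0.0
        v = v + delta
    return trimesh.Trimesh(vertices=v, faces=out.faces.copy(),
                           process=False)
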