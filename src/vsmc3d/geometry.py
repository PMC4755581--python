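"""Small geometric utilities shared across the pipeline.

Angle conventions: beta is measured from the +Y (circumferential) axis
toward +X, wrapped to [-90, 90); alpha is the elevation out of the XY
plane in [0, 90].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n


def rot_x(deg: float) -> np.ndarray:
    """Rotation about +X; positive angles take +Y toward +Z."""
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def rot_z(deg: float) -> np.ndarray:
    """Counter-clockwise rotation about +Z (math convention)."""
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def orientation_matrix(beta_deg: float, alpha_deg: float) -> np.ndarray:
    """Rotation mapping +Y onto the cell's long axis.

    The long axis makes angle beta with +Y inside the XY plane (positive
    toward +X) and is elevated by alpha out of the plane.
    """
    return rot_z(-beta_deg) @ rot_x(alpha_deg)


def wrap_beta(deg: float) -> float:
    """Wrap an axial (180-degree-periodic) angle into [-90, 90)."""
    w = (deg + 90.0) % 180.0 - 90.0
    # the % above maps +90 exactly to -90, matching the half-open range
    return w


def beta_of_vector(vx: float, vy: float) -> float:
    """In-plane angle of an axial 2D direction, from +Y toward +X."""
    if vx == 0 and vy == 0:
        raise ValueError("zero vector has no orientation")
    return wrap_beta(np.degrees(np.arctan2(vx, vy)))


def alpha_of_vector(v) -> float:
    """Elevation of a 3D axial direction out of the XY plane, in [0, 90]."""
    v = unit(v)
    return float(np.degrees(np.arcsin(min(1.0, abs(v[2])))))


@dataclass
class Ellipsoid:
    """A solid triaxial ellipsoid ``(p-c)^T Q (p-c) <= 1`` in world units.

    ``axes`` holds the principal directions as columns (long axis first);
    ``semi`` the corresponding semi-axis lengths.
    """

    center: np.ndarray
    axes: np.ndarray     # 3x3, columns = principal directions
    semi: np.ndarray     # (3,) semi-axis lengths

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.semi = np.asarray(self.semi, dtype=float)
        if np.any(self.semi <= 0):
            raise ValueError("semi-axes must be positive")

    @classmethod
    def from_angles(cls, center, semi, beta_deg, alpha_deg):
        R = orientation_matrix(beta_deg, alpha_deg)
        # long axis = R @ ey; second axis in-plane width; third thickness
        V = np.column_stack([R @ np.array([0.0, 1.0, 0.0]),
                             R @ np.array([1.0, 0.0, 0.0]),
                             R @ np.array([0.0, 0.0, 1.0])])
        return cls(np.asarray(center, float), V, np.asarray(semi, float))

    @property
    def quadric(self) -> np.ndarray:
        return self.axes @ np.diag(1.0 / self.semi**2) @ self.axes.T

    @property
    def long_axis(self) -> np.ndarray:
        return self.axes[:, 0]

    def rho(self, points: np.ndarray) -> np.ndarray:
        """Normalized implicit radius (1 on the surface) for Nx3 points."""
        d = np.atleast_2d(points) - self.center
        Q = self.quadric
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", d, Q, d), 0.0))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """First-order Euclidean distance to the surface (negative inside)."""
        d = np.atleast_2d(points) - self.center
        Q = self.quadric
        r = self.rho(points)
        grad = d @ Q.T
        gn = np.linalg.norm(grad, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            sd = np.where(gn > 0, (r - 1.0) * r / np.maximum(gn, 1e-30),
                          -np.min(self.semi))
        return sd

    def max_z_chord(self) -> float:
        """Longest vertical chord through the solid (the central one)."""
        return 2.0 / np.sqrt(self.quadric[2, 2])

    def shadow(self):
        """XY projection ellipse: ``(r-c2)^T S (r-c2) <= 1``.

        Returns (S 2x2, semi-major p, semi-minor q, major-axis 2D unit
        vector).
        """
        Q = self.quadric
        A, b, c = Q[:2, :2], Q[:2, 2], Q[2, 2]
        S = A - np.outer(b, b) / c
        evals, evecs = np.linalg.eigh(S)
        # smaller eigenvalue -> longer semi-axis
        p = 1.0 / np.sqrt(evals[0])
        q = 1.0 / np.sqrt(evals[1])
        return S, p, q, evecs[:, 0]

    def z_section(self, z: float):
        """Ellipse cut at height z, or None if the plane misses the solid.

        Returns (2D center, 2x2 matrix M with section
        ``(r-c)^T M (r-c) <= 1``).
        """
        Q = self.quadric
        A, b, c = Q[:2, :2], Q[:2, 2], Q[2, 2]
        dz = z - self.center[2]
        Ainv_b = np.linalg.solve(A, b)
        k = 1.0 - dz**2 * (c - b @ Ainv_b)
        if k <= 0:
            return None
        center2 = self.center[:2] - dz * Ainv_b
        return center2, A / k

    def z_section_contour(self, z: float, n: int = 90):
        """Sampled closed contour of the z cross-section (n x 2), or None."""
        sec = self.z_section(z)
        if sec is None:
            return None
        c2, M = sec
        evals, evecs = np.linalg.eigh(M)
        radii = 1.0 / np.sqrt(evals)
        t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        circ = np.stack([np.cos(t), np.sin(t)], axis=1)
        return c2 + (circ * radii) @ evecs.T

    def bounding_extents(self) -> np.ndarray:
        """Half-extents of the axis-aligned bounding box, per world axis."""
        return np.sqrt(np.diag(np.linalg.inv(self.quadric)))


def scattering_angle_deg(points, center, cell_vector) -> np.ndarray:
    """Ray scattering angle of points seen from a cell center, in [0, 360).

    The angle is the cell vector's direction minus the direction of
    (point - center), wrapped modulo 2*pi and converted to degrees, so a
    point straight along the cell vector scores 0 and angles increase
    clockwise in the (x, y) frame.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    center = np.asarray(center, dtype=float)
    d = pts - center
    if np.any(np.all(d == 0, axis=1)):
        raise ValueError("point coincides with the center")
    nx, ny = cell_vector
    theta = np.arctan2(ny, nx) - np.arctan2(d[:, 1], d[:, 0])
    out = np.degrees(theta % (2 * np.pi))
    # float wrap can land exactly on 360
    out[out >= 360.0] = 0.0
    if np.isscalar(points[0]) and np.ndim(points) == 1:
        return float(out[0])
    return out


def central_chord_mean_factor(fraction: float = 0.5) -> float:
    """Mean of sqrt(1-u^2) over the central ``fraction`` of [-1, 1].

    The mean perpendicular chord of an ellipse over the central portion of
    its long axis is ``2q`` times this factor (≈0.9566 at fraction 0.5).
    """
    t = fraction
    integral = t * np.sqrt(1 - t**2) + np.arcsin(t)  # int over [-t, t]
    return float(integral / (2.0 * t))
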