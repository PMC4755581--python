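import numpy as np
import pytest

from vsmc3d.geometry import Ellipsoid
from vsmc3d.preprocess import EdgeSegment, NucleusGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def band_image():
    """A bright vertical band (a straight slender cell) plus mild noise."""
    rng = np.random.default_rng(7)
    img = np.zeros((96, 96))
    img[:, 42:54] = 1.0
    return img + rng.normal(0, 0.02, img.shape)


@pytest.fixture
def disk_image():
    yy, xx = np.mgrid[:96, :96]
    r = np.hypot(xx - 48, yy - 48)
    return 1.0 / (1.0 + np.exp((r - 25) / 0.8))


def make_ellipse_mask(shape=(96, 96), center=(48, 48), semi=(30, 10),
                      angle_deg=0.0):
    """Binary ellipse mask; angle measured from +Y toward +X."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    a = np.radians(angle_deg)
    dx, dy = xx - center[0], yy - center[1]
    u = dx * np.sin(a) + dy * np.cos(a)      # along long axis
    v = dx * np.cos(a) - dy * np.sin(a)
    return (u / semi[0]) ** 2 + (v / semi[1]) ** 2 <= 1.0


def simple_geometry(center=(48.0, 48.0), vector=(0.0, 1.0), half=10.0):
    center = np.asarray(center, float)
    vector = np.asarray(vector, float)
    return NucleusGeometry(
        center=center,
        skeleton=np.array([center - half * vector, center + half * vector]),
        endpoints=np.array([center - half * vector,
                            center + half * vector]),
        cell_vector=vector)


def circle_segment(center=(48.0, 48.0), radius=20.0, n=360,
                   theta0=0.0, theta1=360.0, segment_id=0):
    t = np.radians(np.linspace(theta0, theta1, n, endpoint=False))
    pts = np.column_stack([center[0] + radius * np.cos(t),
                           center[1] + radius * np.sin(t)])
    return EdgeSegment(points=pts, segment_id=segment_id)


@pytest.fixture
def unit_ellipsoid():
    return Ellipsoid.from_angles((0.0, 0.0, 0.0), (30.0, 5.0, 3.0),
                                 beta_deg=20.0, alpha_deg=5.0)
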