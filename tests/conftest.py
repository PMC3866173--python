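import numpy as np
import pytest
from scipy import ndimage

import cdac


@pytest.fixture
def unit_square():
    return cdac.Contour([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def fine_circle():
    """360-gon approximating a circle of radius 10 centered at (50, 50)."""
    th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    return cdac.Contour(np.column_stack([50 + 10 * np.cos(th), 50 + 10 * np.sin(th)]))


def make_smooth_gradient(seed, shape=(24, 24), sigma=3.0):
    """Sobel gradient of a smoothed random image: a generic external field."""
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.normal(0.5, 0.2, shape), sigma)
    return cdac.sobel_gradient(cdac.frame_from_array(np.clip(img, 0.0, 1.0)))


def random_simple_contour(rng, n, center=(12.0, 12.0), rmin=5.0, rmax=9.0):
    """Random star-shaped (hence simple) polygon with n vertices."""
    th = np.sort(rng.uniform(0, 2 * np.pi, n))
    while np.any(np.diff(th) < 1e-3):  # avoid near-coincident angles
        th = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(rmin, rmax, n)
    cx, cy = center
    return cdac.Contour(np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)]))


def segments_cross(p1, p2, p3, p4, eps=1e-12):
    """Proper or touching intersection of open segments p1p2 and p3p4."""

    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    if ((d1 > eps and d2 < -eps) or (d1 < -eps and d2 > eps)) and (
        (d3 > eps and d4 < -eps) or (d3 < -eps and d4 > eps)
    ):
        return True
    return False


def has_self_intersection(contour):
    """O(n^2) brute-force scan for crossing non-adjacent segments."""
    v = contour.vertices
    n = len(v)
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            if segments_cross(v[i], v[(i + 1) % n], v[j], v[(j + 1) % n]):
                return True
    return False
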