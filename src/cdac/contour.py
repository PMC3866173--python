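"""Closed piecewise-linear contours and their multi-scale differential geometry.

A :class:`Contour` is the snake: an ordered list of 2-D vertices in pixel
coordinates (x rightward, y downward), stored counter-clockwise (positive
shoelace area) with wrap-around indexing, so vertex ``i + n`` is vertex ``i``.

Tangents are the Gaussian-weighted multi-scale estimate

    T_i(x) = sum_{j=i-M}^{i+M} exp(-c_ij^2 / 2 sigma(x)^2) sgn(i-j) (p_i - p_j)

where ``c_ij`` is the arc length between vertices i and j, ``sigma(x) =
max(|x|, 1)`` and ``M = floor(3 sigma)`` (a 3-sigma window), clamped to
``(n-1)//2`` vertices per side.  Both halves of the sum point along the
forward traversal direction, so T is the forward tangent; the outward unit
normal of a counter-clockwise contour is T rotated by -90 degrees,
``(T_y, -T_x)/|T|``.  Positive extrusion along the normal grows the enclosed
area.
"""

from __future__ import annotations

import numpy as np
from shapely import make_valid
from shapely.geometry import MultiPolygon, Polygon

__all__ = [
    "Contour",
    "ContourError",
    "DegenerateTangentError",
    "cumulative_distance",
    "total_length",
    "tangent",
    "normal",
    "vertex_normals",
    "resample",
    "remove_self_intersections",
]

_EPS = 1e-12


class ContourError(ValueError):
    """Raised for invalid or collapsed contours."""


class DegenerateTangentError(ContourError):
    """Raised when the multi-scale tangent has (near-)zero magnitude."""


class Contour:
    """Closed polygon in pixel coordinates, canonically counter-clockwise.

    Parameters
    ----------
    vertices : array-like, shape (n, 2)
        Ordered ``(x, y)`` vertices; the closing edge from the last vertex
        back to the first is implicit.  Consecutive duplicates (including
        a duplicated first/last vertex) are dropped.
    orient : bool
        If true (default), reverse clockwise input so the stored polygon has
        positive signed area.  The first vertex is kept first.
    """

    __slots__ = ("vertices",)

    def __init__(self, vertices, *, orient: bool = True):
        v = np.array(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ContourError(f"expected (n, 2) vertex array, got shape {v.shape}")
        if len(v) >= 2:
            keep = np.linalg.norm(v - np.roll(v, 1, axis=0), axis=1) > _EPS
            if not keep[0]:  # wrap duplicate: drop the later copy, keep vertex 0
                keep[0] = True
                last_dup = np.flatnonzero(
                    np.linalg.norm(v - v[0], axis=1) <= _EPS
                )[-1]
                if last_dup != 0:
                    keep[last_dup] = False
            v = v[keep]
        if len(v) < 3:
            raise ContourError(f"contour needs >= 3 distinct vertices, got {len(v)}")
        if orient and _signed_area(v) < 0:
            v = np.concatenate([v[:1], v[1:][::-1]])
        self.vertices = v

    def __len__(self) -> int:
        return len(self.vertices)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Contour(n={len(self)}, area={self.signed_area:.2f})"

    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def signed_area(self) -> float:
        return _signed_area(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def segment_lengths(self) -> np.ndarray:
        """Length of edge (i, i+1) for each i, including the closing edge."""
        v = self.vertices
        return np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)

    def copy(self) -> "Contour":
        return Contour(self.vertices.copy(), orient=False)


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def total_length(contour: Contour) -> float:
    """Perimeter L of the closed contour, in pixels."""
    return float(contour.segment_lengths().sum())


def cumulative_distance(contour: Contour, i: int, j: int) -> float:
    """Arc length from vertex ``i`` forward to vertex ``j``.

    Indices wrap: ``j = i + n`` traverses the full loop once and returns the
    perimeter.  A backward offset (``j < i``) wraps to the equivalent forward
    traversal.
    """
    n = len(contour)
    steps = j - i
    if steps == 0:
        return 0.0
    if steps < 0:
        steps %= n
    loops, rem = divmod(steps, n)
    seg = contour.segment_lengths()
    cum = np.concatenate([[0.0], np.cumsum(seg)])  # cum[k]: vertex 0 -> vertex k
    L = cum[-1]
    i = i % n
    if i + rem <= n:
        partial = cum[i + rem] - cum[i]
    else:
        partial = (L - cum[i]) + cum[i + rem - n]
    return float(loops * L + partial)


def _sigma(x: float) -> float:
    # Retraction (x < 0) smooths like extrusion of equal magnitude; x = 0
    # must not collapse the Gaussian, so the scale is floored at one vertex.
    return max(abs(float(x)), 1.0)


def _window(contour: Contour, sigma: float) -> int:
    n = len(contour)
    return max(1, min(int(3.0 * sigma), (n - 1) // 2))


def tangent(contour: Contour, i: int, x: float) -> np.ndarray:
    """Multi-scale forward tangent T_i(x) at vertex ``i`` for extrusion level ``x``.

    Raises
    ------
    DegenerateTangentError
        If the weighted sum has near-zero magnitude (e.g. a locally
        symmetric spike); callers may fall back to the neighbour chord.
    """
    v = contour.vertices
    n = len(contour)
    i = i % n
    sig = _sigma(x)
    M = _window(contour, sig)
    seg = contour.segment_lengths()
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    L = cum[-1]
    t = np.zeros(2)
    for o in range(1, M + 1):
        jf = i + o
        d_f = (cum[jf] if jf <= n else L + cum[jf - n]) - cum[i]
        jb = i - o
        d_b = cum[i] - (cum[jb] if jb >= 0 else cum[jb + n] - L)
        t += np.exp(-d_f**2 / (2.0 * sig**2)) * (v[jf % n] - v[i])
        t += np.exp(-d_b**2 / (2.0 * sig**2)) * (v[i] - v[jb % n])
    if np.linalg.norm(t) < 1e-9:
        raise DegenerateTangentError(f"degenerate tangent at vertex {i}, level {x}")
    return t


def _rotate_outward(t: np.ndarray) -> np.ndarray:
    """Rotate forward tangent(s) by -90 deg: outward for a CCW contour."""
    return np.stack([t[..., 1], -t[..., 0]], axis=-1)


def normal(contour: Contour, i: int, x: float) -> np.ndarray:
    """Outward unit normal N_i(x), perpendicular to the multi-scale tangent.

    Falls back to the neighbour chord ``p_{i+1} - p_{i-1}`` when the tangent
    degenerates; raises :class:`DegenerateTangentError` only if the chord is
    degenerate too.
    """
    n = len(contour)
    i = i % n
    try:
        t = tangent(contour, i, x)
    except DegenerateTangentError:
        t = contour.vertices[(i + 1) % n] - contour.vertices[(i - 1) % n]
        if np.linalg.norm(t) < _EPS:
            raise
    nvec = _rotate_outward(t)
    return nvec / np.linalg.norm(nvec)


def vertex_normals(contour: Contour, sigma: float) -> np.ndarray:
    """Outward unit normals at every vertex for one smoothing scale.

    Vectorized equivalent of calling :func:`normal` per vertex with
    ``sigma(x) = sigma``; used by the candidate-grid builder where all
    vertices share a level magnitude.
    """
    v = contour.vertices
    n = len(contour)
    sig = max(float(sigma), 1.0)
    M = _window(contour, sig)
    seg = contour.segment_lengths()
    cumv = np.concatenate([[0.0], np.cumsum(seg)])[:-1]  # arc position per vertex
    L = float(seg.sum())
    idx = np.arange(n)
    t = np.zeros((n, 2))
    for o in range(1, M + 1):
        jf = idx + o
        d_f = np.where(jf < n, cumv[jf % n], cumv[jf % n] + L) - cumv
        jb = idx - o
        d_b = cumv - np.where(jb >= 0, cumv[jb % n], cumv[jb % n] - L)
        wf = np.exp(-d_f**2 / (2.0 * sig**2))
        wb = np.exp(-d_b**2 / (2.0 * sig**2))
        t += wf[:, None] * (v[jf % n] - v) + wb[:, None] * (v - v[jb % n])
    norms = np.linalg.norm(t, axis=1)
    bad = norms < 1e-9
    if np.any(bad):
        chord = v[(idx + 1) % n] - v[(idx - 1) % n]
        t[bad] = chord[bad]
        norms = np.linalg.norm(t, axis=1)
        if np.any(norms < _EPS):
            raise DegenerateTangentError(
                f"degenerate tangent and chord at vertices {np.flatnonzero(norms < _EPS)}"
            )
    nvec = _rotate_outward(t)
    return nvec / np.linalg.norm(nvec, axis=1, keepdims=True)


def resample(contour: Contour, target_spacing: float) -> Contour:
    """Redistribute vertices at ~uniform arc-length spacing along the polyline.

    The first vertex is kept as the starting point.  At least 3 vertices are
    retained regardless of spacing.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    v = contour.vertices
    closed = np.concatenate([v, v[:1]], axis=0)
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    L = cum[-1]
    n_new = max(3, int(round(L / target_spacing)))
    targets = L * np.arange(n_new) / n_new
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return Contour(np.column_stack([x, y]))


def remove_self_intersections(contour: Contour) -> Contour:
    """Drop crossing / self-touching loops, keeping the largest-area loop.

    A simple polygon is returned unchanged (same object).  The retained loop
    is re-oriented counter-clockwise.  Raises :class:`ContourError` when no
    loop with >= 3 vertices and positive area survives.
    """
    poly = Polygon(contour.vertices)
    if poly.is_valid:
        return contour
    fixed = make_valid(poly)
    candidates = []
    if isinstance(fixed, Polygon):
        candidates = [fixed]
    elif isinstance(fixed, MultiPolygon):
        candidates = list(fixed.geoms)
    elif hasattr(fixed, "geoms"):  # GeometryCollection: keep polygonal parts
        candidates = [g for g in fixed.geoms if isinstance(g, Polygon)]
        for g in fixed.geoms:
            if isinstance(g, MultiPolygon):
                candidates.extend(g.geoms)
    candidates = [p for p in candidates if p.area > _EPS]
    if not candidates:
        raise ContourError("self-intersection removal left no valid loop")
    best = max(candidates, key=lambda p: p.area)
    coords = np.asarray(best.exterior.coords)[:-1]
    if len(coords) < 3:
        raise ContourError("largest surviving loop has fewer than 3 vertices")
    return Contour(coords)
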