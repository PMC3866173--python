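"""Synthetic phase-contrast-like sequences with exact ground-truth outlines.

Phase optics attenuate low spatial frequencies, so cell interiors sit at
roughly the background level (shade-off) while the boundary shows a dark
band just inside the outline and a bright halo ring just outside.  The
renderer models this with two Gaussian ridges in the signed distance to the
true outline, plus additive Gaussian noise:

    I(r) = bg + interior_offset * [inside]
              + halo_amp * exp(-(sd - halo_offset)^2 / 2 (halo_width/2)^2)
              - band_amp * exp(-(sd + band_offset)^2 / 2 (band_width/2)^2)
              + N(0, noise_sigma),   clipped to [0, 1],

where sd is positive outside the outline.  The halo and band centers sit
symmetrically about the outline so the steepest intensity transition — the
feature the snake locks onto — lies on the true boundary.

Three motion archetypes emulate the behaviours such trackers must handle:
``spread`` (uniform outward growth of a round cell), ``extrude`` (a
pseudopod of fixed width growing along its axis) and ``retract`` (the same
protrusion shrinking).  Every sequence ships its exact truth polygons, so
end-to-end tracking accuracy needs no external data.  This module is the
only seeded source of randomness in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point

from .contour import Contour, resample
from .evaluation import rasterize
from .imaging import ImageFrame

__all__ = [
    "SceneParams",
    "MotionModel",
    "spread_model",
    "extrude_model",
    "retract_model",
    "render_frame",
    "generate_sequence",
]

_ARCHETYPES = ("spread", "extrude", "retract")


@dataclass(frozen=True)
class SceneParams:
    """Appearance of the rendered phase-contrast scene ([0, 1] intensity scale)."""

    shape: tuple = (160, 160)
    background: float = 0.45
    interior_offset: float = 0.0  # shade-off: interior ~ background
    halo_amplitude: float = 0.30
    halo_width: float = 2.0  # px
    halo_offset: float = 2.0  # ridge center, px outside the outline
    band_amplitude: float = 0.25
    band_width: float = 2.0  # px
    band_offset: float = 2.0  # trough center, px inside the outline
    noise_sigma: float = 0.02

    def __post_init__(self):
        if self.halo_width <= 0 or self.band_width <= 0:
            raise ValueError("halo/band widths must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass(frozen=True)
class MotionModel:
    """Ground-truth boundary motion for one archetype.

    ``rate`` is the per-frame boundary displacement in px (kept <= the
    search radius so tracking is feasible by construction).  Protrusion
    geometry applies to the extrude/retract archetypes only.
    """

    archetype: str = "spread"
    rate: float = 1.0
    center: tuple = (80.0, 80.0)
    radius: float = 30.0
    protrusion_base_width: float = 6.0
    protrusion_length0: float = 2.0
    protrusion_axis: tuple = (1.0, 0.0)

    def __post_init__(self):
        if self.archetype not in _ARCHETYPES:
            raise ValueError(f"archetype must be one of {_ARCHETYPES}")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")


def spread_model(**kw) -> MotionModel:
    """Round cell spreading uniformly outward (default 1 px/frame)."""
    return MotionModel(archetype="spread", rate=kw.pop("rate", 1.0), **kw)


def extrude_model(**kw) -> MotionModel:
    """Stationary body extruding a pseudopod (default 2 px/frame, 6 px wide)."""
    kw.setdefault("rate", 2.0)
    kw.setdefault("center", (64.0, 80.0))
    kw.setdefault("radius", 25.0)
    kw.setdefault("protrusion_length0", 2.0)
    return MotionModel(archetype="extrude", **kw)


def retract_model(**kw) -> MotionModel:
    """Stationary body retracting a thin protrusion (default 2 px/frame)."""
    kw.setdefault("rate", 2.0)
    kw.setdefault("center", (64.0, 80.0))
    kw.setdefault("radius", 25.0)
    kw.setdefault("protrusion_length0", 20.0)
    return MotionModel(archetype="retract", **kw)


def _truth_polygon(model: MotionModel, t: int, spacing: float = 2.0) -> Contour:
    """Exact ground-truth outline at frame index t (always a simple polygon)."""
    cx, cy = model.center
    if model.archetype == "spread":
        r = model.radius + model.rate * t
        geom = Point(cx, cy).buffer(r, quad_segs=96)
    else:
        if model.archetype == "extrude":
            length = model.protrusion_length0 + model.rate * t
        else:
            length = max(0.0, model.protrusion_length0 - model.rate * t)
        geom = Point(cx, cy).buffer(model.radius, quad_segs=96)
        if length > 0:
            ax = np.asarray(model.protrusion_axis, float)
            ax = ax / np.linalg.norm(ax)
            tip = np.array([cx, cy]) + (model.radius + length) * ax
            finger = LineString([(cx, cy), tuple(tip)]).buffer(
                model.protrusion_base_width / 2.0, quad_segs=32
            )
            geom = geom.union(finger)
    coords = np.asarray(geom.exterior.coords)[:-1]
    return resample(Contour(coords), spacing)


def body_polygon(model: MotionModel, spacing: float = 2.0) -> Contour:
    """The constant cell body (no protrusion) of an extrude/retract model."""
    cx, cy = model.center
    geom = Point(cx, cy).buffer(model.radius, quad_segs=96)
    return resample(Contour(np.asarray(geom.exterior.coords)[:-1]), spacing)


def _signed_distance(truth: Contour, shape: tuple) -> np.ndarray:
    """Signed distance (px) from each pixel center to the outline; >0 outside."""
    dense = resample(truth, 0.25)
    boundary = np.concatenate([dense.vertices, dense.vertices[:1]])
    tree = cKDTree(boundary)
    h, w = shape
    X, Y = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    d, _ = tree.query(np.column_stack([X.ravel(), Y.ravel()]), workers=-1)
    d = d.reshape(h, w)
    inside = rasterize(truth, shape)
    return np.where(inside, -d, d)


def render_frame(truth: Contour, params: SceneParams, seed: int = 0) -> ImageFrame:
    """Render one phase-contrast-like frame around the truth outline."""
    h, w = params.shape
    sd = _signed_distance(truth, (h, w))
    img = np.full((h, w), params.background, dtype=float)
    if params.interior_offset:
        img += params.interior_offset * (sd < 0)
    if params.halo_amplitude:
        sig = params.halo_width / 2.0
        img += params.halo_amplitude * np.exp(
            -((sd - params.halo_offset) ** 2) / (2.0 * sig**2)
        )
    if params.band_amplitude:
        sig = params.band_width / 2.0
        img -= params.band_amplitude * np.exp(
            -((sd + params.band_offset) ** 2) / (2.0 * sig**2)
        )
    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, params.noise_sigma, size=img.shape)
    return ImageFrame(np.clip(img, 0.0, 1.0), 0)


def generate_sequence(
    model: MotionModel, params: SceneParams, n_frames: int, seed: int = 0
):
    """Render a sequence and its exact truth polygons.

    Returns ``(frames, truths)``.  Raises if the motion would carry the
    outline (plus its halo) outside the frame.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    h, w = params.shape
    margin = params.halo_offset + 2.0 * params.halo_width
    seeds = np.random.SeedSequence(seed).generate_state(n_frames) % (2**31)
    frames, truths = [], []
    for t in range(n_frames):
        truth = _truth_polygon(model, t)
        v = truth.vertices
        if (
            v[:, 0].min() < margin
            or v[:, 1].min() < margin
            or v[:, 0].max() > w - 1 - margin
            or v[:, 1].max() > h - 1 - margin
        ):
            raise ValueError(
                f"frame {t}: motion pushed the outline within {margin:.0f} px "
                f"of the {h}x{w} frame border"
            )
        frames.append(render_frame(truth, params, seed=int(seeds[t])))
        truths.append(truth)
    return frames, truths
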