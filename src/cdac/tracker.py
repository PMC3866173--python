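"""Frame-to-frame tracking loop.

Each frame after the first is segmented by initializing the snake from the
previous frame's contour and running one global extrusion-optimization step:

    Sobel gradient -> optimize extrusion -> apply -> remove
    self-intersections -> resample at uniform arc-length spacing.

Frame 0 holds the (resampled) user initialization verbatim — the method
deliberately has no automatic initialization front-end, since normal
extrusion cannot converge from a rough outline.  Frames whose optimal
extrusion is all-zero keep the previous contour object untouched, so
sequences with no image evidence of motion are exact fixed points.

The method is fully deterministic: identical inputs yield bit-identical
contour sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contour import Contour, ContourError, remove_self_intersections, resample
from .energy import EnergyParams, external_energy
from .imaging import ImageFrame, sobel_gradient
from .optimizer import apply_extrusion, optimize_extrusion
from .polyio import read_polygon, write_polygon_csv

__all__ = ["TrackParams", "FrameRecord", "TrackResult", "track_sequence", "read_initial_contour"]


@dataclass(frozen=True)
class TrackParams:
    """Tracking parameters; defaults are the method's standard values."""

    R: int = 16
    kappa: float = 0.02
    resample_spacing: float = 2.0
    closure: str = "exact"
    segment_sample_step: float = 0.25

    def __post_init__(self):
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.resample_spacing <= 0:
            raise ValueError("resample_spacing must be > 0")

    def energy_params(self) -> EnergyParams:
        return EnergyParams(kappa=self.kappa, segment_sample_step=self.segment_sample_step)


@dataclass(frozen=True)
class FrameRecord:
    """Per-frame contour plus optimization diagnostics."""

    index: int
    contour: Contour
    dp_energy: float  # minimized -|sum of segment costs| + kappa|S| (nan for frame 0)
    external_energy: float  # length-normalized external energy E_X of the contour
    max_abs_level: int
    moved_segments: int
    warnings: tuple = ()


@dataclass
class TrackResult:
    frames: list = field(default_factory=list)
    params: TrackParams = field(default_factory=TrackParams)
    aborted: bool = False
    abort_reason: str = ""

    @property
    def contours(self) -> list:
        return [f.contour for f in self.frames]

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": [f.index for f in self.frames],
                "dp_energy": [f.dp_energy for f in self.frames],
                "external_energy": [f.external_energy for f in self.frames],
                "max_abs_level": [f.max_abs_level for f in self.frames],
                "moved_segments": [f.moved_segments for f in self.frames],
                "warnings": ["; ".join(f.warnings) for f in self.frames],
            }
        )

    def write_outputs(self, out_dir) -> None:
        """One polygon CSV per frame plus a run-summary table."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in self.frames:
            write_polygon_csv(out / f"contour_{rec.index:03d}.csv", rec.contour)
        self.summary_table().to_csv(out / "summary.csv", index=False)


def read_initial_contour(path, frame_shape=None) -> Contour:
    """Read and normalize a user-drawn initial polygon (CSV or ImageJ ROI).

    Orientation is normalized counter-clockwise; with ``frame_shape`` given,
    out-of-bounds vertices are clamped into the frame with a warning.
    """
    verts = read_polygon(path)
    if frame_shape is not None:
        h, w = frame_shape
        lo = np.array([0.0, 0.0])
        hi = np.array([w - 1.0, h - 1.0])
        clipped = np.clip(verts, lo, hi)
        if not np.array_equal(clipped, verts):
            n_out = int(np.sum(np.any(clipped != verts, axis=1)))
            warnings.warn(
                f"{path}: {n_out} initial-contour vertices fell outside the "
                f"{h}x{w} frame and were clamped to its bounds",
                stacklevel=2,
            )
            verts = clipped
    return Contour(verts)


def track_sequence(frames, init: Contour, params: TrackParams | None = None) -> TrackResult:
    """Track a cell outline through an ordered frame sequence.

    ``frames`` is a list of :class:`~cdac.imaging.ImageFrame`; ``init`` is
    the frame-0 contour.  Returns per-frame contours and diagnostics; if the
    contour collapses (< 3 vertices after cleaning) tracking aborts at that
    frame and the partial result is returned with ``aborted=True``.
    """
    params = params or TrackParams()
    if not frames:
        raise ValueError("need at least one frame")
    if not all(isinstance(f, ImageFrame) for f in frames):
        raise TypeError("frames must be ImageFrame instances")
    eparams = params.energy_params()

    result = TrackResult(params=params)
    current = resample(init, params.resample_spacing)
    grad0 = sobel_gradient(frames[0])
    result.frames.append(
        FrameRecord(
            index=0,
            contour=current,
            dp_energy=float("nan"),
            external_energy=external_energy(current, grad0, eparams),
            max_abs_level=0,
            moved_segments=0,
        )
    )

    for t in range(1, len(frames)):
        grad = sobel_gradient(frames[t])
        ext, dp_energy, grid = optimize_extrusion(
            current, grad, eparams, R=params.R, closure=params.closure
        )
        frame_warnings = []
        if ext.max_abs >= params.R:
            frame_warnings.append(
                f"extrusion level hit the search radius R={params.R}; "
                "usually a tracking error"
            )
        if ext.all_zero():
            new = current  # nothing moved: exact fixed point, skip cleanup
        else:
            try:
                new = apply_extrusion(current, grid, ext)
                new = remove_self_intersections(new)
                new = resample(new, params.resample_spacing)
            except ContourError as exc:
                result.aborted = True
                result.abort_reason = f"frame {t}: contour collapsed ({exc})"
                return result
        result.frames.append(
            FrameRecord(
                index=t,
                contour=new,
                dp_energy=dp_energy,
                external_energy=external_energy(new, grad, eparams),
                max_abs_level=ext.max_abs,
                moved_segments=ext.n_moved_segments,
                warnings=tuple(frame_warnings),
            )
        )
        current = new
    return result
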