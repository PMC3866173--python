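"""Rasterization and segmentation metrics (Dice, sensitivity, specificity).

Masks are boolean pixel grids; a pixel belongs to a contour's mask iff its
center (integer coordinates) satisfies the even-odd rule for the polygon,
with centers exactly on the boundary counted as inside.  Metrics follow the
usual confusion-matrix definitions with the reference mask as truth:

    dice        = 2|R ∩ T| / (|R| + |T|)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

Sequence summaries exclude frame 0: its contour is the user initialization,
which would bias sensitivity and specificity toward 100%.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon

from .contour import Contour

__all__ = [
    "MetricError",
    "rasterize",
    "dice",
    "sensitivity_specificity",
    "evaluate_sequence",
    "summarize_metrics",
]


class MetricError(ValueError):
    """Raised for undefined metrics (e.g. empty reference) or shape mismatch."""


def rasterize(contour: Contour, shape: tuple) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside (or on) the polygon."""
    h, w = int(shape[0]), int(shape[1])
    mask = np.zeros((h, w), dtype=bool)
    poly = Polygon(contour.vertices)
    if not poly.is_valid:
        fixed = shapely.make_valid(poly)
        polys = []
        if isinstance(fixed, Polygon):
            polys = [fixed]
        elif isinstance(fixed, MultiPolygon):
            polys = list(fixed.geoms)
        elif hasattr(fixed, "geoms"):
            polys = [g for g in fixed.geoms if isinstance(g, Polygon)]
        if not polys:
            return mask
        poly = max(polys, key=lambda p: p.area)
    minx, miny, maxx, maxy = poly.bounds
    x0, x1 = max(0, int(np.floor(minx))), min(w - 1, int(np.ceil(maxx)))
    y0, y1 = max(0, int(np.floor(miny))), min(h - 1, int(np.ceil(maxy)))
    if x0 > x1 or y0 > y1:
        return mask
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    X, Y = np.meshgrid(xs, ys)
    shapely.prepare(poly)
    inside = shapely.intersects_xy(poly, X.ravel(), Y.ravel())
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside.reshape(X.shape)
    return mask


def _check_shapes(test: np.ndarray, ref: np.ndarray) -> None:
    if test.shape != ref.shape:
        raise MetricError(f"mask shapes differ: {test.shape} vs {ref.shape}")


def dice(test: np.ndarray, ref: np.ndarray) -> float:
    """Dice coefficient 2|R∩T|/(|R|+|T|); 1.0 when both masks are empty."""
    _check_shapes(test, ref)
    t = int(test.sum())
    r = int(ref.sum())
    if t + r == 0:
        return 1.0
    inter = int(np.logical_and(test, ref).sum())
    return 2.0 * inter / (t + r)


def sensitivity_specificity(test: np.ndarray, ref: np.ndarray) -> tuple:
    """(TP/(TP+FN), TN/(TN+FP)) with the reference mask defining truth."""
    _check_shapes(test, ref)
    tp = int(np.sum(test & ref))
    fn = int(np.sum(~test & ref))
    tn = int(np.sum(~test & ~ref))
    fp = int(np.sum(test & ~ref))
    if tp + fn == 0:
        raise MetricError("sensitivity undefined: reference inside-set is empty")
    if tn + fp == 0:
        raise MetricError("specificity undefined: reference outside-set is empty")
    return tp / (tp + fn), tn / (tn + fp)


def evaluate_sequence(
    test_contours, ref_contours, shape: tuple, frames=None
) -> pd.DataFrame:
    """Per-frame metrics table for matched test/reference contour sequences."""
    if len(test_contours) != len(ref_contours):
        raise MetricError(
            f"sequence lengths differ: {len(test_contours)} tracked vs "
            f"{len(ref_contours)} reference contours"
        )
    if frames is None:
        frames = list(range(len(test_contours)))
    rows = []
    for f, tc, rc in zip(frames, test_contours, ref_contours):
        tm = rasterize(tc, shape)
        rm = rasterize(rc, shape)
        sens, spec = sensitivity_specificity(tm, rm)
        rows.append(
            {"frame": f, "dice": dice(tm, rm), "sensitivity": sens, "specificity": spec}
        )
    return pd.DataFrame(rows)


def summarize_metrics(table: pd.DataFrame, exclude_first: bool = True) -> dict:
    """Mean ± sd summary of a metrics table, excluding frame 0 by default."""
    df = table
    if exclude_first and len(df) > 1:
        df = df[df["frame"] != df["frame"].min()]
    out = {}
    for col in ("dice", "sensitivity", "specificity"):
        out[f"{col}_mean"] = float(df[col].mean())
        out[f"{col}_std"] = float(df[col].std(ddof=1)) if len(df) > 1 else 0.0
    out["n_frames"] = int(len(df))
    return out
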