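"""Polygon I/O: CSV vertex lists and ImageJ ROI polygon files.

CSV format: header ``x,y``, one vertex per row, 0-based pixel coordinates
(x rightward, y downward).  ImageJ ``.roi`` support covers polygon, freehand
and traced ROI types.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .contour import Contour

__all__ = ["read_polygon_csv", "write_polygon_csv", "read_imagej_roi", "read_polygon"]


class PolygonFileError(ValueError):
    """Raised for malformed polygon files."""


def read_polygon_csv(path) -> np.ndarray:
    """Read an ``x,y`` CSV vertex list into an (n, 2) float array."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise PolygonFileError(f"cannot read polygon file {path}: {exc}") from exc
    rows = []
    for lineno, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if lineno == 0 and parts[:2] == ["x", "y"]:
            continue
        if len(parts) < 2:
            raise PolygonFileError(f"{path}:{lineno + 1}: expected 'x,y', got {line!r}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise PolygonFileError(f"{path}:{lineno + 1}: non-numeric vertex {line!r}") from exc
    if len(rows) < 3:
        raise PolygonFileError(f"{path}: polygon needs >= 3 vertices, got {len(rows)}")
    return np.asarray(rows, dtype=float)


def write_polygon_csv(path, contour: Contour) -> None:
    """Write a contour as an ``x,y`` CSV with full float precision."""
    lines = ["x,y"]
    for x, y in contour.vertices:
        lines.append(f"{x:.17g},{y:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ImageJ ROI type codes that describe closed polygons.
_POLYGON_TYPES = {0: "polygon", 7: "freehand", 8: "traced"}


def read_imagej_roi(path) -> np.ndarray:
    """Read the vertex list of an ImageJ polygon/freehand/traced ``.roi`` file."""
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 64 or data[:4] != b"Iout":
        raise PolygonFileError(f"{path}: not an ImageJ ROI file")
    roi_type = data[6]
    if roi_type not in _POLYGON_TYPES:
        raise PolygonFileError(
            f"{path}: ROI type {roi_type} is not a closed polygon "
            f"(supported: {sorted(_POLYGON_TYPES.values())})"
        )
    top, left = struct.unpack(">hh", data[8:12])
    (n,) = struct.unpack(">h", data[16:18])
    if n < 3:
        raise PolygonFileError(f"{path}: polygon needs >= 3 vertices, got {n}")
    need = 64 + 4 * n
    if len(data) < need:
        raise PolygonFileError(f"{path}: truncated ROI file")
    xs = np.frombuffer(data, dtype=">i2", count=n, offset=64).astype(float) + left
    ys = np.frombuffer(data, dtype=">i2", count=n, offset=64 + 2 * n).astype(float) + top
    return np.column_stack([xs, ys])


def read_polygon(path) -> np.ndarray:
    """Dispatch on suffix: ``.roi`` -> ImageJ reader, otherwise CSV."""
    path = Path(path)
    if path.suffix.lower() == ".roi":
        return read_imagej_roi(path)
    return read_polygon_csv(path)
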