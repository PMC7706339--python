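"""Reverse calculation: project microplots back onto raw aerial frames.

Orthomosaic-derived microplot corners are 3-D world points (X, Y from the
extraction step, Z the mean surface-model height under the plot).  Each
point is shifted by the SfM offset vector — the constant difference between
the reconstruction's local frame and the output CRS — and multiplied by the
raw image's 3x4 P-matrix; perspective division then yields raw-image pixel
coordinates::

    (X', Y', Z') = (X, Y, Z) - offset
    (x, y, z)^T  = P (X', Y', Z', 1)^T
    u = x / z,   v = y / z

The primary product is a CSV with 11 columns per visible (plot, image)
pair: column number, crop-row number, raw image name, and the four (u, v)
plot corners, ordered top-left, top-right, bottom-right, bottom-left in the
world frame.  A plot is written for an image only when all four corners
fall inside it (an ``any``-corner mode is selectable); pixel bounds are
half-open, so u == width is outside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon

from .errors import FrameMismatchError, NotVisibleError
from .geoio import GeoRaster

__all__ = [
    "CameraModel",
    "apply_offset",
    "project",
    "backproject_to_height",
    "plot_mean_height",
    "reverse_calculate",
    "read_pmatrix_file",
    "write_pmatrix_file",
    "read_offset_file",
    "write_offset_file",
]

REVERSE_CSV_COLUMNS = ["column", "row", "image",
                       "u1", "v1", "u2", "v2", "u3", "v3", "u4", "v4"]


@dataclass
class CameraModel:
    """One raw image's camera: 3x4 P-matrix plus pixel dimensions."""

    image_name: str
    pmat: np.ndarray
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        self.pmat = np.asarray(self.pmat, dtype=float)
        if self.pmat.shape != (3, 4):
            raise ValueError(f"P-matrix must be 3x4, got {self.pmat.shape}")


def apply_offset(point, offset) -> np.ndarray:
    """Shift world coordinates into the reconstruction frame (Eq. subtraction)."""
    return np.asarray(point, dtype=float) - np.asarray(offset, dtype=float)


def project(point, cam: CameraModel) -> tuple[float, float, float]:
    """Project an offset-corrected world point to raw-image pixels.

    Returns ``(u, v, z)`` with ``z`` the camera-frame depth.  Raises
    :class:`NotVisibleError` for points at or behind the camera plane.
    """
    hom = np.append(np.asarray(point, dtype=float), 1.0)
    x, y, z = cam.pmat @ hom
    if z <= 0:
        raise NotVisibleError(
            f"point {tuple(point)} is behind camera {cam.image_name} (z={z:.3g})")
    return float(x / z), float(y / z), float(z)


def backproject_to_height(cam: CameraModel, u: float, v: float, z_world: float) -> np.ndarray:
    """Invert :func:`project` onto the horizontal plane ``Z' = z_world``.

    Valid for cameras whose P-matrix has a nonsingular left 3x3 block (all
    synthetic cameras).  Coordinates are in the offset-corrected frame.
    """
    m = cam.pmat[:, :3]
    m_inv = np.linalg.inv(m)
    center = -m_inv @ cam.pmat[:, 3]
    direction = m_inv @ np.array([u, v, 1.0])
    if direction[2] == 0:
        raise NotVisibleError("viewing ray parallel to the height plane")
    lam = (z_world - center[2]) / direction[2]
    return center + lam * direction


def plot_mean_height(dsm: GeoRaster, polygon) -> float:
    """Mean DSM height over a plot: cells whose centers fall in the polygon.

    Nodata cells are ignored; a plot with no valid cell under it is an
    error.  ``polygon`` is in the DSM's world frame.
    """
    poly = Polygon(np.asarray(polygon, dtype=float))
    inv = dsm.transform.inverse()
    corners = inv.apply(np.asarray(poly.exterior.coords))
    x0 = max(0, int(np.floor(corners[:, 0].min())))
    x1 = min(dsm.width, int(np.ceil(corners[:, 0].max())))
    y0 = max(0, int(np.floor(corners[:, 1].min())))
    y1 = min(dsm.height, int(np.ceil(corners[:, 1].max())))
    if x1 <= x0 or y1 <= y0:
        raise ValueError("polygon does not overlap the DSM extent")
    cols, rows = np.meshgrid(np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5)
    centers = dsm.transform.apply(np.column_stack([cols.ravel(), rows.ravel()]))
    inside = contains_xy(Polygon(np.asarray(polygon)), centers[:, 0], centers[:, 1])
    values = np.asarray(dsm.data[y0:y1, x0:x1], dtype=float).ravel()[inside]
    if dsm.nodata is not None:
        values = values[values != dsm.nodata]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no valid DSM cells under the plot polygon")
    return float(values.mean())


def _corners_visible(uv: np.ndarray, cam: CameraModel) -> np.ndarray:
    return ((uv[:, 0] >= 0) & (uv[:, 0] < cam.image_width) &
            (uv[:, 1] >= 0) & (uv[:, 1] < cam.image_height))


def reverse_calculate(plots, cams, dsm: GeoRaster, offset,
                      visibility: str = "all") -> pd.DataFrame:
    """Project every microplot into every raw image where it is visible.

    Returns one row per visible (plot, camera) pair with the 11 fields of
    :data:`REVERSE_CSV_COLUMNS`.  ``visibility="all"`` (default) requires
    all four corners inside the frame; ``"any"`` accepts partial plots.
    As a side effect fills each plot's ``mean_height``.  Raises
    :class:`FrameMismatchError` when no plot is visible in any camera —
    the usual symptom of inputs in different coordinate frames.
    """
    if visibility not in ("all", "any"):
        raise ValueError(f"visibility must be 'all' or 'any', got {visibility!r}")
    cams = list(cams)
    if not cams:
        raise ValueError("empty camera list")
    offset = np.asarray(offset, dtype=float)

    rows = []
    for plot in plots:
        corners = np.asarray(plot.world_polygon, dtype=float)[:4]
        z = plot_mean_height(dsm, corners)
        plot.mean_height = z
        pts = apply_offset(np.column_stack([corners, np.full(4, z)]), offset)
        for cam in cams:
            hom = cam.pmat @ np.column_stack([pts, np.ones(4)]).T
            if np.any(hom[2] <= 0):
                continue
            uv = (hom[:2] / hom[2]).T
            visible = _corners_visible(uv, cam)
            if (visibility == "all" and not visible.all()) or not visible.any():
                continue
            rows.append({"column": plot.column_index, "row": plot.row_index,
                         "image": cam.image_name,
                         **{f"{ax}{i + 1}": uv[i, j]
                            for i in range(4) for j, ax in enumerate("uv")}})
    if not rows:
        raise FrameMismatchError(
            "no microplot is visible in any camera; are the plots, DSM, "
            "offset and P-matrices in the same coordinate frame?")
    return pd.DataFrame(rows, columns=REVERSE_CSV_COLUMNS)


# ---------------------------------------------------------------------------
# File dialects (Pix4D-style text exports)
# ---------------------------------------------------------------------------

def read_pmatrix_file(path, image_width: int, image_height: int) -> list[CameraModel]:
    """Read a P-matrix text file: per line, image name + 12 row-major entries."""
    cams = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 13:
            raise ValueError(f"{path}: expected name + 12 entries, got {len(parts)}")
        pmat = np.array([float(v) for v in parts[1:]]).reshape(3, 4)
        cams.append(CameraModel(parts[0], pmat, image_width, image_height))
    if not cams:
        raise ValueError(f"{path}: no camera entries")
    return cams


def write_pmatrix_file(cams, path) -> Path:
    path = Path(path)
    lines = [" ".join([c.image_name] + [f"{v:.12g}" for v in c.pmat.ravel()])
             for c in cams]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_offset_file(path) -> np.ndarray:
    """Read the 3-number whitespace-separated offset file."""
    values = Path(path).read_text().split()
    if len(values) != 3:
        raise ValueError(f"{path}: expected 3 numbers, got {len(values)}")
    return np.array([float(v) for v in values])


def write_offset_file(offset, path) -> Path:
    path = Path(path)
    path.write_text(" ".join(f"{float(v):.12g}" for v in np.asarray(offset)) + "\n")
    return path
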