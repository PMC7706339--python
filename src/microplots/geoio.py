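"""Georeferenced raster I/O and per-microplot output products.

Rasters are GeoTIFFs handled through :mod:`tifffile`; the georeferencing
tags (ModelPixelScale/ModelTiepoint for axis-aligned transforms,
ModelTransformation otherwise, GeoAsciiParams for an opaque CRS tag) are
written and parsed directly.  The CRS tag is carried verbatim and never
reprojected.  Non-georeferenced images (PNG, plain TIFF) fall back to an
identity pixel transform with a warning flag, in which case all "world"
coordinates are simply pixel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import RasterFormatError
from .transforms import Affine2D

__all__ = [
    "GeoRaster",
    "read_orthomosaic",
    "write_geotiff",
    "write_plot_shapefiles",
    "write_intersection_sheet",
    "crop_plot_images",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_TRANSFORM = 34264
_TAG_GEO_ASCII = 34737


@dataclass
class GeoRaster:
    """A raster (1 or 3 bands) tied to an affine pixel->world transform."""

    data: np.ndarray
    transform: Affine2D = field(default_factory=Affine2D.identity)
    crs_tag: str | None = None
    nodata: float | None = None
    georef_missing: bool = False

    def __post_init__(self) -> None:
        if self.transform.determinant == 0.0:
            raise ValueError("geotransform must be invertible")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[2]


def _geotransform_tags(transform: Affine2D, crs_tag: str | None) -> list[tuple]:
    tags = []
    if transform.is_axis_aligned():
        tags.append((_TAG_PIXEL_SCALE, "d", 3, (transform.a, -transform.e, 0.0)))
        tags.append((_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.c, transform.f, 0.0)))
    else:
        m = (transform.a, transform.b, 0.0, transform.c,
             transform.d, transform.e, 0.0, transform.f,
             0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0)
        tags.append((_TAG_TRANSFORM, "d", 16, m))
    if crs_tag:
        text = str(crs_tag) + "|"
        tags.append((_TAG_GEO_ASCII, "s", len(text) + 1, text))
    return tags


def write_geotiff(path, data: np.ndarray, transform: Affine2D | None = None,
                  crs_tag: str | None = None) -> Path:
    """Write a 1- or 3-band array as a (Geo)TIFF."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim not in (2, 3) or (data.ndim == 3 and data.shape[2] != 3):
        raise RasterFormatError(f"cannot write raster of shape {data.shape}")
    extratags = _geotransform_tags(transform, crs_tag) if transform is not None else []
    photometric = "rgb" if data.ndim == 3 else "minisblack"
    tifffile.imwrite(path, data, photometric=photometric, extratags=extratags)
    return path


def _parse_geotiff_tags(page) -> tuple[Affine2D | None, str | None]:
    tags = page.tags
    crs_tag = None
    if _TAG_GEO_ASCII in tags:
        crs_tag = str(tags[_TAG_GEO_ASCII].value).rstrip("|\x00") or None
    if _TAG_TRANSFORM in tags:
        m = np.asarray(tags[_TAG_TRANSFORM].value, dtype=float).reshape(4, 4)
        return Affine2D(m[0, 0], m[0, 1], m[0, 3], m[1, 0], m[1, 1], m[1, 3]), crs_tag
    if _TAG_PIXEL_SCALE in tags and _TAG_TIEPOINT in tags:
        sx, sy = np.asarray(tags[_TAG_PIXEL_SCALE].value, dtype=float)[:2]
        tp = np.asarray(tags[_TAG_TIEPOINT].value, dtype=float)
        i, j, _, x, y, _ = tp[:6]
        return Affine2D(sx, 0.0, x - sx * i, 0.0, -sy, y + sy * j), crs_tag
    return None, crs_tag


def _check_bands(data: np.ndarray, path) -> np.ndarray:
    if data.ndim == 2:
        return data
    if data.ndim == 3:
        if data.shape[2] == 3:
            return data
        if data.shape[2] == 4:  # silently drop an alpha channel
            return data[:, :, :3]
    n = data.shape[2] if data.ndim == 3 else data.ndim
    raise RasterFormatError(f"{path}: unsupported band count ({n})")


def read_orthomosaic(path) -> GeoRaster:
    """Read a raster; GeoTIFF georeferencing is honored when present.

    Files without georeferencing get an identity transform and
    ``georef_missing=True``, so downstream coordinates are pixel positions.
    """
    path = Path(path)
    if not path.exists():
        raise RasterFormatError(f"{path}: no such file")
    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            with tifffile.TiffFile(path) as tif:
                data = tif.series[0].asarray()
                transform, crs_tag = _parse_geotiff_tags(tif.pages[0])
        except tifffile.TiffFileError as exc:
            raise RasterFormatError(f"{path}: unreadable TIFF ({exc})") from exc
    else:
        try:
            data = np.asarray(iio.imread(path))
        except Exception as exc:
            raise RasterFormatError(f"{path}: unreadable image ({exc})") from exc
        transform, crs_tag = None, None
    data = _check_bands(data, path)
    if transform is None:
        return GeoRaster(data, Affine2D.identity(), crs_tag, georef_missing=True)
    return GeoRaster(data, transform, crs_tag)


# ---------------------------------------------------------------------------
# Per-plot products: shapefile layer, corner spreadsheet, image crops.
# ---------------------------------------------------------------------------

def write_plot_shapefiles(plots, crs_tag, out_dir, per_plot: bool = False) -> list[Path]:
    """Write all microplot polygons as one shapefile layer.

    The attribute table carries the 1-based ``col`` and ``row`` grid indices.
    With ``per_plot=True`` an individual single-polygon shapefile per plot is
    written alongside the combined layer.
    """
    from .shapefile_io import write_polygons

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    polygons = [p.world_polygon for p in plots]
    records = [{"col": p.column_index, "row": p.row_index} for p in plots]
    paths = [write_polygons(out_dir / "microplots.shp", polygons, records, crs_tag)]
    if per_plot:
        for poly, rec in zip(polygons, records):
            name = f"plot_{rec['col']:02d}_{rec['row']:02d}.shp"
            paths.append(write_polygons(out_dir / name, [poly], [rec], crs_tag))
    return paths


def write_intersection_sheet(plots, out_path) -> Path:
    """Save plot corner (intersection) points, one row per plot.

    Columns: grid indices plus the four corner world coordinates
    ``x1..y4``.  CSV by default; ``.xlsx`` paths get a true spreadsheet.
    """
    plots = list(plots)
    if not plots:
        raise ValueError("no plots to write")
    out_path = Path(out_path)
    rows = []
    for p in plots:
        corners = np.asarray(p.world_polygon, dtype=float)[:4]
        rows.append({"col": p.column_index, "row": p.row_index,
                     **{f"{ax}{i + 1}": corners[i, j]
                        for i in range(4) for j, ax in enumerate("xy")}})
    frame = pd.DataFrame(rows)
    if out_path.suffix.lower() == ".xlsx":
        frame.to_excel(out_path, index=False)
    else:
        frame.to_csv(out_path, index=False)
    return out_path


def crop_plot_images(raster: GeoRaster, plots, out_dir, fmt: str = "tif") -> list[Path]:
    """Crop the source raster to each plot's pixel bounding box.

    Crops come from the original (unrotated) raster; each file is named
    ``plot_<col>_<row>``.  GeoTIFF crops keep a correctly shifted
    geotransform; ``fmt="png"`` writes plain images.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in plots:
        (x0, x1), (y0, y1) = p.pixel_bounds
        if x0 < 0 or y0 < 0 or x1 > raster.width or y1 > raster.height:
            raise ValueError(
                f"plot ({p.column_index},{p.row_index}) bounds {p.pixel_bounds} "
                f"outside raster {raster.width}x{raster.height}")
        crop = raster.data[y0:y1, x0:x1]
        name = f"plot_{p.column_index:02d}_{p.row_index:02d}.{fmt}"
        path = out_dir / name
        if fmt in ("tif", "tiff"):
            shifted = raster.transform @ Affine2D.translation(x0, y0)
            write_geotiff(path, crop, shifted, raster.crs_tag)
        else:
            iio.imwrite(path, crop)
        paths.append(path)
    return paths
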