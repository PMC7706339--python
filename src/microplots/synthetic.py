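"""Synthetic field scenes with exact ground truth.

Emulates the inputs of a UAV plot-extraction run — an RGB orthomosaic of a
gridded breeding field, its vegetation mask, a digital surface model, nadir
cameras and the SfM offset — from a compact parametric description, so
every pipeline stage can be tested against known truth without flying
anything.  Plants are solid color-noised rectangles on soil; weeds are
small disks (diameter capped by ``weed_max_size_px``, so the segmentation
``noise`` parameter can provably remove them); the whole scene may be
rotated; the world frame is a local planar metric frame (pixel size
``gsd_m``), with no geodesy.

Not emulated: radiometric effects (shadows, vignetting), canopy texture or
overlap, growth stages, terrain beyond a smooth low-relief surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
from skimage.draw import disk as draw_disk

from .detection import MicroplotRecord, PixelInterval, _rotate_binary
from .geoio import GeoRaster, write_geotiff
from .reverse import CameraModel, write_offset_file, write_pmatrix_file
from .transforms import Affine2D

__all__ = ["SyntheticFieldSpec", "SyntheticScene", "generate_field", "generate_cameras"]


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Parameters of a synthetic field scene.

    Geometry is declared in pixels of the (unrotated) orthomosaic; the
    default grid mirrors a typical sugarbeet trial (4 columns x 34 crop
    rows).  ``plant_fill`` is the planted fraction of each nominal grid
    cell (plants occupy the full cell width and a centered
    ``plant_fill x row_height_px`` band); ``weed_density`` is the expected
    number of weed disks per 10^4 px^2 of canvas.
    """

    n_columns: int = 4
    n_rows: int = 34
    column_width_px: int = 48
    column_gap_px: int = 14
    row_height_px: int = 32
    row_gap_px: int = 12
    rotation_deg: float = 0.0
    orientation: str = "vertical"
    plant_fill: float = 0.9
    weed_density: float = 0.5
    weed_max_size_px: int = 5
    soil_color_rgb: tuple = (120, 92, 70)
    plant_color_rgb: tuple = (58, 140, 60)
    color_noise: int = 10
    margin_px: int = 24
    canvas_px: tuple | None = None  # (width, height); None = auto-fit
    gsd_m: float = 0.01
    world_origin: tuple = (100.0, 200.0)
    relief_amplitude_m: float = 0.2
    crop_height_m: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_columns", "n_rows", "column_width_px", "row_height_px",
                     "weed_max_size_px"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.column_gap_px < 1 or self.row_gap_px < 1:
            raise ValueError("gaps must be >= 1 px: crop rows must not touch")
        if not -45.0 <= self.rotation_deg <= 45.0:
            raise ValueError("rotation_deg must be within [-45, 45]")
        if not 0.0 < self.plant_fill <= 1.0:
            raise ValueError("plant_fill must be in (0, 1]")
        if self.weed_density < 0:
            raise ValueError("weed_density must be >= 0")
        if self.orientation not in ("vertical", "horizontal"):
            raise ValueError("orientation must be vertical|horizontal")

    @property
    def field_size_px(self) -> tuple[int, int]:
        w = self.n_columns * self.column_width_px + (self.n_columns - 1) * self.column_gap_px
        h = self.n_rows * self.row_height_px + (self.n_rows - 1) * self.row_gap_px
        return w, h

    @property
    def planted_band_px(self) -> int:
        """Rasterized height of the planted band inside each cell."""
        return max(1, round(self.plant_fill * self.row_height_px))

    @property
    def planted_area_fraction(self) -> float:
        """Analytic vegetation fraction of the unrotated canvas."""
        fw, fh = self.field_size_px
        canvas = (fw + 2 * self.margin_px) * (fh + 2 * self.margin_px)
        planted = self.n_columns * self.n_rows * self.column_width_px * self.planted_band_px
        return planted / canvas


@dataclass
class SyntheticScene:
    """A generated scene plus everything needed to grade results against it."""

    spec: SyntheticFieldSpec
    rgb_image: np.ndarray
    truth_mask: np.ndarray
    truth_grid: list[MicroplotRecord]
    geotransform: Affine2D
    dsm: GeoRaster
    cameras: list[CameraModel] = dataclass_field(default_factory=list)
    offset: np.ndarray = dataclass_field(default_factory=lambda: np.zeros(3))
    crs_tag: str = "LOCAL_METRIC"

    @property
    def ortho(self) -> GeoRaster:
        return GeoRaster(self.rgb_image, self.geotransform, self.crs_tag)

    def write(self, out_dir) -> dict[str, Path]:
        """Write the scene in the exact dialects the pipeline reads.

        GeoTIFF orthomosaic/mask/DSM, truth-grid shapefile, P-matrix and
        offset text files.
        """
        from .geoio import write_plot_shapefiles

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ortho": write_geotiff(out_dir / "ortho.tif", self.rgb_image,
                                   self.geotransform, self.crs_tag),
            "mask": write_geotiff(out_dir / "mask.tif",
                                  self.truth_mask.astype(np.uint8) * 255,
                                  self.geotransform, self.crs_tag),
            "dsm": write_geotiff(out_dir / "dsm.tif", self.dsm.data,
                                 self.geotransform, self.crs_tag),
            "truth": write_plot_shapefiles(self.truth_grid, self.crs_tag,
                                           out_dir / "truth")[0],
        }
        if self.cameras:
            paths["pmatrix"] = write_pmatrix_file(self.cameras, out_dir / "pmatrix.txt")
            paths["offset"] = write_offset_file(self.offset, out_dir / "offset.txt")
        return paths


def _paint_plots(spec: SyntheticFieldSpec) -> tuple[np.ndarray, list]:
    """Unrotated plant mask and per-plot integer pixel rectangles."""
    fw, fh = spec.field_size_px
    w, h = fw + 2 * spec.margin_px, fh + 2 * spec.margin_px
    mask = np.zeros((h, w), dtype=bool)
    band = spec.planted_band_px
    cells = []
    for ci in range(spec.n_columns):
        x0 = spec.margin_px + ci * (spec.column_width_px + spec.column_gap_px)
        x1 = x0 + spec.column_width_px
        for ri in range(spec.n_rows):
            cy0 = spec.margin_px + ri * (spec.row_height_px + spec.row_gap_px)
            y0 = cy0 + (spec.row_height_px - band) // 2
            y1 = y0 + band
            mask[y0:y1, x0:x1] = True
            cells.append((ci + 1, ri + 1, x0, x1, y0, y1))
    return mask, cells


def _scatter_weeds(spec: SyntheticFieldSpec, plant_mask: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    h, w = plant_mask.shape
    weeds = np.zeros_like(plant_mask)
    n = rng.poisson(spec.weed_density * w * h / 1e4)
    placed = 0
    attempts = 0
    while placed < n and attempts < 50 * max(1, n):
        attempts += 1
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        if plant_mask[min(int(cy), h - 1), min(int(cx), w - 1)]:
            continue  # weeds live off-plot
        radius = rng.uniform(0.5, spec.weed_max_size_px / 2.0)
        rr, cc = draw_disk((cy, cx), radius, shape=(h, w))
        weeds[rr, cc] = True
        placed += 1
    return weeds & ~plant_mask


def generate_field(spec: SyntheticFieldSpec) -> SyntheticScene:
    """Render a synthetic orthomosaic scene from its parametric description.

    Deterministic for a fixed ``spec.seed``.  The returned scene holds the
    8-bit RGB image, the exact vegetation mask, the truth grid (one record
    per cell with world polygons), the DSM and the pixel->world transform.
    """
    rng = np.random.default_rng(spec.seed)
    plant_mask, cells = _paint_plots(spec)
    weed_mask = _scatter_weeds(spec, plant_mask, rng)

    rotation = spec.rotation_deg - (90.0 if spec.orientation == "horizontal" else 0.0)
    if rotation != 0.0:
        plant_rot, forward = _rotate_binary(plant_mask, rotation)
        weed_rot, _ = _rotate_binary(weed_mask, rotation)
    else:
        plant_rot, weed_rot = plant_mask, weed_mask
        forward = Affine2D.identity()

    if spec.canvas_px is not None:
        cw, ch = spec.canvas_px
        h, w = plant_rot.shape
        if w > cw or h > ch:
            raise ValueError(
                f"rotated grid ({w}x{h} px) exceeds requested canvas ({cw}x{ch})")
        px, py = (cw - w) // 2, (ch - h) // 2
        pad = np.zeros((ch, cw), dtype=bool)
        pad[py:py + h, px:px + w] = plant_rot
        plant_rot, tmp = pad, np.zeros((ch, cw), dtype=bool)
        tmp[py:py + h, px:px + w] = weed_rot
        weed_rot = tmp
        forward = Affine2D.translation(px, py) @ forward

    h, w = plant_rot.shape
    veg = plant_rot | weed_rot
    noise = rng.integers(-spec.color_noise, spec.color_noise + 1, size=(h, w, 3))
    rgb = np.where(veg[..., None],
                   np.asarray(spec.plant_color_rgb),
                   np.asarray(spec.soil_color_rgb)) + noise
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)

    x0, y0 = spec.world_origin
    geotransform = Affine2D(spec.gsd_m, 0.0, x0, 0.0, -spec.gsd_m, y0)

    # smooth low-relief ground plus crop height on the plots
    yy, xx = np.mgrid[0:h, 0:w]
    relief = spec.relief_amplitude_m * np.sin(2 * np.pi * xx / max(w, 1)) \
        * np.cos(2 * np.pi * yy / max(h, 1))
    dsm_data = (relief + spec.crop_height_m * plant_rot).astype(np.float32)
    dsm = GeoRaster(dsm_data, geotransform, "LOCAL_METRIC")

    truth = []
    for ci, ri, cx0, cx1, cy0, cy1 in cells:
        corners_px = forward.apply(np.array(
            [[cx0, cy0], [cx1, cy0], [cx1, cy1], [cx0, cy1]], dtype=float))
        bx0 = int(np.clip(np.floor(corners_px[:, 0].min()), 0, w))
        bx1 = int(np.clip(np.ceil(corners_px[:, 0].max()), 0, w))
        by0 = int(np.clip(np.floor(corners_px[:, 1].min()), 0, h))
        by1 = int(np.clip(np.ceil(corners_px[:, 1].max()), 0, h))
        truth.append(MicroplotRecord(
            column_index=ci, row_index=ri,
            pixel_bounds=(PixelInterval(bx0, bx1), PixelInterval(by0, by1)),
            world_polygon=geotransform.apply(corners_px)))

    return SyntheticScene(spec=spec, rgb_image=rgb, truth_mask=veg,
                          truth_grid=truth, geotransform=geotransform, dsm=dsm)


def generate_cameras(scene: SyntheticScene, n_cameras: int, altitude_m: float,
                     image_width: int = 4000, image_height: int = 3000,
                     focal_px: float | None = None,
                     offset=None) -> list[CameraModel]:
    """Attach nadir pinhole cameras whose footprints jointly cover the field.

    Cameras sit at ``altitude_m`` above the ground plane along the field's
    vertical world axis; each P-matrix is ``K [R | t]`` with world
    coordinates taken in the offset-subtracted frame (the SfM convention).
    The camera list and offset are stored on the scene and returned.
    """
    if n_cameras < 1:
        raise ValueError("n_cameras must be >= 1")
    h, w = scene.truth_mask.shape
    corners = scene.geotransform.apply(
        np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float))
    lo, hi = corners.min(axis=0), corners.max(axis=0)
    center = (lo + hi) / 2.0
    extent = hi - lo

    if focal_px is None:
        margin = 1.25  # whole-field coverage with a visibility margin
        focal_px = altitude_m * min(image_width / (margin * extent[0]),
                                    image_height / (margin * extent[1]))
    k = np.array([[focal_px, 0.0, image_width / 2.0],
                  [0.0, focal_px, image_height / 2.0],
                  [0.0, 0.0, 1.0]])
    # nadir: camera x along +X, image v grows toward -Y (south), looking down
    r = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])

    offset = np.floor([center[0], center[1], 0.0]) if offset is None \
        else np.asarray(offset, dtype=float)
    span = 0.25 * extent[1]
    ys = np.linspace(center[1] - span, center[1] + span, n_cameras) \
        if n_cameras > 1 else np.array([center[1]])

    cams = []
    for i, y in enumerate(ys):
        cam_center = np.array([center[0], y, altitude_m]) - offset
        t = -r @ cam_center
        pmat = k @ np.hstack([r, t[:, None]])
        cams.append(CameraModel(f"IMG_{i:04d}.JPG", pmat, image_width, image_height))
    scene.cameras = cams
    scene.offset = offset
    return cams
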