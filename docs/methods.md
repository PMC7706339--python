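# Methods

## Problem and model

A breeding field is modelled as a planar grid: `n_columns` planted strips
("columns"), each containing `n_rows` crop rows, with soil gaps between
strips and between rows.  The orthomosaic is assumed planar (orthorectified),
so all geometry is affine: pixel ↔ world conversion is a 2×3 geotransform
and the field's tilt is a single rotation angle.  The method requires that
crop rows do not touch each other and that the region of interest contains
no segmented object other than the field; weeds are tolerated as long as
they are small (relative to the `noise` parameter) or contribute little
profile mass.

## Segmentation

* **ExG** is computed on chromaticity coordinates `r = R/(R+G+B)` etc.,
  with an all-zero pixel mapped to ExG 0.  Per-pixel normalization makes
  the index invariant to per-pixel brightness scaling; a `global-max`
  normalization mode is provided for callers that want raw-scale behaviour,
  since "normalized" admits both readings.
* **Otsu** operates on the ExG map quantized to 256 levels over its
  observed range — classic Otsu is histogram-based and the fixed
  quantization makes the threshold reproducible across dtypes.  Ties in
  between-class variance resolve to the lowest level.  A constant map is
  rejected (`UnsegmentableImageError`) rather than thresholded arbitrarily;
  an all-soil image is the canonical trigger.
* **Noise removal** drops 8-connected components with area strictly below
  `noise` px (8-connectivity because diagonal pixel chains are common at
  leaf edges).  `noise = 0` is the identity; the operation is idempotent.

## Grid detection

* **Rotation.** The tilt is the orientation (normalized to [−45°, 45°)) of
  the minimum-area rotated bounding rectangle of the vegetation boundary
  pixels (convex hull first, for speed).  Masks are rotated with
  nearest-neighbour resampling, which preserves binarity; the affine
  rotated→original pixel map is kept and is exact (invertible to well
  under 0.5 px).  Fields with horizontal columns get an extra 90° turn so
  a single vertical-columns code path serves both orientations.
* **Columns.** One 3×3 erosion pass then one 1×9 horizontal dilation pass
  even out the mask ("slightly manipulated"; kernel sizes are
  configurable — the defaults bridge within-column gaps without joining
  columns separated by ≥ 10 px).  The x-profile (white pixels per image
  column) is erased below 1/3 of its mean — the mean over *all* entries,
  zeros included, and the comparison is strict, so ties at the cutoff
  survive — and maximal positive runs become half-open column intervals.
* **Rows.** Within each column crop, the y-profile is erased below 1/2 of
  its per-column mean (rows are more homogeneous and inter-row weeds more
  frequent, hence the higher cutoff) and scanned the same way.
* **Count reconciliation.** The detected interval count must equal the
  declared layout.  Surplus intervals are dropped by profile mass, and a
  kept interval absorbs a dropped neighbour closer than half the median
  inter-interval gap (fragments of a split column).  A deficit raises
  `DetectionError` naming both counts: missing structure means the
  segmentation needs fixing, and silent padding would misnumber every
  downstream plot.  Reconciliation emits a warning that the CLI surfaces
  in the run manifest.
* **Edge refinement.** The horizontal dilation inflates every column by
  its radius, so intervals are re-tightened against the *unprocessed*
  rotated mask: the supported extent (profile ≥ 25% of the interior
  median, which ignores stray weed pixels) with a subpixel correction from
  the coverage of the two boundary lines.  Row intervals are re-tightened
  within a ±2 px window for the same reason (the erasure can clip a
  partially covered edge line).
* **Shear correction.** The derotation angle comes from a rasterized
  rectangle and is typically accurate to ~0.1°; over a 2000-px column that
  residual displaces end plots by 2–3 px.  A count-weighted regression of
  the vegetation x-centroid on y inside each column recovers the residual
  slope, and plot rectangles are sheared by it (slopes above 0.05 are
  treated as spurious and ignored).  This is applied per column, so it
  also tolerates slightly non-parallel columns.
* **Conventions.** 0-based pixel indices, half-open intervals, origin
  top-left, x rightward, y downward; world mapping uses pixel-corner
  coordinates so adjacent polygons tile exactly.  Column indices ascend
  along rotated +x, row indices along rotated +y, 1-based.  Plot corner
  order is top-left, top-right, bottom-right, bottom-left.

## Products

Shapefile output is a single polygon layer with `col`/`row` attributes
(clockwise outer rings, `.prj` carrying the CRS tag verbatim); per-plot
files are optional.  The corner spreadsheet is CSV by default (portable),
XLSX on request.  Image crops are taken from the *original* orientation
raster — the axis-aligned bounding box of the mapped corners — to avoid
resampling the RGB data a second time; GeoTIFF crops carry a shifted
geotransform.

## Reverse calculation

Corners are lifted to 3-D with `Z` = mean DSM value over cells whose
centers fall inside the plot polygon (nodata ignored; no valid cell is an
error), offset-subtracted, multiplied by the image's P-matrix and
perspective-divided.  Depth `z ≤ 0` means behind the camera.  A plot is
written for an image only if **all four** corners land inside it (a
partial plot is unusable for per-plot traits); `visibility="any"` relaxes
this.  Bounds are half-open: `u = width` is outside.  A run in which no
plot is visible in any camera raises `FrameMismatchError` — the usual
symptom of plots, DSM, offset and P-matrices in different frames —
whereas a single off-field camera simply contributes zero rows.

## Evaluation

Areas are planar shoelace areas in CRS units.  Pairs are matched by
`(col, row)` attributes when both layers carry a consistent set, otherwise
by maximum-overlap bipartite assignment (`linear_sum_assignment`), which
reproduces per-plot comparison without requiring identical record order.
Spread uses the population SD (divisor *n*).  The per-pair identity
`IOU = 1/(1/P + 1/R − 1)` (fractional form) is exact and is asserted in
tests to 1e-9.

## Synthetic scenes

The generator emulates: a rectangular grid of solid planted cells (plants
fill the cell width and a centered `plant_fill` fraction of its height),
additive uniform color noise (±10 by default) around distinct soil/plant
colors, off-plot weed disks with diameter ≤ `weed_max_size_px` (area
< π/4·d², hence provably removable by `noise` ≥ 30 at the default d = 5),
global field rotation, a smooth ±0.2 m relief plus 0.3 m crop height as
the DSM, and nadir pinhole cameras at 30 m whose P-matrices follow the
`K·[R|t]` construction in an offset-subtracted frame (offset defaults to
the floored field center, deliberately nonzero).  Default grid: 4 columns
× 34 rows of 48×32 px cells with 14/12 px gaps at 1 cm ground sampling.
The world frame is local planar metric — no geodesy, since the math is
affine throughout; the CRS tag is an opaque string carried verbatim.

Not emulated: shadows, vignetting, canopy texture and overlap, growth
stages, perspective or stitching artifacts, non-rectangular plots.
Passing tests therefore show correctness of the geometry and of the
profile logic under ideal radiometry, not robustness to difficult imagery
— for poor light or color variation the intended route is an externally
segmented binary mask (`input_type="binary"`).

## Numerical choices and degenerate inputs

Nearest-neighbour resampling everywhere a mask is warped.  Otsu ties →
lowest level.  Profile-erasure ties → kept.  Empty mask, all-zero profile,
constant ExG, zero-area polygons, empty camera/plot lists, cardinality
mismatches → explicit errors, never silent results.  The minimum-area
rectangle of fewer than 4 boundary points degrades to angle 0.

## Test and verification sizes

The suite runs synthetic scenes from 1×1 up to 9×39 cells; the end-to-end
recovery check covers the three trial-field layouts (4×34, 7×48, 9×39) at
tilts 0/±5/±12° with weeds, ~4100 plots total, in well under a minute.
Formula-level checks compare Otsu against an exhaustive 256-threshold scan
on 1000 random histograms, transition scanning against literal run-length
encoding on 1000 random vectors, the population SD against a two-pass
formula, and P-matrix projection against an explicit `K(RX+t)` pinhole on
100 random points at 1e-9.

## Known limitations

* Reconciliation can only drop or merge intervals; a column genuinely
  split by a planting failure larger than the merge window will abort the
  run rather than guess.
* The rotation estimate assumes one dominant grid orientation; ROIs
  containing two differently oriented fields are out of scope.
* Shapefile I/O covers single-ring 2-D polygons with flat numeric/text
  attributes — sufficient for plot layers, not a general GIS reader.
* Lens distortion is not modelled; the P-matrix is taken as the complete
  camera description, so reverse projection inherits whatever residual
  distortion the SfM calibration left.
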