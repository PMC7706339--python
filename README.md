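# microplots

Semiautomatic microplot extraction from UAV orthomosaics of breeding
fields.

Plant-breeding trials are laid out as a grid of *microplots*: long planted
columns, each subdivided into crop rows, one experimental unit per cell.
High-throughput phenotyping pipelines need every microplot cut out of the
field orthomosaic — usually a slow, manual GIS job.  `microplots` automates
it from four user inputs (number of columns, crop rows per column, column
orientation, and a noise size) plus an optional region-of-interest polygon:

1. **Segmentation** — the Excess Green index `ExG = 2g − r − b` on
   chromaticity-normalized channels, binarized at the Otsu threshold
   (maximum between-class variance over 256 levels); connected components
   smaller than the `noise` parameter are removed.  Externally produced
   binary masks are accepted as-is.
2. **Grid detection** — the field is rotated to axis alignment via the
   minimum-area bounding rectangle of the vegetation.  Column edges come
   from the per-column white-pixel profile after an erosion + horizontal
   dilation: entries below 1/3 of the profile mean are erased and
   black↔white transitions mark edges.  Crop rows repeat the procedure
   inside each column along y with a 1/2-mean cutoff.  The interval count
   must equal the declared layout.
3. **Products** — a polygon shapefile (one record per plot, `col`/`row`
   attributes), a corner-coordinate spreadsheet, and per-plot image crops,
   all in the orthomosaic's coordinate system.
4. **Reverse calculation** — with the SfM outputs (per-image 3×4 P-matrix,
   offset vector, DSM), plot corners `(X, Y, Z)` are projected into each
   raw aerial frame: `(x, y, z)ᵗ = P·(X−oX, Y−oY, Z−oZ, 1)ᵗ`, `u = x/z`,
   `v = y/z`, with `Z` the mean DSM height under the plot — so traits can
   be measured at native image resolution.  Output is an 11-column CSV
   (column, row, image name, four `(u, v)` corners).
5. **Evaluation** — extracted plots vs reference plots:
   `IOU% = 100·|A∩B| / |A∪B|`, precision `P = |A∩B|/|A|`, recall
   `R = |A∩B|/|B|`, population SD; written as the 6-column comparison CSV.

A synthetic-scene generator (`microplots.synthetic`) fabricates
orthomosaics, truth grids, DSMs and cameras with known parameters, so the
whole pipeline is testable without flying a drone.

## Worked example

```python
import numpy as np
import microplots as mp
from microplots.evaluation import polygon_iou

# a 4-column x 34-row trial field, tilted 12 degrees, weeds present
spec = mp.SyntheticFieldSpec(n_columns=4, n_rows=34, rotation_deg=12.0, seed=7)
scene = mp.generate_field(spec)

mask = mp.segment_vegetation(scene.rgb_image, noise=30)
rotation = mp.estimate_rotation(mask)
plots = mp.extract_microplots(mask, mp.FieldLayout(4, 34), rotation,
                              scene.geotransform)

ious = [polygon_iou(p.world_polygon, t.world_polygon)
        for p, t in zip(plots, scene.truth_grid)]
print(f"recovered tilt: {rotation.angle_deg:.2f} deg")
print(f"plots extracted: {len(plots)}")
print(f"mean IOU vs truth: {np.mean(ious):.2f}%  (SD {mp.population_sd(ious):.2f}%)")
```

prints

```
recovered tilt: 12.00 deg
plots extracted: 136
mean IOU vs truth: 99.90%  (SD 0.04%)
```

i.e. the detected grid has exactly the declared 4 × 34 = 136 cells, the
field tilt was recovered to 0.01°, and the extracted plot polygons overlap
the generating truth almost perfectly.

The same run from the shell, on a scene written to disk:

```sh
microplots --input scene/ortho.tif --columns 4 --rows 34 --noise 30 \
    --pmatrix scene/pmatrix.txt --offset scene/offset.txt --dsm scene/dsm.tif \
    --raw-width 4000 --raw-height 3000 --manual-shp scene/truth/microplots.shp \
    --out out/
```

writes `out/microplots.shp`, `out/intersections.csv`, `out/crops/`,
`out/reverse.csv`, `out/evaluation.csv` and a `manifest.json` recording
every parameter and stage.  Stages whose inputs are missing are skipped
and marked so in the manifest.

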