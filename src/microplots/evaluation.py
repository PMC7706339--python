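"""Agreement between program-determined and reference microplot polygons.

Per matched plot pair the intersection-over-union

    IOU% = 100 * area(manual ∩ program) / area(manual ∪ program)

measures boundary agreement, and precision/recall split the disagreement by
side: P = TP / (TP + FP) is the fraction of program-labeled area that is
correct, R = TP / (TP + FN) the fraction of reference area recovered, with
TP the intersection area, FP the program-only area and FN the
reference-only area.  Spread is summarized with the *population* standard
deviation (divisor n).  Areas are planar (CRS-plane shoelace), matching how
plot shapefiles are compared in practice; no geodesic correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from shapely.geometry import Polygon

__all__ = [
    "EvaluationRecord",
    "EvaluationSummary",
    "polygon_iou",
    "precision_recall",
    "population_sd",
    "compare_plot_sets",
    "EVALUATION_CSV_COLUMNS",
]

EVALUATION_CSV_COLUMNS = ["plot_id", "program_area", "manual_area",
                          "intersection_area", "union_area", "iou"]


@dataclass
class EvaluationRecord:
    """Areas and agreement statistics for one plot pair."""

    plot_id: str
    program_area: float
    manual_area: float
    intersection_area: float  # TP
    union_area: float
    iou_pct: float
    precision_pct: float
    recall_pct: float

    @property
    def fp_area(self) -> float:
        return self.program_area - self.intersection_area

    @property
    def fn_area(self) -> float:
        return self.manual_area - self.intersection_area


@dataclass
class EvaluationSummary:
    n: int
    mean_iou: float
    sd_iou: float
    mean_precision: float
    sd_precision: float
    mean_recall: float
    sd_recall: float


def _as_polygon(p) -> Polygon:
    return p if isinstance(p, Polygon) else Polygon(np.asarray(p, dtype=float))


def polygon_iou(a, b) -> float:
    """Intersection-over-union of two simple polygons, in percent."""
    pa, pb = _as_polygon(a), _as_polygon(b)
    union = pa.union(pb).area
    if union == 0.0:
        raise ValueError("both polygons are degenerate (zero union area)")
    return 100.0 * pa.intersection(pb).area / union


def precision_recall(program, manual) -> tuple[float, float]:
    """(P, R) in percent: correct fraction of program resp. manual area."""
    pp, pm = _as_polygon(program), _as_polygon(manual)
    if pp.area == 0.0 or pm.area == 0.0:
        raise ValueError("zero-area polygon")
    inter = pp.intersection(pm).area
    return 100.0 * inter / pp.area, 100.0 * inter / pm.area


def population_sd(values) -> float:
    """Population standard deviation (divisor n, not n-1)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty vector")
    return float(np.sqrt(np.mean((values - values.mean()) ** 2)))


def _pair_indices(program_polys, manual_polys, program_recs, manual_recs):
    """Match plots by (col, row) attributes, else by greatest overlap."""
    def keyed(recs):
        keys = []
        for r in recs:
            lowered = {k.lower(): v for k, v in r.items()}
            if "col" in lowered and "row" in lowered:
                keys.append((int(lowered["col"]), int(lowered["row"])))
            else:
                return None
        return keys

    pk, mk = keyed(program_recs), keyed(manual_recs)
    if pk is not None and mk is not None and sorted(pk) == sorted(mk) \
            and len(set(pk)) == len(pk):
        lookup = {k: j for j, k in enumerate(mk)}
        return [(i, lookup[k]) for i, k in enumerate(pk)], pk

    # maximum-overlap bipartite assignment
    n = len(program_polys)
    overlap = np.zeros((n, n))
    for i, pp in enumerate(program_polys):
        for j, mp in enumerate(manual_polys):
            overlap[i, j] = pp.intersection(mp).area
    rows, cols = linear_sum_assignment(-overlap)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    for i, j in pairs:
        if overlap[i, j] == 0.0:
            raise ValueError(
                f"program plot {i} overlaps no reference plot; cannot pair")
    return pairs, None


def compare_plot_sets(program_file, manual_file, out_csv=None,
                      extended: bool = False):
    """Compare two polygon shapefiles plot by plot.

    Plots are paired by matching ``(col, row)`` attributes when both layers
    carry them, otherwise by maximum-overlap assignment.  Returns
    ``(records, summary)`` and optionally writes the six-column comparison
    CSV (plot id, program area, manual area, intersection, union, IOU);
    ``extended=True`` appends precision/recall columns.
    """
    from .shapefile_io import read_polygons

    prog_rings, prog_recs, _ = read_polygons(program_file)
    man_rings, man_recs, _ = read_polygons(manual_file)
    if len(prog_rings) != len(man_rings):
        raise ValueError(
            f"plot count mismatch: {len(prog_rings)} program vs "
            f"{len(man_rings)} reference polygons")
    prog_polys = [Polygon(r) for r in prog_rings]
    man_polys = [Polygon(r) for r in man_rings]
    pairs, keys = _pair_indices(prog_polys, man_polys, prog_recs, man_recs)

    records = []
    for i, j in pairs:
        pp, mp = prog_polys[i], man_polys[j]
        inter = pp.intersection(mp).area
        union = pp.union(mp).area
        plot_id = f"c{keys[i][0]:02d}_r{keys[i][1]:02d}" if keys else str(i)
        p_pct, r_pct = precision_recall(pp, mp)
        records.append(EvaluationRecord(
            plot_id=plot_id, program_area=pp.area, manual_area=mp.area,
            intersection_area=inter, union_area=union,
            iou_pct=100.0 * inter / union,
            precision_pct=p_pct, recall_pct=r_pct))

    ious = [r.iou_pct for r in records]
    precs = [r.precision_pct for r in records]
    recalls = [r.recall_pct for r in records]
    summary = EvaluationSummary(
        n=len(records),
        mean_iou=float(np.mean(ious)), sd_iou=population_sd(ious),
        mean_precision=float(np.mean(precs)), sd_precision=population_sd(precs),
        mean_recall=float(np.mean(recalls)), sd_recall=population_sd(recalls))

    if out_csv is not None:
        frame = pd.DataFrame({
            "plot_id": [r.plot_id for r in records],
            "program_area": [r.program_area for r in records],
            "manual_area": [r.manual_area for r in records],
            "intersection_area": [r.intersection_area for r in records],
            "union_area": [r.union_area for r in records],
            "iou": ious,
        }, columns=EVALUATION_CSV_COLUMNS)
        if extended:
            frame["precision"] = precs
            frame["recall"] = recalls
        frame.to_csv(Path(out_csv), index=False)
    return records, summary
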