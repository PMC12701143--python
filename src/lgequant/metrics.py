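"""Pairwise comparison metrics between two tasks' scar geometries.

Dice and Hausdorff measure geometric agreement; two LGE-specific
metrics trace disagreement back to the thresholding itself:

* TD, the threshold difference ``t1 - t2`` (signal-intensity units);
* ATDT, the area difference per threshold step
  ``(area1 - area2) / (t1 - t2)`` — how much scar area one intensity
  unit of threshold is worth between the two tasks.

Dice is computed on exact polygon areas (not binary masks); two empty
scars agree perfectly (Dice 1).  Metrics that are undefined (Hausdorff
of an empty scar, ATDT at equal thresholds) return ``None`` rather than
raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial.distance import directed_hausdorff
from shapely.geometry import MultiPolygon

from .scar import TaskResult

__all__ = [
    "SliceComparison",
    "dice",
    "hausdorff",
    "threshold_difference",
    "atdt",
    "compare_task_results",
]

HAUSDORFF_DENSIFY_PX = 0.1


@dataclass(frozen=True)
class SliceComparison:
    """Per-slice agreement metrics between two tasks."""

    sop_uid: str
    dsc: float
    hd_mm: float | None
    td: float | None
    atdt: float | None
    area_diff_mm2: float


def _area(geom) -> float:
    return 0.0 if geom is None or geom.is_empty else float(geom.area)


def dice(a, b) -> float:
    """Dice similarity 2|a∩b| / (|a|+|b|) on exact polygon areas."""
    area_a, area_b = _area(a), _area(b)
    if area_a == 0.0 and area_b == 0.0:
        return 1.0  # perfect agreement on absence
    inter = float(a.intersection(b).area)
    return 2.0 * inter / (area_a + area_b)


def _boundary_points(geom) -> np.ndarray:
    boundary = geom.boundary
    densified = shapely.segmentize(boundary, HAUSDORFF_DENSIFY_PX)
    return shapely.get_coordinates(densified)


def hausdorff(a, b, pixel_spacing: tuple[float, float]) -> float | None:
    """Symmetric boundary Hausdorff distance in mm.

    Boundaries are densified to segments of at most 0.1 pixel before the
    point-set distance; pixel coordinates are scaled by the mean of the
    row/column spacing (a warning is issued if they differ).
    """
    if a is None or b is None or a.is_empty or b.is_empty:
        return None
    sr, sc = pixel_spacing
    if not np.isclose(sr, sc):
        warnings.warn(
            f"anisotropic pixel spacing {pixel_spacing}; Hausdorff uses the mean",
            stacklevel=2,
        )
    scale = 0.5 * (sr + sc)
    pa = _boundary_points(a)
    pb = _boundary_points(b)
    d_ab = directed_hausdorff(pa, pb)[0]
    d_ba = directed_hausdorff(pb, pa)[0]
    return float(max(d_ab, d_ba) * scale)


def threshold_difference(t1: float | None, t2: float | None) -> float | None:
    """TD = t1 - t2; None when either threshold is undefined."""
    if t1 is None or t2 is None:
        return None
    return float(t1 - t2)


def atdt(area1: float, area2: float, t1: float | None, t2: float | None) -> float | None:
    """ATDT = (area1 - area2)/(t1 - t2); None on a zero threshold step."""
    if t1 is None or t2 is None or t1 == t2:
        return None
    return float((area1 - area2) / (t1 - t2))


def compare_task_results(res1: TaskResult, res2: TaskResult, case) -> list[SliceComparison]:
    """Slice-by-slice comparison of two task results on the same case."""
    scars1 = {s.sop_uid: s for s in res1.slices}
    scars2 = {s.sop_uid: s for s in res2.slices}
    rows: list[SliceComparison] = []
    for img in case.slices:
        sop = img.sop_uid
        if sop not in scars1 and sop not in scars2:
            continue
        s1, s2 = scars1.get(sop), scars2.get(sop)
        g1 = s1.scar_final if s1 else MultiPolygon()
        g2 = s2.scar_final if s2 else MultiPolygon()
        px_area = img.pixel_area_mm2
        a1, a2 = _area(g1) * px_area, _area(g2) * px_area
        t1 = s1.threshold if s1 else None
        t2 = s2.threshold if s2 else None
        rows.append(
            SliceComparison(
                sop_uid=sop,
                dsc=dice(g1, g2),
                hd_mm=hausdorff(g1, g2, img.pixel_spacing),
                td=threshold_difference(t1, t2),
                atdt=atdt(a1, a2, t1, t2),
                area_diff_mm2=a1 - a2,
            )
        )
    return rows
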