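"""Scar multipolygon generation, exclusions and per-case clinical results.

The scar of a slice is the union, over all pixels whose intensity is
greater than or equal to the threshold, of the part of the pixel square
lying inside the myocardial contour — i.e. an exact sub-pixel geometry,
not a binary mask.  Manually drawn exclusion regions (artifacts) are
subtracted afterwards; only the part of an exclusion that intersects
the raw scar counts toward the excluded volume.

Per case, eight clinical parameters are reported: myocardial mass [g],
scar mass [g], scar percentage [%], exclusion volume [mL], scar mass
before exclusions [g], number of slices, number of slices carrying a
reference (ROI or remote) annotation, and the summed remote area [mm²].
Masses use a myocardial density of 1.05 g/mL (the usual CMR convention;
configurable).  A slice's tissue volume is its contour area times the
through-plane slice distance (SpacingBetweenSlices if present, else
SliceThickness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPolygon

from .annotation_io import Case, ImageSlice, SliceAnnotations, Task
from .errors import (
    MetadataError,
    MissingAnnotationError,
    MissingGroundworkError,
    MissingReferenceError,
    UsageError,
)
from .raster import (
    WeightedSample,
    clean_shape,
    rasterize_exact,
    rasterize_mode,
    weighted_sample,
)
from .threshold import ThresholdResult, fwhm_threshold, nsd_threshold

__all__ = [
    "MYOCARDIAL_DENSITY_G_PER_ML",
    "SliceScar",
    "ClinicalResults",
    "TaskResult",
    "generate_scar",
    "apply_exclusions",
    "clinical_results",
    "run_task",
]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05

FALLBACK_POLICIES = ("none", "pooled", "nearest")


@dataclass
class SliceScar:
    """Scar geometry of one slice before and after exclusions."""

    sop_uid: str
    threshold: float | None
    scar_raw: MultiPolygon
    scar_final: MultiPolygon
    excluded_region: MultiPolygon


@dataclass(frozen=True)
class ClinicalResults:
    """The eight per-case clinical parameters."""

    myo_mass_g: float
    scar_mass_g: float
    scar_percent: float
    exclusions_volume_ml: float
    scar_mass_before_exclusions_g: float
    n_slices: int
    n_slices_with_reference: int
    remote_area_sum_mm2: float

    FIELDS = (
        "myo_mass_g",
        "scar_mass_g",
        "scar_percent",
        "exclusions_volume_ml",
        "scar_mass_before_exclusions_g",
        "n_slices",
        "n_slices_with_reference",
        "remote_area_sum_mm2",
    )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.FIELDS}


@dataclass
class TaskResult:
    """End-to-end output of one task on one case."""

    case_id: str
    task: Task
    thresholds: dict[str, ThresholdResult]
    slices: list[SliceScar]
    clinical: ClinicalResults
    derived: dict[str, SliceAnnotations]


def _mp(geom) -> MultiPolygon:
    """Coerce any polygonal result to a MultiPolygon, dropping slivers."""
    if geom is None or geom.is_empty:
        return MultiPolygon()
    polys = []
    for part in getattr(geom, "geoms", [geom]):
        if part.geom_type == "Polygon" and part.area > 0:
            polys.append(part)
        elif part.geom_type in ("MultiPolygon", "GeometryCollection"):
            polys.extend(
                p for p in part.geoms if p.geom_type == "Polygon" and p.area > 0
            )
    return MultiPolygon(polys)


def generate_scar(
    image: ImageSlice, myo: MultiPolygon, threshold: float
) -> MultiPolygon:
    """Exact scar geometry: bright pixel squares clipped to the myocardium.

    Every pixel whose square intersects the myocardium and whose
    intensity is >= threshold (inclusive) contributes its clipped
    sub-pixel geometry.
    """
    myo = clean_shape(myo)
    if myo.is_empty:
        raise MissingGroundworkError("scar generation requires a myocardial contour")
    touched = rasterize_mode(myo, image.grid, mode="touched")
    if touched.is_empty:
        return MultiPolygon()
    rows, cols = touched.pixel_indices()
    vals = image.pixels[rows, cols]
    bright = vals >= threshold
    if not np.any(bright):
        return MultiPolygon()
    r = rows[bright].astype(float)
    c = cols[bright].astype(float)
    boxes = shapely.box(c - 0.5, r - 0.5, c + 0.5, r + 0.5)
    bright_region = shapely.unary_union(boxes)
    return _mp(myo.intersection(bright_region))


def apply_exclusions(
    scar_raw: MultiPolygon, exclusions: MultiPolygon
) -> tuple[MultiPolygon, MultiPolygon]:
    """Subtract exclusion regions from the raw scar.

    Returns ``(scar_final, excluded_region)`` with
    ``excluded_region = exclusions ∩ scar_raw`` — exclusions outside the
    scar contribute nothing to the excluded volume.
    """
    scar_raw = _mp(scar_raw)
    exclusions = _mp(exclusions)
    if exclusions.is_empty or scar_raw.is_empty:
        return scar_raw, MultiPolygon()
    excluded = _mp(scar_raw.intersection(exclusions))
    final = _mp(scar_raw.difference(exclusions))
    return final, excluded


def clinical_results(
    case: Case,
    task: Task,
    per_slice: list[SliceScar],
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> ClinicalResults:
    """Aggregate per-slice geometry into the eight clinical parameters."""
    annotations = case.annotations.get(task, {})
    scar_by_sop = {s.sop_uid: s for s in per_slice}
    myo_vol = scar_vol = scar_raw_vol = excl_vol = 0.0  # mm^3
    remote_area = 0.0  # mm^2
    n_ref = 0
    for img in case.slices:
        ann = annotations.get(img.sop_uid)
        if ann is None:
            continue
        px_area = img.pixel_area_mm2
        if px_area <= 0 or img.slice_distance_mm <= 0:
            raise MetadataError(f"unusable spacing metadata on {img.sop_uid}")
        dz = img.slice_distance_mm
        myo_vol += ann.get("myo").area * px_area * dz
        remote_area += ann.get("remote").area * px_area
        if ann.has("roi") or ann.has("remote"):
            n_ref += 1
        ss = scar_by_sop.get(img.sop_uid)
        if ss is not None:
            scar_vol += ss.scar_final.area * px_area * dz
            scar_raw_vol += ss.scar_raw.area * px_area * dz
            excl_vol += ss.excluded_region.area * px_area * dz
    myo_mass = density * myo_vol / 1000.0
    scar_mass = density * scar_vol / 1000.0
    scar_raw_mass = density * scar_raw_vol / 1000.0
    if myo_mass <= 0:
        raise MissingGroundworkError(
            f"case {case.study_uid}: zero myocardial mass, scar percentage undefined"
        )
    return ClinicalResults(
        myo_mass_g=myo_mass,
        scar_mass_g=scar_mass,
        scar_percent=100.0 * scar_mass / myo_mass,
        exclusions_volume_ml=excl_vol / 1000.0,
        scar_mass_before_exclusions_g=scar_raw_mass,
        n_slices=len(case.slices),
        n_slices_with_reference=n_ref,
        remote_area_sum_mm2=remote_area,
    )


def _reference_kind(task: Task) -> str:
    return "roi" if task.method == "fwhm" else "remote"


def _slice_threshold(
    img: ImageSlice, ann: SliceAnnotations, task: Task
) -> ThresholdResult | None:
    """Threshold of one slice from its own reference annotation."""
    kind = _reference_kind(task)
    if not ann.has(kind):
        return None
    ref_sample = weighted_sample(img, rasterize_exact(ann.get(kind), img.grid))
    if task.method == "fwhm":
        myo_sample = weighted_sample(img, rasterize_exact(ann.get("myo"), img.grid))
        return fwhm_threshold(myo_sample, ref_sample, sop_uid=img.sop_uid)
    return nsd_threshold(ref_sample, task.n, sop_uid=img.sop_uid)


def _pooled_threshold(case: Case, task: Task, annotated: list[tuple[ImageSlice, SliceAnnotations]]):
    """Case-level threshold from all reference pixels pooled together."""
    kind = _reference_kind(task)
    ref_parts, myo_parts = [], []
    for img, ann in annotated:
        if ann.has(kind):
            ref_parts.append(
                weighted_sample(img, rasterize_exact(ann.get(kind), img.grid))
            )
            if task.method == "fwhm":
                myo_parts.append(
                    weighted_sample(img, rasterize_exact(ann.get("myo"), img.grid))
                )
    if not ref_parts:
        raise MissingReferenceError(
            f"case {case.study_uid}: no {kind} annotation on any slice for {task.label}"
        )
    ref = WeightedSample.concatenate(ref_parts)
    if task.method == "fwhm":
        return fwhm_threshold(WeightedSample.concatenate(myo_parts), ref, sop_uid="")
    return nsd_threshold(ref, task.n, sop_uid="")


def run_task(
    case: Case,
    task: Task,
    fallback: str = "none",
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> TaskResult:
    """Evaluate one task over one case: thresholds, scars, clinical results.

    ``fallback`` decides what happens on myocardium-bearing slices
    without their own reference annotation: ``none`` leaves them without
    scar, ``pooled`` applies the case-level threshold from all reference
    pixels, ``nearest`` borrows the nearest annotated slice's threshold.
    Gold tasks pass stored scar polygons through without thresholding.
    """
    if fallback not in FALLBACK_POLICIES:
        raise UsageError(f"unknown fallback policy {fallback!r}")
    annotations = case.annotations.get(task)
    if not annotations:
        raise MissingAnnotationError(
            f"case {case.study_uid} has no annotations for task {task.label}"
        )
    annotated = [
        (case.slice_for(sop), ann)
        for sop, ann in annotations.items()
        if ann.has("myo")
    ]
    annotated.sort(key=lambda pair: case.sop_uids.index(pair[0].sop_uid))
    thresholds: dict[str, ThresholdResult] = {}
    slices: list[SliceScar] = []
    derived: dict[str, SliceAnnotations] = {}

    if task.method == "gold":
        if not any(ann.has("scar") for _, ann in annotated):
            raise MissingAnnotationError(
                f"gold task {task.label} has no stored scar on case {case.study_uid}"
            )
        for img, ann in annotated:
            raw = _mp(ann.get("scar"))
            final, excluded = apply_exclusions(raw, ann.get("exclusion"))
            slices.append(SliceScar(img.sop_uid, None, raw, final, excluded))
            derived[img.sop_uid] = _derived_annotations(img.sop_uid, ann, final, excluded)
        clinical = clinical_results(case, task, slices, density=density)
        return TaskResult(case.study_uid, task, thresholds, slices, clinical, derived)

    # per-slice thresholds where a reference exists
    per_slice_t: dict[str, ThresholdResult] = {}
    for img, ann in annotated:
        t = _slice_threshold(img, ann, task)
        if t is not None:
            per_slice_t[img.sop_uid] = t
    if not per_slice_t:
        raise MissingReferenceError(
            f"case {case.study_uid}: task {task.label} has no reference annotation"
        )
    pooled = None
    if fallback == "pooled":
        pooled = _pooled_threshold(case, task, annotated)
    ref_order = [img.sop_uid for img, _ in annotated if img.sop_uid in per_slice_t]

    for idx, (img, ann) in enumerate(annotated):
        sop = img.sop_uid
        tres = per_slice_t.get(sop)
        if tres is None:
            if fallback == "pooled":
                tres = ThresholdResult(sop, pooled.method, pooled.threshold, pooled.inputs_summary)
            elif fallback == "nearest":
                order = case.sop_uids
                nearest = min(
                    ref_order, key=lambda u: (abs(order.index(u) - order.index(sop)), order.index(u))
                )
                src = per_slice_t[nearest]
                tres = ThresholdResult(sop, src.method, src.threshold, src.inputs_summary)
            else:
                continue  # no scar on this slice
        thresholds[sop] = tres
        raw = generate_scar(img, ann.get("myo"), tres.threshold)
        final, excluded = apply_exclusions(raw, ann.get("exclusion"))
        slices.append(SliceScar(sop, tres.threshold, raw, final, excluded))
        derived[sop] = _derived_annotations(sop, ann, final, excluded)

    clinical = clinical_results(case, task, slices, density=density)
    return TaskResult(case.study_uid, task, thresholds, slices, clinical, derived)


def _derived_annotations(
    sop_uid: str,
    groundwork: SliceAnnotations,
    scar_final: MultiPolygon,
    excluded: MultiPolygon,
) -> SliceAnnotations:
    """Groundwork plus the computed scar/exclusion geometry, ready to write."""
    contours = {
        k: v for k, v in groundwork.contours.items() if k not in ("scar", "exclusion")
    }
    contours["scar"] = _mp(scar_final)
    if not excluded.is_empty:
        contours["exclusion"] = _mp(excluded)
    return SliceAnnotations(sop_uid=sop_uid, contours=contours)
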