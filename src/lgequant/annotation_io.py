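"""DICOM stacks, annotation JSON, tasks and the file-based cohort store.

An LGE study is a short-axis stack of DICOM slices ordered base→apex.
Per-slice contour annotations (myocardium, ROI, remote region,
exclusions, scar) are stored as multipolygons in a small JSON schema in
continuous pixel coordinates (see :mod:`lgequant.raster` for the pixel
square convention).  A *task* identifies who produced an annotation set
and how: reader × method (gold / fwhm / nsd-with-n) × time interval.

A cohort lives in one directory::

    <cohort>/cohort.json                      index: tasks, case ids, labels
    <cohort>/cases/<study_uid>/dicom/*.dcm
    <cohort>/cases/<study_uid>/annotations/<task-label>.json
    <cohort>/cases/<study_uid>/ground_truth.json   (synthetic cases only)

Annotation JSON schema (canonical form: sorted keys, contours sorted by
kind, coordinates at 6-decimal precision, so files are diffable)::

    {"<sop_uid>": {"contours": [
        {"kind": "myo", "polygons": [
            {"exterior": [[x, y], ...], "holes": [[[x, y], ...], ...]}
        ]}, ...]}}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.errors import InvalidDicomError
from shapely.geometry import MultiPolygon, Polygon

from .errors import (
    AmbiguityError,
    GeometryError,
    InputError,
    MetadataError,
    UsageError,
    ValidationError,
)

__all__ = [
    "CONTOUR_KINDS",
    "ImageSlice",
    "SliceAnnotations",
    "Task",
    "Case",
    "Cohort",
    "read_dicom_stack",
    "read_annotations",
    "write_annotations",
    "annotations_to_dict",
    "load_cohort",
    "save_cohort_index",
]

CONTOUR_KINDS = ("myo", "roi", "remote", "exclusion", "scar")
COORD_DECIMALS = 6
MAX_TASKS = 20  # comparison views support between one and twenty tasks


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ImageSlice:
    """One LGE short-axis DICOM slice with geometry metadata."""

    sop_uid: str
    study_uid: str
    pixels: np.ndarray
    pixel_spacing: tuple[float, float]  # (row mm/px, col mm/px)
    slice_thickness: float
    spacing_between_slices: float | None
    position: tuple[float, float, float]
    orientation: tuple[float, ...] | None = None
    instance_number: int | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("pixels must be a non-empty 2-D grid")
        if self.pixel_spacing[0] <= 0 or self.pixel_spacing[1] <= 0:
            raise ValidationError("pixel spacing must be positive")
        if self.slice_thickness <= 0:
            raise ValidationError("slice thickness must be positive")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def grid(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]

    @property
    def slice_distance_mm(self) -> float:
        """Through-plane extent of one slice's tissue contribution.

        SpacingBetweenSlices when present (accounts for inter-slice
        gaps), else SliceThickness.
        """
        if self.spacing_between_slices is not None:
            return self.spacing_between_slices
        return self.slice_thickness


@dataclass
class SliceAnnotations:
    """The contour multipolygons attached to one image for one task."""

    sop_uid: str
    contours: dict[str, MultiPolygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for kind in self.contours:
            if kind not in CONTOUR_KINDS:
                raise ValidationError(
                    f"unknown contour kind {kind!r} on {self.sop_uid}; "
                    f"expected one of {CONTOUR_KINDS}"
                )
        self.contours = {k: _as_multipolygon(v) for k, v in self.contours.items()}

    def get(self, kind: str) -> MultiPolygon:
        return self.contours.get(kind, MultiPolygon())

    def has(self, kind: str) -> bool:
        geom = self.contours.get(kind)
        return geom is not None and not geom.is_empty

    def validate_containment(self, rel_tol: float = 1e-6) -> None:
        """Check that any stored scar lies inside the myocardium."""
        scar = self.get("scar")
        myo = self.get("myo")
        if scar.is_empty or myo.is_empty:
            return
        excess = scar.difference(myo.buffer(1e-6)).area
        if excess > rel_tol * max(scar.area, 1.0):
            raise ValidationError(
                f"scar extends outside myocardium on {self.sop_uid} "
                f"(excess area {excess:.3g} px^2)"
            )


@dataclass(frozen=True)
class Task:
    """Reader × method × time-interval identity of one annotation set."""

    reader: str
    method: str  # "gold" | "fwhm" | "nsd"
    n: int | None = None
    time_interval: str = ""
    software: str = ""

    def __post_init__(self) -> None:
        if self.method not in ("gold", "fwhm", "nsd"):
            raise UsageError(f"unknown method {self.method!r}")
        if self.method == "nsd":
            if self.n is None or not 1 <= int(self.n) <= 9:
                raise UsageError("nsd tasks require n in [1, 9]")
        elif self.n is not None:
            raise UsageError(f"n is only valid for nsd tasks, not {self.method}")

    @property
    def method_label(self) -> str:
        return f"nsd{self.n}" if self.method == "nsd" else self.method

    @property
    def label(self) -> str:
        return f"{self.reader}__{self.method_label}__{self.time_interval}"

    def to_dict(self) -> dict:
        d = {
            "reader": self.reader,
            "method": self.method,
            "time_interval": self.time_interval,
        }
        if self.method == "nsd":
            d["n"] = int(self.n)
        if self.software:
            d["software"] = self.software
        return d

    @staticmethod
    def from_dict(d: dict) -> "Task":
        return Task(
            reader=d["reader"],
            method=d["method"],
            n=d.get("n"),
            time_interval=d.get("time_interval", ""),
            software=d.get("software", ""),
        )


@dataclass
class Case:
    """One study: an ordered slice stack plus per-task annotations."""

    study_uid: str
    slices: list[ImageSlice]
    annotations: dict[Task, dict[str, SliceAnnotations]] = field(default_factory=dict)
    artifact_label: bool = False

    def __post_init__(self) -> None:
        uids = [s.sop_uid for s in self.slices]
        if len(set(uids)) != len(uids):
            raise ValidationError(f"duplicate SOP UIDs in case {self.study_uid}")

    @property
    def sop_uids(self) -> list[str]:
        return [s.sop_uid for s in self.slices]

    def slice_for(self, sop_uid: str) -> ImageSlice:
        for s in self.slices:
            if s.sop_uid == sop_uid:
                return s
        raise InputError(f"sop_uid {sop_uid} not in case {self.study_uid}")

    def add_annotations(self, task: Task, per_slice: dict[str, SliceAnnotations]) -> None:
        known = set(self.sop_uids)
        for sop in per_slice:
            if sop not in known:
                raise InputError(
                    f"annotation references unknown sop_uid {sop} "
                    f"in case {self.study_uid}"
                )
        self.annotations[task] = dict(per_slice)


@dataclass
class Cohort:
    """Named set of cases analysed under a common task list."""

    name: str
    case_ids: list[str]
    tasks: list[Task]
    artifact_labels: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= len(self.tasks) <= MAX_TASKS:
            raise UsageError(
                f"a cohort holds between 1 and {MAX_TASKS} tasks, got {len(self.tasks)}"
            )
        labels = [t.label for t in self.tasks]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate task identities in cohort")


# ---------------------------------------------------------------------------
# geometry (de)serialization helpers


def _as_multipolygon(geom) -> MultiPolygon:
    if geom is None or geom.is_empty:
        return MultiPolygon()
    if isinstance(geom, Polygon):
        return MultiPolygon([geom])
    if isinstance(geom, MultiPolygon):
        return geom
    raise GeometryError(f"expected (Multi)Polygon, got {geom.geom_type}")


def _ring_from_json(ring, sop_uid: str, index: str) -> list[tuple[float, float]]:
    pts = [
        (round(float(x), COORD_DECIMALS), round(float(y), COORD_DECIMALS))
        for x, y in ring
    ]
    if len(pts) < 4:
        raise ValidationError(
            f"ring {index} on {sop_uid} has fewer than 4 vertices"
        )
    if pts[0] != pts[-1]:
        raise ValidationError(
            f"open ring {index} on {sop_uid}: first vertex != last vertex"
        )
    return pts


def _polygon_from_json(pdict: dict, sop_uid: str, index: int) -> Polygon:
    exterior = _ring_from_json(pdict["exterior"], sop_uid, f"{index}/exterior")
    holes = [
        _ring_from_json(h, sop_uid, f"{index}/hole{j}")
        for j, h in enumerate(pdict.get("holes", []))
    ]
    poly = Polygon(exterior, holes)
    if not poly.is_valid:
        raise GeometryError(
            f"polygon {index} on {sop_uid} is invalid: "
            f"{__import__('shapely').is_valid_reason(poly)}"
        )
    return poly


def _ring_to_json(coords) -> list[list[float]]:
    return [[round(float(x), COORD_DECIMALS), round(float(y), COORD_DECIMALS)] for x, y in coords]


def _polygon_to_json(poly: Polygon) -> dict:
    return {
        "exterior": _ring_to_json(poly.exterior.coords),
        "holes": [_ring_to_json(r.coords) for r in poly.interiors],
    }


def annotations_to_dict(annotations: dict[str, SliceAnnotations]) -> dict:
    """Canonical JSON-ready dict for a per-slice annotation map."""
    out: dict = {}
    for sop in sorted(annotations):
        ann = annotations[sop]
        contours = []
        for kind in sorted(ann.contours):
            geom = ann.contours[kind]
            contours.append(
                {
                    "kind": kind,
                    "polygons": [_polygon_to_json(p) for p in geom.geoms],
                }
            )
        out[sop] = {"contours": contours}
    return out


def write_annotations(annotations: dict[str, SliceAnnotations], file: Path) -> None:
    """Serialize annotations canonically (diffable, byte-stable)."""
    file = Path(file)
    payload = annotations_to_dict(annotations)
    file.write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_annotations(file: Path) -> dict[str, SliceAnnotations]:
    """Parse an annotation JSON file into per-slice contour maps."""
    file = Path(file)
    try:
        payload = json.loads(file.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed annotation JSON {file}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ValidationError(f"annotation file {file} must hold a JSON object")
    result: dict[str, SliceAnnotations] = {}
    for sop, entry in payload.items():
        contours: dict[str, MultiPolygon] = {}
        for centry in entry.get("contours", []):
            kind = centry.get("kind")
            if kind not in CONTOUR_KINDS:
                raise ValidationError(
                    f"unknown contour kind {kind!r} for {sop} in {file}"
                )
            polys = [
                _polygon_from_json(p, sop, i)
                for i, p in enumerate(centry.get("polygons", []))
            ]
            polys = [p for p in polys if not p.is_empty]
            contours[kind] = MultiPolygon(polys)
        result[sop] = SliceAnnotations(sop_uid=sop, contours=contours)
    return result


# ---------------------------------------------------------------------------
# DICOM ingestion


_REQUIRED_TAGS = ("PixelSpacing", "SliceThickness", "ImagePositionPatient")


def _slice_from_dataset(ds) -> ImageSlice:
    for tag in _REQUIRED_TAGS:
        if getattr(ds, tag, None) is None:
            raise MetadataError(f"DICOM {getattr(ds, 'SOPInstanceUID', '?')} missing tag {tag}")
    pixels = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    if slope != 1.0 or intercept != 0.0:
        pixels = pixels * slope + intercept
    spacing = getattr(ds, "SpacingBetweenSlices", None)
    orientation = getattr(ds, "ImageOrientationPatient", None)
    instance = getattr(ds, "InstanceNumber", None)
    return ImageSlice(
        sop_uid=str(ds.SOPInstanceUID),
        study_uid=str(ds.StudyInstanceUID),
        pixels=pixels,
        pixel_spacing=(float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])),
        slice_thickness=float(ds.SliceThickness),
        spacing_between_slices=float(spacing) if spacing is not None else None,
        position=tuple(float(v) for v in ds.ImagePositionPatient),
        orientation=tuple(float(v) for v in orientation) if orientation else None,
        instance_number=int(instance) if instance is not None else None,
    )


def _stack_normal(slices: list[ImageSlice]) -> np.ndarray:
    for s in slices:
        if s.orientation is not None and len(s.orientation) == 6:
            row = np.asarray(s.orientation[:3])
            col = np.asarray(s.orientation[3:])
            normal = np.cross(row, col)
            norm = np.linalg.norm(normal)
            if norm > 0:
                return normal / norm
    return np.array([0.0, 0.0, 1.0])


def read_dicom_stack(directory: Path) -> Case:
    """Read every DICOM slice in a directory into one ordered Case.

    Slices are sorted base→apex by projecting ImagePositionPatient onto
    the stack normal (row direction × column direction); InstanceNumber
    and then SOP UID break ties.  File enumeration order is irrelevant.
    """
    directory = Path(directory)
    slices: list[ImageSlice] = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except (InvalidDicomError, OSError):
            continue
        slices.append(_slice_from_dataset(ds))
    if not slices:
        raise InputError(f"no parsable DICOM files in {directory}")
    study_uids = {s.study_uid for s in slices}
    if len(study_uids) > 1:
        raise AmbiguityError(
            f"directory {directory} mixes study UIDs: {sorted(study_uids)}"
        )
    normal = _stack_normal(slices)
    slices.sort(
        key=lambda s: (
            float(np.dot(np.asarray(s.position), normal)),
            s.instance_number if s.instance_number is not None else 0,
            s.sop_uid,
        )
    )
    return Case(study_uid=slices[0].study_uid, slices=slices)


# ---------------------------------------------------------------------------
# cohort store


def save_cohort_index(cohort: Cohort, cohort_dir: Path) -> Path:
    cohort_dir = Path(cohort_dir)
    cohort_dir.mkdir(parents=True, exist_ok=True)
    index = {
        "cohort": cohort.name,
        "tasks": [t.to_dict() for t in cohort.tasks],
        "cases": list(cohort.case_ids),
        "artifact_labels": {k: bool(v) for k, v in sorted(cohort.artifact_labels.items())},
    }
    path = cohort_dir / "cohort.json"
    path.write_text(json.dumps(index, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    return path


def load_cohort(cohort_dir: Path, load_cases: bool = True) -> tuple[Cohort, list[Case]]:
    """Load a cohort index and (optionally) its cases with annotations."""
    cohort_dir = Path(cohort_dir)
    index_path = cohort_dir / "cohort.json"
    if not index_path.exists():
        raise InputError(f"no cohort.json in {cohort_dir}")
    index = json.loads(index_path.read_text(encoding="utf-8"))
    cohort = Cohort(
        name=index["cohort"],
        case_ids=list(index["cases"]),
        tasks=[Task.from_dict(t) for t in index["tasks"]],
        artifact_labels={k: bool(v) for k, v in index.get("artifact_labels", {}).items()},
    )
    cases: list[Case] = []
    if load_cases:
        for case_id in cohort.case_ids:
            case_dir = cohort_dir / "cases" / case_id
            case = read_dicom_stack(case_dir / "dicom")
            case.artifact_label = cohort.artifact_labels.get(case_id, False)
            ann_dir = case_dir / "annotations"
            if ann_dir.exists():
                for task in cohort.tasks:
                    f = ann_dir / f"{task.label}.json"
                    if f.exists():
                        case.add_annotations(task, read_annotations(f))
            cases.append(case)
    return cohort, cases
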