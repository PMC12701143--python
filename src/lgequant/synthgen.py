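"""Synthetic LGE cohorts with controllable ground truth.

Each case is a short-axis stack whose myocardium is an annulus tapering
from base to apex.  Pixel intensities follow the two-component model
that intensity thresholding rests on: a darker healthy component and a
brighter enhanced (scar) component, drawn as truncated-at-zero normals
with controllable means and SDs (an optional Rician-style mode is
available).  The true scar is an angular sector of the annulus with a
chosen transmural extent, so the true scar fraction is known exactly
from the geometry.  Optional bright artifact patches emulate the image
faults that force manual exclusions.

Reference-region placement policies mirror how human readers differ:

* the FWHM ROI either includes or deliberately excludes the brightest
  myocardial pixel;
* the nSD remote region covers a small (~1/6-1/4), medium (~1/3-1/2) or
  large (>=1/2) fraction of the myocardium.

Everything (pixel data, annotations, ground-truth record, cohort index)
is written through the same readers/writers the analysis pipeline uses,
and is byte-deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage
from shapely.geometry import MultiPolygon, Point, Polygon

from .annotation_io import (
    Cohort,
    SliceAnnotations,
    Task,
    save_cohort_index,
    write_annotations,
)
from .errors import SpecError, UsageError
from .raster import rasterize_exact

__all__ = ["SynthSpec", "default_tasks", "generate_case", "generate_cohort"]

UID_ROOT = "1.2.826.0.1.3680043.8.498"
REMOTE_SIZES = {"small": 0.20, "medium": 0.40, "large": 0.55}
_CIRCLE_SEGS = 90  # quarter-circle segments for buffer()


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic case (defaults: a plausible LGE study)."""

    slices_per_case: int = 5
    image_size: tuple[int, int] = (128, 128)
    pixel_spacing: tuple[float, float] = (1.5, 1.5)  # mm/px
    slice_thickness: float = 8.0  # mm
    spacing_between_slices: float = 10.0  # mm
    center: tuple[float, float] = (63.5, 63.5)  # (x=col, y=row)
    outer_radius_base: float = 26.0  # px
    outer_radius_apex: float = 18.0  # px
    wall_thickness: float = 7.0  # px
    healthy_mean: float = 100.0
    healthy_sd: float = 10.0
    enhanced_mean: float = 300.0
    enhanced_sd: float = 20.0
    background_mean: float = 40.0
    background_sd: float = 8.0
    scar_fraction: float = 0.25  # angular fraction of the annulus
    scar_center_angle: float = 0.0  # radians
    transmural_extent: float = 1.0  # fraction of wall, from endocardium
    artifact_radius: float = 3.0  # px
    artifact_mean: float = 400.0
    artifact_sd: float = 30.0
    artifact_slice_prob: float = 1.0  # per-slice patch probability in artifact cases
    roi_policy: str = "include_brightest"  # or "exclude_brightest"
    roi_radius: float = 2.5  # px
    remote_size: str | float = "medium"
    rician: bool = False

    def __post_init__(self) -> None:
        if self.slices_per_case < 1:
            raise SpecError("need at least one slice per case")
        if self.enhanced_mean <= self.healthy_mean:
            raise SpecError("enhanced mean must exceed healthy mean")
        if not 0.0 <= self.scar_fraction <= 1.0:
            raise SpecError("scar fraction must be in [0, 1]")
        if not 0.0 < self.transmural_extent <= 1.0:
            raise SpecError("transmural extent must be in (0, 1]")
        if self.wall_thickness <= 0 or self.outer_radius_apex <= self.wall_thickness:
            raise SpecError("annulus radii must be positive and nested")
        if self.roi_policy not in ("include_brightest", "exclude_brightest"):
            raise SpecError(f"unknown roi policy {self.roi_policy!r}")
        if not 0.0 <= self.artifact_slice_prob <= 1.0:
            raise SpecError("artifact_slice_prob must be in [0, 1]")
        # remote wedge + scar wedge must fit around the annulus with margin
        margin = 0.25
        if self.remote_angular_halfwidth + np.pi * self.scar_fraction + margin > np.pi:
            raise SpecError(
                "remote region does not fit into the healthy sector "
                f"(remote fraction {self.remote_fraction}, scar fraction {self.scar_fraction})"
            )

    @property
    def remote_fraction(self) -> float:
        if isinstance(self.remote_size, str):
            try:
                return REMOTE_SIZES[self.remote_size]
            except KeyError:
                raise SpecError(f"unknown remote size {self.remote_size!r}") from None
        return float(self.remote_size)

    @property
    def remote_angular_halfwidth(self) -> float:
        return self.remote_fraction * np.pi  # area fraction == angle fraction

    def outer_radius(self, s: int) -> float:
        if self.slices_per_case == 1:
            return self.outer_radius_base
        t = s / (self.slices_per_case - 1)
        return self.outer_radius_base + t * (self.outer_radius_apex - self.outer_radius_base)


def default_tasks(reader: str = "synth", time_interval: str = "T0") -> list[Task]:
    """Gold + FWHM + 2SD..7SD, the standard comparison battery."""
    tasks = [
        Task(reader="gold", method="gold", time_interval=time_interval),
        Task(reader=reader, method="fwhm", time_interval=time_interval),
    ]
    tasks += [
        Task(reader=reader, method="nsd", n=n, time_interval=time_interval)
        for n in range(2, 8)
    ]
    return tasks


# ---------------------------------------------------------------------------
# geometry builders


def _circle(center: tuple[float, float], radius: float) -> Polygon:
    return Point(center).buffer(radius, quad_segs=_CIRCLE_SEGS)


def _wedge(center: tuple[float, float], a0: float, a1: float, radius: float) -> Polygon:
    """Filled circular sector from angle a0 to a1 (a1 > a0)."""
    steps = max(8, int(np.ceil((a1 - a0) / 0.02)))
    angles = np.linspace(a0, a1, steps)
    pts = [center] + [
        (center[0] + radius * np.cos(a), center[1] + radius * np.sin(a))
        for a in angles
    ]
    return Polygon(pts)


def _annulus(spec: SynthSpec, s: int) -> Polygon:
    r_out = spec.outer_radius(s)
    return _circle(spec.center, r_out).difference(
        _circle(spec.center, r_out - spec.wall_thickness)
    )


def _scar_region(spec: SynthSpec, s: int) -> MultiPolygon:
    if spec.scar_fraction <= 0.0:
        return MultiPolygon()
    r_out = spec.outer_radius(s)
    r_in = r_out - spec.wall_thickness
    r_scar_out = r_in + spec.transmural_extent * spec.wall_thickness
    band = _circle(spec.center, r_scar_out).difference(_circle(spec.center, r_in))
    if spec.scar_fraction >= 1.0:
        region = band
    else:
        half = np.pi * spec.scar_fraction
        wedge = _wedge(
            spec.center,
            spec.scar_center_angle - half,
            spec.scar_center_angle + half,
            r_out + 5.0,
        )
        region = band.intersection(wedge)
    if region.geom_type == "Polygon":
        return MultiPolygon([region])
    return MultiPolygon([g for g in region.geoms if g.geom_type == "Polygon"])


def _remote_region(spec: SynthSpec, s: int) -> Polygon:
    r_out = spec.outer_radius(s)
    half = spec.remote_angular_halfwidth
    center_angle = spec.scar_center_angle + np.pi
    wedge = _wedge(spec.center, center_angle - half, center_angle + half, r_out + 5.0)
    return _annulus(spec, s).intersection(wedge)


def _artifact_center(spec: SynthSpec, s: int) -> tuple[float, float]:
    """Artifact disc placed in the gap between scar and remote wedges."""
    scar_half = np.pi * spec.scar_fraction
    remote_edge = np.pi - spec.remote_angular_halfwidth
    angle = spec.scar_center_angle + 0.5 * (scar_half + remote_edge)
    r_out = spec.outer_radius(s)
    r_mid = r_out - 0.5 * spec.wall_thickness
    return (
        spec.center[0] + r_mid * np.cos(angle),
        spec.center[1] + r_mid * np.sin(angle),
    )


# ---------------------------------------------------------------------------
# intensity synthesis


def _draw(rng: np.random.Generator, mean: float, sd: float, shape, rician: bool):
    if rician:
        re = rng.normal(mean, sd, shape)
        im = rng.normal(0.0, sd, shape)
        return np.sqrt(re**2 + im**2)
    return np.clip(rng.normal(mean, sd, shape), 0.0, None)


def _slice_pixels(
    spec: SynthSpec,
    s: int,
    rng: np.random.Generator,
    artifact: bool,
) -> tuple[np.ndarray, dict]:
    import shapely

    rows, cols = spec.image_size
    C, R = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    annulus = _annulus(spec, s)
    scar = _scar_region(spec, s)
    in_myo = shapely.intersects_xy(annulus, C, R)
    in_scar = (
        shapely.intersects_xy(scar, C, R) if not scar.is_empty else np.zeros_like(in_myo)
    )
    img = _draw(rng, spec.background_mean, spec.background_sd, (rows, cols), spec.rician)
    healthy = _draw(rng, spec.healthy_mean, spec.healthy_sd, (rows, cols), spec.rician)
    enhanced = _draw(rng, spec.enhanced_mean, spec.enhanced_sd, (rows, cols), spec.rician)
    img[in_myo] = healthy[in_myo]
    img[in_myo & in_scar] = enhanced[in_myo & in_scar]
    info = {"artifact": False}
    if artifact:
        ax, ay = _artifact_center(spec, s)
        disc = _circle((ax, ay), spec.artifact_radius)
        in_art = shapely.intersects_xy(disc, C, R)
        art = _draw(rng, spec.artifact_mean, spec.artifact_sd, (rows, cols), spec.rician)
        img[in_art] = art[in_art]
        info = {"artifact": True, "artifact_center": (ax, ay)}
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16), info


# ---------------------------------------------------------------------------
# reference placement


def _brightest_myo_pixel(pixels: np.ndarray, annulus, grid) -> tuple[int, int]:
    mask = rasterize_exact(annulus, grid)
    rr, cc = mask.pixel_indices()
    vals = pixels[rr, cc]
    k = int(np.argmax(vals))
    return int(rr[k]), int(cc[k])


def _roi_polygon(
    spec: SynthSpec, s: int, pixels: np.ndarray, annulus
) -> Polygon:
    """ROI disc inside the enhanced myocardium, per placement policy."""
    grid = pixels.shape
    br, bc = _brightest_myo_pixel(pixels, annulus, grid)
    r_out = spec.outer_radius(s)
    r_mid = r_out - 0.5 * spec.wall_thickness
    if spec.roi_policy == "include_brightest":
        roi = _circle((float(bc), float(br)), spec.roi_radius).intersection(annulus)
        return roi
    # exclude_brightest: scan candidate angles inside the scar sector,
    # keeping the disc clear of the brightest pixel's square
    half = np.pi * max(spec.scar_fraction, 1e-3)
    for da in np.linspace(0.0, half * 0.8, 17):
        for sign in (1.0, -1.0):
            angle = spec.scar_center_angle + sign * da
            cx = spec.center[0] + r_mid * np.cos(angle)
            cy = spec.center[1] + r_mid * np.sin(angle)
            if np.hypot(cx - bc, cy - br) > spec.roi_radius + 1.0:
                return _circle((cx, cy), spec.roi_radius).intersection(annulus)
    raise SpecError("could not place a ROI excluding the brightest pixel")


# ---------------------------------------------------------------------------
# DICOM writing


def _write_slice_dicom(
    path: Path,
    pixels: np.ndarray,
    spec: SynthSpec,
    study_uid: str,
    series_uid: str,
    sop_uid: str,
    instance: int,
    z: float,
) -> None:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = f"{UID_ROOT}.1"
    meta.ImplementationVersionName = "LGEQUANT01"

    ds = FileDataset(str(path), Dataset(), file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = sop_uid
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "MR"
    ds.SeriesDescription = "synthetic LGE SAX"
    ds.ContentDate = "20240101"
    ds.ContentTime = "000000"
    ds.InstanceNumber = instance
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.ImageOrientationPatient = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]
    ds.PixelSpacing = [float(spec.pixel_spacing[0]), float(spec.pixel_spacing[1])]
    ds.SliceThickness = float(spec.slice_thickness)
    ds.SpacingBetweenSlices = float(spec.spacing_between_slices)
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(pixels, dtype="<u2").tobytes()
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# case / cohort generation


def generate_case(
    spec: SynthSpec,
    seed: int,
    out_dir: Path,
    study_uid: str | None = None,
    artifact: bool = False,
    tasks: list[Task] | None = None,
) -> dict:
    """Write one synthetic case (DICOMs + annotations + ground truth).

    Deterministic given ``seed``.  Returns the ground-truth record.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    if study_uid is None:
        study_uid = f"{UID_ROOT}.{seed % (2**31)}.1"
    if tasks is None:
        tasks = default_tasks()
    dicom_dir = out_dir / "dicom"
    ann_dir = out_dir / "annotations"
    dicom_dir.mkdir(parents=True, exist_ok=True)
    ann_dir.mkdir(parents=True, exist_ok=True)
    series_uid = f"{study_uid}.0"

    per_task_ann: dict[str, dict[str, SliceAnnotations]] = {t.label: {} for t in tasks}
    truth_slices = []
    myo_area_total = scar_area_total = 0.0

    # decide patch-bearing slices up front; an artifact case gets >= 1
    patch = np.zeros(spec.slices_per_case, dtype=bool)
    if artifact:
        patch = rng.uniform(size=spec.slices_per_case) < spec.artifact_slice_prob
        if not patch.any():
            patch[spec.slices_per_case // 2] = True

    for s in range(spec.slices_per_case):
        sop_uid = f"{study_uid}.{s + 1}"
        pixels, info = _slice_pixels(spec, s, rng, bool(patch[s]))
        z = s * spec.spacing_between_slices
        _write_slice_dicom(
            dicom_dir / f"slice_{s:02d}.dcm",
            pixels, spec, study_uid, series_uid, sop_uid, s + 1, z,
        )
        annulus = _annulus(spec, s)
        scar = _scar_region(spec, s)
        remote = _remote_region(spec, s)
        myo_area_total += annulus.area
        scar_area_total += scar.area

        exclusion = MultiPolygon()
        if info["artifact"]:
            exclusion = MultiPolygon(
                [_circle(info["artifact_center"], spec.artifact_radius + 1.5)]
            )

        roi = None
        for task in tasks:
            contours = {"myo": annulus}
            if task.method == "gold":
                contours["scar"] = scar
            elif task.method == "fwhm":
                if roi is None:
                    roi = _roi_polygon(spec, s, pixels.astype(float), annulus)
                contours["roi"] = roi
                if not exclusion.is_empty:
                    contours["exclusion"] = exclusion
            else:  # nsd
                contours["remote"] = remote
                if not exclusion.is_empty:
                    contours["exclusion"] = exclusion
            per_task_ann[task.label][sop_uid] = SliceAnnotations(
                sop_uid=sop_uid, contours=dict(contours)
            )
        truth_slices.append(
            {
                "sop_uid": sop_uid,
                "outer_radius_px": spec.outer_radius(s),
                "myo_area_px2": annulus.area,
                "scar_area_px2": scar.area,
                "artifact": bool(info["artifact"]),
            }
        )

    for task in tasks:
        write_annotations(per_task_ann[task.label], ann_dir / f"{task.label}.json")

    truth = {
        "study_uid": study_uid,
        "seed": int(seed),
        "artifact": bool(artifact),
        "true_scar_fraction": scar_area_total / myo_area_total,
        "true_scar_percent": 100.0 * scar_area_total / myo_area_total,
        "healthy": [spec.healthy_mean, spec.healthy_sd],
        "enhanced": [spec.enhanced_mean, spec.enhanced_sd],
        "roi_policy": spec.roi_policy,
        "remote_fraction": spec.remote_fraction,
        "slices": truth_slices,
    }
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return truth


def generate_cohort(
    spec: SynthSpec,
    n_cases: int,
    artifact_fraction: float,
    seed: int,
    out_dir: Path,
    name: str = "synthetic",
    tasks: list[Task] | None = None,
) -> Cohort:
    """Write a labeled cohort of synthetic cases under ``out_dir``."""
    if n_cases < 1:
        raise UsageError("n_cases must be >= 1")
    if not 0.0 <= artifact_fraction <= 1.0:
        raise UsageError("artifact_fraction must be in [0, 1]")
    out_dir = Path(out_dir)
    if tasks is None:
        tasks = default_tasks()
    n_artifact = int(round(n_cases * artifact_fraction))
    case_ids, labels = [], {}
    base = int(seed) % (2**31)
    for i in range(n_cases):
        study_uid = f"{UID_ROOT}.{base}.{i + 1}"
        has_artifact = i < n_artifact
        case_seed = (base * 1000 + i) % (2**31)
        generate_case(
            spec,
            seed=case_seed,
            out_dir=out_dir / "cases" / study_uid,
            study_uid=study_uid,
            artifact=has_artifact,
            tasks=tasks,
        )
        case_ids.append(study_uid)
        labels[study_uid] = has_artifact
    cohort = Cohort(name=name, case_ids=case_ids, tasks=tasks, artifact_labels=labels)
    save_cohort_index(cohort, out_dir)
    return cohort
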