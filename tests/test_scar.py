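"""Scar geometry, exclusions, clinical parameters, task execution."""

import numpy as np
import pytest
from shapely.geometry import MultiPolygon, box

from lgequant import (
    ImageSlice,
    SliceAnnotations,
    Task,
    apply_exclusions,
    clinical_results,
    generate_scar,
    run_task,
)
from lgequant.annotation_io import Case
from lgequant.errors import MissingAnnotationError, MissingGroundworkError
from lgequant.scar import SliceScar

from conftest import star_polygon, supersample_weights


def make_slice(pixels, spacing=(1.0, 1.0), thickness=10.0, gap=None, sop="s1", z=0.0):
    return ImageSlice(
        sop_uid=sop,
        study_uid="st1",
        pixels=np.asarray(pixels, dtype=float),
        pixel_spacing=spacing,
        slice_thickness=thickness,
        spacing_between_slices=gap,
        position=(0.0, 0.0, z),
    )


class TestGenerateScar:
    def test_threshold_above_max_gives_empty(self, rng):
        img = make_slice(rng.uniform(0, 100, (20, 20)))
        myo = MultiPolygon([star_polygon(rng)])
        assert generate_scar(img, myo, 101.0).is_empty

    def test_threshold_below_min_saturates_to_myo(self, rng):
        img = make_slice(rng.uniform(50, 100, (20, 20)))
        myo = MultiPolygon([star_polygon(rng)])
        scar = generate_scar(img, myo, 0.0)
        assert scar.area == pytest.approx(myo.area, rel=1e-6)

    def test_inclusive_comparison_at_threshold(self):
        img = make_slice(np.full((6, 6), 200.0))
        myo = MultiPolygon([box(0.5, 0.5, 4.5, 4.5)])
        scar = generate_scar(img, myo, 200.0)  # equality counts as scar
        assert scar.area == pytest.approx(16.0, rel=1e-9)

    def test_two_level_image_matches_supersampling_oracle(self, rng):
        """Scar area of a bright/dark split equals the supersampled
        overlap of bright pixel squares with the myocardium."""
        px = np.full((24, 24), 100.0)
        px[:, 12:] = 300.0  # right half enhanced
        img = make_slice(px)
        myo = MultiPolygon([star_polygon(rng, center=(11.5, 11.5), r_mean=7.0)])
        scar = generate_scar(img, myo, 200.0)
        bright = box(11.5, -0.5, 23.5, 23.5)  # pixel squares of columns >= 12
        expected = supersample_weights(
            myo.intersection(bright), (0, 23, 0, 23), k=64
        ).sum()
        assert scar.area == pytest.approx(expected, abs=5e-2)
        # and exactly against the analytic overlap
        assert scar.area == pytest.approx(myo.intersection(bright).area, rel=1e-9)

    def test_scar_area_non_increasing_in_threshold(self, rng):
        img = make_slice(rng.uniform(0, 300, (20, 20)))
        myo = MultiPolygon([star_polygon(rng)])
        areas = [generate_scar(img, myo, t).area for t in np.linspace(0, 310, 25)]
        assert all(a >= b - 1e-9 for a, b in zip(areas, areas[1:]))

    def test_empty_myo_is_groundwork_error(self):
        img = make_slice(np.zeros((5, 5)))
        with pytest.raises(MissingGroundworkError):
            generate_scar(img, MultiPolygon(), 10.0)


class TestExclusions:
    def test_empty_exclusions_pass_through(self, rng):
        scar = MultiPolygon([star_polygon(rng)])
        final, excluded = apply_exclusions(scar, MultiPolygon())
        assert final.area == pytest.approx(scar.area)
        assert excluded.is_empty

    def test_total_exclusion_empties_scar(self, rng):
        scar = MultiPolygon([star_polygon(rng, r_mean=3.0)])
        cover = MultiPolygon([box(-20, -20, 40, 40)])
        final, excluded = apply_exclusions(scar, cover)
        assert final.is_empty
        assert excluded.area == pytest.approx(scar.area, rel=1e-9)

    def test_area_additivity_random_geometries(self, rng):
        for _ in range(15):
            scar = MultiPolygon([star_polygon(rng)])
            excl = MultiPolygon([star_polygon(rng, center=(9.0, 7.0), r_mean=3.0)])
            final, excluded = apply_exclusions(scar, excl)
            assert final.area + excluded.area == pytest.approx(scar.area, rel=1e-6)

    def test_exclusions_outside_scar_contribute_nothing(self):
        scar = MultiPolygon([box(0, 0, 2, 2)])
        excl = MultiPolygon([box(10, 10, 12, 12)])
        final, excluded = apply_exclusions(scar, excl)
        assert excluded.is_empty
        assert final.area == pytest.approx(4.0)


def case_with_annulus(area_mm2=1000.0, thickness=10.0, scar_area_frac=0.0):
    """One-slice case: square myo contour of the requested physical area."""
    side = np.sqrt(area_mm2)  # 1 mm pixels
    px = np.full((64, 64), 100.0)
    myo = MultiPolygon([box(0.5, 0.5, 0.5 + side, 0.5 + side)])
    img = make_slice(px, spacing=(1.0, 1.0), thickness=thickness)
    task = Task(reader="r", method="gold")
    scar = MultiPolygon()
    if scar_area_frac:
        scar = MultiPolygon([box(0.5, 0.5, 0.5 + side * scar_area_frac, 0.5 + side)])
    ann = SliceAnnotations("s1", {"myo": myo, "scar": scar})
    case = Case(study_uid="st1", slices=[img])
    case.add_annotations(task, {"s1": ann})
    return case, task, myo, scar


class TestClinicalResults:
    def test_mass_formula_at_density_1_05(self):
        case, task, myo, _ = case_with_annulus(area_mm2=1000.0, thickness=10.0)
        per = [SliceScar("s1", None, MultiPolygon(), MultiPolygon(), MultiPolygon())]
        res = clinical_results(case, task, per)
        assert res.myo_mass_g == pytest.approx(10.5, rel=1e-9)  # 10 mL * 1.05
        assert res.scar_mass_g == 0.0

    def test_full_scar_is_100_percent(self):
        case, task, myo, scar = case_with_annulus(scar_area_frac=1.0)
        per = [SliceScar("s1", None, scar, scar, MultiPolygon())]
        res = clinical_results(case, task, per)
        assert res.scar_percent == pytest.approx(100.0, rel=1e-9)

    def test_three_slice_totals_are_sums_of_slices(self, rng):
        imgs, anns, per = [], {}, []
        task = Task(reader="r", method="gold")
        expected_myo_vol = 0.0
        for i in range(3):
            sop = f"s{i}"
            img = make_slice(np.zeros((30, 30)), spacing=(1.5, 1.5),
                             thickness=8.0, gap=10.0, sop=sop, z=10.0 * i)
            myo = MultiPolygon([star_polygon(rng, center=(14, 14), r_mean=8.0)])
            scar = MultiPolygon([star_polygon(rng, center=(14, 14), r_mean=4.0)])
            scar = MultiPolygon([scar.geoms[0].intersection(myo.geoms[0])]) \
                if scar.geoms[0].intersection(myo.geoms[0]).geom_type == "Polygon" else myo
            imgs.append(img)
            anns[sop] = SliceAnnotations(sop, {"myo": myo, "scar": scar})
            per.append(SliceScar(sop, None, scar, scar, MultiPolygon()))
            expected_myo_vol += myo.area * 1.5 * 1.5 * 10.0
        case = Case(study_uid="st1", slices=imgs)
        case.add_annotations(task, anns)
        res = clinical_results(case, task, per)
        assert res.myo_mass_g == pytest.approx(1.05 * expected_myo_vol / 1000.0, rel=1e-9)
        assert res.n_slices == 3

    def test_mass_conservation_with_exclusions(self, rng):
        """mass before exclusions = mass after + density * excluded volume."""
        img = make_slice(rng.uniform(150, 300, (20, 20)), spacing=(1.2, 1.2),
                         thickness=9.0)
        task = Task(reader="r", method="gold")
        myo = MultiPolygon([star_polygon(rng)])
        ann = SliceAnnotations("s1", {"myo": myo, "scar": myo})
        case = Case(study_uid="st1", slices=[img])
        case.add_annotations(task, {"s1": ann})
        excl = MultiPolygon([star_polygon(rng, center=(9, 9), r_mean=3.0)])
        final, excluded = apply_exclusions(myo, excl)
        per = [SliceScar("s1", None, myo, final, excluded)]
        res = clinical_results(case, task, per)
        assert res.scar_mass_before_exclusions_g == pytest.approx(
            res.scar_mass_g + 1.05 * res.exclusions_volume_ml, rel=1e-6
        )


class TestRunTask:
    def test_gold_passthrough(self, small_cohort):
        case = small_cohort["cases"][0]
        gold = next(t for t in small_cohort["cohort"].tasks if t.method == "gold")
        res = run_task(case, gold)
        assert res.thresholds == {}
        assert res.clinical.scar_percent > 0
        truth_frac = None
        import json
        gt = json.loads(
            (small_cohort["dir"] / "cases" / case.study_uid / "ground_truth.json").read_text()
        )
        assert res.clinical.scar_percent == pytest.approx(gt["true_scar_percent"], abs=0.5)

    def test_gold_without_scar_raises(self, small_cohort):
        case = small_cohort["cases"][0]
        fake_gold = Task(reader="x", method="gold")
        fwhm = next(t for t in small_cohort["cohort"].tasks if t.method == "fwhm")
        # fwhm annotations carry no scar contour
        case.annotations[fake_gold] = case.annotations[fwhm]
        try:
            with pytest.raises(MissingAnnotationError):
                run_task(case, fake_gold)
        finally:
            del case.annotations[fake_gold]

    def test_fwhm_results_satisfy_invariants(self, small_cohort):
        case = small_cohort["cases"][0]
        fwhm = next(t for t in small_cohort["cohort"].tasks if t.method == "fwhm")
        res = run_task(case, fwhm)
        c = res.clinical
        assert 0 <= c.scar_percent <= 100
        assert c.scar_mass_g <= c.scar_mass_before_exclusions_g + 1e-12
        assert c.n_slices_with_reference <= c.n_slices
        assert c.remote_area_sum_mm2 == 0.0  # fwhm groundwork has no remote
        for sop, ss in zip(res.thresholds, res.slices):
            assert ss.scar_raw.area + 1e-9 >= ss.scar_final.area

    def test_nsd_scar_percent_non_increasing_in_n(self, small_cohort):
        case = small_cohort["cases"][1]
        percents = []
        for task in small_cohort["cohort"].tasks:
            if task.method == "nsd":
                percents.append((task.n, run_task(case, task).clinical.scar_percent))
        percents.sort()
        vals = [p for _, p in percents]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_derived_annotations_contain_scar_kind(self, small_cohort):
        case = small_cohort["cases"][0]
        task = next(t for t in small_cohort["cohort"].tasks if t.method == "nsd" and t.n == 4)
        res = run_task(case, task)
        for sop, ann in res.derived.items():
            assert "scar" in ann.contours
            ann.validate_containment()

    def test_artifact_case_needs_more_exclusion_than_clean(self, small_cohort):
        """Bright artifacts are caught by the threshold and must be
        excluded: the artifact case shows excluded volume, the clean
        case none (same task, same thresholding rules)."""
        task = next(t for t in small_cohort["cohort"].tasks if t.method == "nsd" and t.n == 4)
        by_label = {c.artifact_label: c for c in small_cohort["cases"]}
        res_art = run_task(by_label[True], task)
        res_clean = run_task(by_label[False], task)
        assert res_art.clinical.exclusions_volume_ml > res_clean.clinical.exclusions_volume_ml
        assert res_clean.clinical.exclusions_volume_ml == 0.0


def test_fwhm_roi_placement_effect(small_cohort):
    """A ROI that misses the brightest myocardial pixel lowers the
    threshold and can only enlarge the scar."""
    from lgequant import SynthSpec, generate_case, read_dicom_stack
    from lgequant.annotation_io import read_annotations
    import tempfile, pathlib

    results = {}
    with tempfile.TemporaryDirectory() as td:
        for policy in ("include_brightest", "exclude_brightest"):
            spec = SynthSpec(slices_per_case=1, roi_policy=policy)
            out = pathlib.Path(td) / policy
            generate_case(spec, seed=11, out_dir=out, artifact=False)
            case = read_dicom_stack(out / "dicom")
            task = Task(reader="synth", method="fwhm", time_interval="T0")
            case.add_annotations(
                task, read_annotations(out / "annotations" / f"{task.label}.json")
            )
            res = run_task(case, task)
            t = next(iter(res.thresholds.values())).threshold
            results[policy] = (t, res.clinical.scar_mass_g)
    t_inc, scar_inc = results["include_brightest"]
    t_exc, scar_exc = results["exclude_brightest"]
    assert t_exc < t_inc
    assert scar_exc >= scar_inc
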