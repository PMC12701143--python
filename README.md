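# lgequant

Scar quantification and multi-reader comparison for late-gadolinium-
enhancement (LGE) cardiac MRI.

In LGE imaging, fibrotic myocardium retains contrast agent and appears
bright, so the left-ventricular myocardium shows two overlapping
intensity distributions: a darker healthy component and a brighter
enhanced one.  How much of the muscle is scar depends heavily on *how*
that boundary is drawn — the thresholding method, the reader, and the
placement and size of the reference regions all shift the result.
`lgequant` is for researchers who need to quantify those differences
and trace them back to their causes, rather than trust a single number.

It implements, on exact sub-pixel polygon geometry:

* **FWHM thresholding** — `t = b_roi − (b_roi − d_myo)/2`, with `b_roi`
  the brightest pixel intensity inside a region of interest in enhanced
  myocardium and `d_myo` the darkest pixel of the myocardium;
* **nSD thresholding** — `t = m + n·s` for `n = 1..9`, with `m`, `s` the
  reliability-weighted mean and unbiased SD of a remote healthy region;
* **exact rasterization** — each boundary pixel carries the analytic
  fraction of its square covered by the contour, so histograms, extreme
  statistics and areas lose no sub-pixel information;
* **scar geometry** — pixels ≥ threshold clipped to the myocardium, with
  manual exclusion regions subtracted and accounted as excluded volume;
* **per-case clinical parameters** — myocardial mass, scar mass, scar %,
  exclusion volume, pre-exclusion scar mass, slice counts, remote area;
* **comparison metrics** — Dice, Hausdorff [mm], threshold difference
  `TD = t₁ − t₂`, and area difference per threshold step
  `ATDT = (area₁ − area₂)/(t₁ − t₂)`;
* **multi-task statistics** — up to 20 reader × method × time tasks,
  artifact subgrouping, closest-to-reference assignment, boxplot/tracking
  exports;
* **a synthetic cohort generator** — annulus myocardium, two-component
  intensities, controllable true scar fraction, artifact patches and
  reference-placement policies, so everything is testable offline.

## Worked example

```python
from lgequant import SynthSpec, generate_cohort, load_cohort, run_task

spec = SynthSpec(slices_per_case=4)          # true scar fraction: 25 %
generate_cohort(spec, n_cases=4, artifact_fraction=0.5, seed=42,
                out_dir="demo/cohort")
cohort, cases = load_cohort("demo/cohort")

case = cases[0]
print(f"case {case.study_uid} (artifact: {case.artifact_label})")
for task in cohort.tasks:
    res = run_task(case, task)
    c = res.clinical
    print(f"  {task.method_label:>5}: scar {c.scar_percent:5.1f} %  "
          f"({c.scar_mass_g:.1f} g of {c.myo_mass_g:.1f} g, "
          f"excluded {c.exclusions_volume_ml:.2f} mL)")
```

prints

```
case 1.2.826.0.1.3680043.8.498.42.1 (artifact: True)
   gold: scar  25.0 %  (19.2 g of 76.9 g, excluded 0.00 mL)
   fwhm: scar  24.2 %  (18.6 g of 76.9 g, excluded 2.54 mL)
   nsd2: scar  24.5 %  (18.8 g of 76.9 g, excluded 2.54 mL)
   nsd3: scar  24.3 %  (18.7 g of 76.9 g, excluded 2.54 mL)
   nsd4: scar  24.3 %  (18.7 g of 76.9 g, excluded 2.54 mL)
   nsd5: scar  24.3 %  (18.7 g of 76.9 g, excluded 2.54 mL)
   nsd6: scar  24.3 %  (18.7 g of 76.9 g, excluded 2.54 mL)
   nsd7: scar  24.3 %  (18.7 g of 76.9 g, excluded 2.54 mL)
```

The gold row is the stored ground-truth annotation (exactly the 25 %
the generator drew).  Every thresholding method lands within a fraction
of a percentage point of it because the synthetic intensity components
are well separated; the 2.54 mL excluded volume is the bright artifact
patch that the thresholds pick up as false scar and the exclusion
annotation removes.  Scar percentage is non-increasing in `n` by
construction of the nSD family.

The same pipeline runs from the shell:

```
lgequant synth    --out demo/cohort --cases 4 --slices 4 --seed 42
lgequant quantify --cohort demo/cohort --out demo/quant
lgequant compare  --cohort demo/cohort --reference gold__gold__T0 \
                  --out demo/report
```

`quantify` writes an eight-parameter clinical-results CSV and the
derived scar annotations (JSON, same schema as the input annotations);
`compare` writes per-task group statistics, the closest-to-reference
table, per-slice Dice/Hausdorff/TD/ATDT rows, and a boxplot with
per-case tracking lines.  Per-slice thresholds are logged as JSON lines
for headless difference tracing.

Real data: point `read_dicom_stack` at a directory of short-axis DICOM
slices and supply annotations in the documented JSON schema (pixel
coordinates, pixel centers integral; see `docs/methods.md`).

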