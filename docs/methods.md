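# Methods

`lgequant` quantifies myocardial scar in late-gadolinium-enhancement
(LGE) cardiac MRI from contour annotations, and compares the results of
multiple readers and thresholding methods against each other.  This
note records the models, numerical choices and known limitations.

## The measurement model

LGE imaging makes fibrotic myocardium bright: instead of the single
intensity distribution of healthy myocardium, an infarcted left
ventricle shows two overlapping components — a darker healthy one and a
brighter enhanced one.  Thresholding methods try to separate them:

* **FWHM** (full width at half maximum).  With `b_roi` the brightest
  pixel intensity inside a region of interest placed in enhanced
  myocardium and `d_myo` the darkest pixel intensity of the myocardium,

      t_fwhm = b_roi − (b_roi − d_myo) / 2.

* **nSD**.  With `m` and `s` the weighted mean and SD of a remote
  (healthy) myocardial region, assumed approximately normal,

      t_nsd = m + n·s,        n ∈ {1, …, 9}.

Scar on a slice is every pixel part inside the myocardial contour with
intensity ≥ threshold (inclusive).  Manually drawn exclusion regions
(artifacts) are subtracted afterwards; only the part of an exclusion
intersecting the raw scar counts toward the excluded volume.

## Exact rasterization

Annotations are polygons in continuous pixel coordinates; pixel
`(r, c)` is the closed square `[c−0.5, c+0.5] × [r−0.5, r+0.5]`.  The
convention that pixel *centers* are integral is fixed package-wide —
the alternative (integral corners) would shift every mask by half a
pixel, and nothing in common annotation formats pins this down.

A contour becomes a *weighted mask* in three steps: find all pixels
whose square intersects the shape; give fully covered pixels weight 1;
give each remaining boundary pixel the analytic area of
(square ∩ shape), computed by polygon clipping.  Pixels touching the
shape only along a zero-area boundary are dropped, so the support is
exactly the positive-measure pixels.  Total weight therefore equals the
polygon area to float rounding (tested at 1e-6 relative), and weighted
histograms and statistics lose no sub-pixel information.  Overlapping
members of an input multipolygon are unioned first so no pixel can
exceed weight 1.  `centroid` (pixel center inside) and `touched`
(square intersects) modes are provided for comparison; their supports
bracket the exact support.

This exactness matters most for FWHM: `b_roi` and `d_myo` are extreme
statistics, and a mask that misses a partially covered pixel can change
the threshold discontinuously.  Extremes are taken over the full
support — a pixel only 1 % inside the myocardium still counts for
`d_myo`, which mirrors how the weighted histograms display the data.

## Weighted statistics

The weighted mean is `Σxw / Σw`.  The SD uses reliability weights with
the standard unbiased correction:

    s² = Σ w(x − m)² · W / (W² − Σw²),     W = Σw.

With equal weights this reduces exactly to the textbook unbiased sample
SD (tested to 1e-12).  A sample needs effective size `W²/Σw² > 1`;
otherwise a degenerate-reference error is raised rather than returning
a meaningless 0/0.  nSD thresholds are affine-equivariant: rescaling
intensities by `a > 0` and shifting by `b` maps `t → a·t + b`, so
results do not depend on scanner intensity scaling.

## Thresholds per slice, and slices without a reference

Thresholds are computed per slice from that slice's own reference
annotation.  Reading protocols that annotate a reference only on some
slices (e.g. a single midventricular ROI) need a propagation rule; it
is configurable: `none` (default — no reference, no scar on that
slice), `pooled` (one case-level threshold from all reference pixels of
all slices), or `nearest` (borrow the nearest annotated slice's
threshold).  The default is deliberately conservative.

## Clinical parameters

Eight per-case parameters: myocardial mass [g], scar mass [g], scar
percentage [%], exclusion volume [mL], scar mass before exclusions [g],
slice count, count of slices with a reference annotation, and summed
remote area [mm²].  A slice's tissue volume is contour area ×
(row spacing × col spacing) × slice distance, where slice distance is
`SpacingBetweenSlices` when present, else `SliceThickness` (otherwise
inter-slice gaps would under-count mass).  Masses use a myocardial
density of 1.05 g/mL, the usual CMR convention; the constant is
configurable and cancels out of the scar percentage.  Exclusion volume
is reported in mL without a density factor.

## Comparison metrics

Dice is computed on exact polygon areas, not binary masks; two empty
scars have Dice 1 (agreement on absence).  Hausdorff distance is taken
between boundaries densified to ≤ 0.1 px segments and reported in mm
(mean of row/col spacing, with a warning if anisotropic).  Two
LGE-specific metrics trace differences back to the thresholding: the
threshold difference `TD = t₁ − t₂`, and the area difference per
threshold step `ATDT = (area₁ − area₂)/(t₁ − t₂)`, undefined at equal
thresholds.  ATDT is reported per slice; a case-level variant can be
formed from summed areas but both are kept distinct.

Multi-task aggregation (up to 20 tasks) uses ddof = 1 SDs,
linear-interpolation quartiles and 1.5·IQR whiskers; cases can be
filtered by their artifact label, and each case is assigned the
candidate task whose value is closest to a reference task (ties broken
by candidate order and flagged).

## DICOM handling

Slices are ordered base→apex by projecting `ImagePositionPatient` onto
the stack normal (row × column direction cosines), with
`InstanceNumber` and SOP UID as tie-breaks — sorting by SOP UID alone
is not geometrically meaningful across vendors.  The direction label is
metadata only; no computed quantity depends on it.  Rescale
slope/intercept are applied at load.

## Synthetic cohort generator

The generator emulates exactly the features the pipeline is sensitive
to, with known ground truth:

* an annulus-shaped myocardium tapering base→apex (default outer radius
  26 → 18 px at 1.5 mm/px, wall 7 px, 5 slices, 8 mm thick, 10 mm
  apart);
* two-component myocardial intensities — healthy N(100, 10²) and
  enhanced N(300, 20²), truncated at zero (an optional Rician-style
  mode exists, since scanner noise may be Rician or non-central χ);
* a true scar as an angular sector (default 25 % of the annulus, fully
  transmural), so the true scar fraction is known exactly from the
  geometry;
* bright artifact patches (N(400, 30²) discs) in the healthy sector of
  artifact-labeled cases, with matching exclusion annotations;
* reference-placement policies: the FWHM ROI either includes or
  deliberately avoids the brightest myocardial pixel; the nSD remote
  region covers a small (~1/6–1/4), medium (~1/3–1/2) or large (≥ 1/2)
  angular fraction of the myocardium.

Pixel class membership is decided at pixel centers; intensities are
drawn per pixel.  Everything is written through the package's own
DICOM/JSON writers and is byte-deterministic given the seed.

What the generator does **not** model: realistic anatomy, partial
voluming between tissue classes, bright blood pool (background is kept
dim at N(40, 8²) — the generator models the myocardial distribution the
thresholds operate on, not blood-pool physics), surface-coil intensity
gradients, or k-space artifacts.  Passing recovery tests therefore
demonstrates correctness of the computational pipeline under the
two-component model, not clinical accuracy on real scans, where the
distributions overlap far more.

## Problem sizes and tolerances

Tests and the acceptance script run on deliberately small instances
chosen as the package's own verification sizes: 128×128 slices, 2–5
slices per case, cohorts of 2–10 cases, 100-shape rasterization sweeps.
Geometric conservation is asserted at 1e-6 relative; equal-weight SD
reduction at 1e-12; parameter recovery at ±2 percentage points of the
true scar fraction; rasterizer-vs-supersampling agreement at 5e-3 per
pixel using a 64×64 stratified antithetic sampling oracle (a plain
fixed grid aliases on edges of small-rational slope).  Scar geometry
uses inclusive ≥ at the threshold; extreme statistics use exact
comparisons with no interpolation.

## Known limitations

* Gold tasks pass stored scar polygons through unchanged; they are not
  re-rasterized, so a gold scar drawn outside the myocardium is
  rejected by validation rather than clipped.
* Hausdorff on very fine structures is limited by the 0.1 px
  densification step.
* The file-based cohort store assumes one study per directory; there is
  no concurrency control.
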