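# Methods

## Scope and model overview

`y90pet` analyses post-treatment ⁹⁰Y PET studies of liver radioembolization
at the level of *reconstructed images*: it does not reconstruct (no OSEM,
TOF or sinograms), simulate list-mode events, or transport photons.  The
pipeline is

1. **Phantom** — a voxelized ground-truth activity distribution and label map;
2. **Acquisition surrogate** — PSF blur plus count-statistics noise per
   scan-duration/iteration condition;
3. **VOI analysis** — lesion and background statistics on identical voxel
   masks across all conditions;
4. **Image-quality metrics** — SNR_peak, SNR_mean, COV, LBR;
5. **Dosimetry** — local-deposition-model voxel dose, DVH statistics,
   partition-model compartment doses, planar geometric-mean lung shunt;
6. **Statistics** — paired Wilcoxon signed-rank comparisons over the
   condition grid.

## Phantom and study conditions

The default phantom lives on a 64³ grid of 3.3 × 3.3 × 1.65 mm voxels (a
long-axial-FOV PET reconstruction grid).  Tissue layout and concentrations:

| region | geometry | concentration | rationale |
|---|---|---|---|
| tumor | 20 mm-radius sphere in the liver | 6000 kBq/ml | ~290 Gy LDM dose, the clinical tumor-dose scale |
| normal liver | ellipsoid, ~0.42 L | 750 kBq/ml | ~36 Gy whole-liver normal-tissue dose |
| lungs | two ellipsoids, ~0.17 L | 10 kBq/ml | ~2 Gy mean lung dose, low shunt |
| scatter floor | abdominal halo around the liver | 500 kBq/ml | makes LBR land in the clinically observed 8–15 range |
| far background | elsewhere | 0 | cold thorax: the scatter floor must not blur into the lungs |

The scatter floor is a modelling device: in clinical ⁹⁰Y PET the "no-uptake"
background VOIs still read a sizeable baseline (lesion-to-background ratios
of order 10 despite lesion concentrations of thousands of kBq/ml).  A
uniform floor over the whole body would, after PSF blur, dominate the
low-uptake lungs, so it is confined to an abdominal ellipsoid that contains
all eight background VOIs and stays clear of the thorax.

Because the grid holds a ~0.42 L liver rather than a clinical 1.5–2 L organ,
the administered activity commensurate with the phantom is derived from it
(liver + lung activity, ≈ 0.49 GBq by default) instead of being fixed at a
clinical median.  Concentration and dose scales are preserved; volumes and
total activity are scaled down together.

Study conditions follow the clinical factorial: scan durations 20, 15, 10,
5, 1 min × OSEM iteration numbers 2, 4, 6, 8 (5 subsets implied), reference
condition 20 min / 2 iterations, 17 replicates standing in for a 17-patient
cohort.

## Acquisition surrogate

Each condition image is `clip(blur(truth) + ε, 0)` with

* **PSF**: isotropic Gaussian, default FWHM 6 mm, applied in mm-space on the
  anisotropic grid.  This is the *effective* system resolution (detector
  blur, positron/pair range, reconstruction filter combined); the
  reconstruction-side Gaussian filter alone would be ~2 mm.
* **Noise**: zero-mean Gaussian with per-voxel SD
  `g(it) · sqrt(mean / (c · t))`, the large-count limit of Poisson counting
  noise expressed in concentration units, where `c` is the calibration
  `counts_per_kbqml_min` and `t` the scan duration.  The iteration gain
  `g = {2: 1.0, 4: 1.15, 6: 1.3, 8: 1.45}` is a documented surrogate for
  OSEM convergence noise: more iterations amplify noise monotonically, with
  2 iterations as the unit reference.
* **Calibration**: `c = 0.04` counts/(kBq/ml·min)/voxel.  Chosen once so
  that every tissue stays ≥ ~4 SD from the zero-clip boundary at all
  durations — the domain where the Gaussian model and the `1/√t` law are
  exact.  Consequently absolute background COV (0.05 at 20 min, 0.22 at
  1 min) is lower than clinical values (≈0.4–0.8); the *ratios*, orderings
  and significance structure are the emulated quantities, not the absolute
  noise level (a clipped Gaussian cannot hold both).
* **Seeding**: every image's generator seed derives deterministically from
  (master seed, duration, iterations, replicate); identical configs are
  bit-identical, conditions and replicates are independent.

Planar anterior/posterior views for the shunt estimate are parallel
projections along the anterior–posterior axis of counts ∝ activity, with
per-organ multiplicative attenuation factors and optional Poisson noise.
The pre-treatment (MAA surrogate) phantom deliberately mis-specifies the
treatment distribution — tumor uptake ×1.09, lung uptake ×2, no soft-tissue
floor — to emulate the clinically observed predicted-vs-actual discrepancies
(prediction overshoots both tumor and lung dose).

## VOI protocol

Exactly one spherical lesion VOI and eight equal-radius background VOIs
(default radius 10 mm), drawn once on the reference grid and propagated as
*identical voxel index sets* to all 20 condition images.  Statistics:

* `lesion_peak`: mean over a 1 cm³ sphere (radius 6.20 mm) centered on the
  hottest lesion voxel; the sphere may leave the lesion VOI but not the grid
  (configurable to warn-and-clip, or to use an equal-volume cube).  Ties for
  the maximum resolve to the first voxel in array order.
* `bg_mean`: mean of the eight per-VOI means.
* `bg_sd`: sample SD (ddof = 1) of the voxels pooled over the eight VOIs.
  This is a voxel-noise SD, the scale COV needs; the SD *across* the eight
  VOI means (≈ √n smaller) is available behind `sd_mode="across_means"`.

Undefined metrics (zero background SD or mean) raise immediately rather
than emitting NaN rows.

## Dosimetry

**Voxel dose (LDM).**  All β energy is deposited in the source voxel:
`D = C·τ·Ē_β/ρ` with τ = T½/ln 2.  Constants are pinned in one
`PhysicsConstants` table (T½ = 64.05 h; Ē_β = 0.9267 MeV, ICRP-107; soft
tissue 1.03 g/ml; lung 0.26 g/ml; reference lung mass 1 kg) and passed
explicitly to every dose operation.  The map satisfies exact energy
conservation: Σ dose×mass = total activity × 49.39 J/GBq (the constant is
always derived, never hard-coded).

**DVH.**  D_x is the dose received by the hottest x% of the structure:
nearest-rank on the descending sort, rank ⌈x/100·n⌉, which guarantees
D2 ≥ D50 ≥ D70; a linear-interpolation variant sits behind a flag.

**Partition model.**  Liver-directed activity `A(1−LSF)` splits between
tumor and normal liver by image counts; lungs receive `A·LSF`; each
compartment dose is `49.39·A_c/m_c`.  In the pipeline, compartment masses
come from the segmented volumes and tissue densities (so predicted and
measured lung doses are commensurate); the standalone operation accepts any
masses, including the conventional 1 kg lung pair.

**Lung shunt.**  Per organ, the geometric mean of anterior and posterior ROI
*totals* — robust to zero pixels and exactly cancelling reciprocal
attenuation; `LSF = GM_lung/(GM_lung + GM_liver)`.  ROIs are projections of
the 3-D organ masks.  A utility flags mean lung dose ≥ 20 Gy.

The "actual" doses in the predicted-vs-actual table are replicate-averaged
LDM doses at the reference condition (20 min / 2 iterations), normalized to
imaged activity; the prediction uses the administered activity.  Both
normalizations are exposed because which one commercial compartment software
uses is not standardized.

## Statistics

Two-sided Wilcoxon signed-rank test on paired per-replicate values.  Zero
differences are dropped (classical convention; Pratt's method behind a
flag), ties in |d| get midranks.  For n ≤ 25 the p-value is *exact*: the
null distribution of W⁺ over all 2ⁿ sign patterns is built by dynamic
programming over doubled midranks — numerically identical to brute-force
enumeration (verified in tests) at polynomial cost; beyond that, the normal
approximation with tie correction (no continuity correction).  A cohort of
17 falls in the exact regime.  Quartiles use linear interpolation (numpy
default); whiskers are the most extreme data within 1.5·IQR of the
quartiles.  No multiple-testing correction is applied — comparisons are
reported pair by pair, matching common clinical practice; this is a
documented limitation, and "no difference" (p > 0.05) is never a formal
equivalence claim.

The comparison matrix covers the six duration pairs (20–15, 15–10, 10–5,
5–1, 20–5, 20–1 min) at the reference iteration number and the iteration
pairs (2–4, 2–6, 2–8) at the reference duration, for every image-quality and
dose metric.

## What passing tests do and do not show

The synthetic cohort consists of replicates of *one* phantom differing only
in noise realization.  There is no between-patient variability in anatomy,
uptake, injected activity or tumor burden, so systematic condition effects
(e.g. COV growing at shorter durations) are detected with near-certainty and
most pairwise p-values are small — unlike a clinical cohort, where
heterogeneity masks small effects.  Passing tests therefore demonstrate the
*correctness of the estimators and the machinery* (metrics, dose closed
forms, DVH ranks, shunt recovery, exact p-values, noise-law calibration),
not clinical effect sizes.  Likewise the acquisition surrogate reproduces
first- and second-moment behaviour of reconstructed images, not OSEM
convergence artifacts, scatter structure, motion or attenuation-correction
errors.

**Parameter recovery** is defined against the noise-free expectation image
(the PSF-blurred truth): with a 6 mm PSF and a 20 mm tumor, partial-volume
contrast loss is a deterministic ~13% that clinical reconstructions counter
with resolution modelling (out of scope here), so the noise-recovery
property — tumor Dmean within 5% at 20 min, D2 dispersing more at 1 min —
is measured against the simulator's own reference.

## Numerical choices and degenerate inputs

* Units: kBq/ml everywhere inside the package; converters at the boundary.
* Geometry: axis order (x, y, z), anterior–posterior = y, voxel centers at
  (index + 0.5)·size, 0-based indices; no resampling — all inputs must share
  one grid, and mismatches are rejected naming both grids.
* Sphere masks include a voxel iff its *center* is inside; an empty mask or
  a sphere leaving the grid is an error.
* Negative noise excursions clip at 0 (bias < 1e-2 kBq/ml at default
  calibration); the noiseless limit (`counts_per_kbqml_min = inf`) returns
  the blurred truth exactly.
* NIfTI I/O is bit-exact for float64 volumes; label maps carry a JSON
  sidecar naming each label's compartment role.
* All-zero paired differences give p = 1 with a warning flag; empty
  summaries, empty DVH masks, zero compartment masses/counts are errors.

## Problem sizes

Default analyses use the 64³ phantom with 17 replicates × 20 conditions
(≈ 3 s per full study on one CPU); Monte-Carlo checks use 30–50 replicates;
unit tests use a 32³ phantom.  These sizes give Monte-Carlo standard errors
well below the asserted tolerances (e.g. COV-ratio SE ≈ 0.5% against a ±15%
band).
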