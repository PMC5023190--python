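# Methods

`pavol` measures the central pulmonary arteries (MPA, RPA, LPA) in 3D
contrast-enhanced MR angiography: model-based tubular segmentation from one
seed point per vessel, centerline-referenced volumetry between anatomical
landmarks, indexing to vessel length and body surface area, and the cohort
statistics used to evaluate such measurements as predictors of pulmonary
hypertension.  This note records the models, the defaults and why, and what
the synthetic phantoms do and do not establish.

## Cylindrical intensity model

A local vessel segment is modeled as a straight circular cylinder of radius
`R` on background `a0` with plateau `a1`, convolved with an isotropic
Gaussian point-spread function of width `sigma`.  In the plane normal to
the axis the profile is the convolution of a disk indicator with a 2D
Gaussian, which has an exact closed form: with `d` the distance from the
axis,

    I(d) = a0 + (a1 - a0) * P( chi'^2_2(d^2/sigma^2) <= R^2/sigma^2 ),

the CDF of a noncentral chi-square with 2 degrees of freedom (equivalently
the Rice CDF `1 - Q1(d/sigma, R/sigma)`), evaluated with
`scipy.special.chndtr`.  For `R >> sigma` this reduces to the familiar edge
response `Phi((R-d)/sigma)`; we keep the exact form because the next-order
term, `-(sigma/2R) * phi((R-d)/sigma)`, is what distinguishes a curved tube
boundary from a straight edge.  Fitting the plain `Phi` model instead
biases the estimated radius low by about `sigma^2/(2R)` — 2.5% at `R = 5 mm`
and an effective blur of ~1.15 mm, which squared into a 5% volume error.
The exact profile agrees with a brute-force rasterized disk-blur oracle to
raster precision (≈0.5% of contrast; asserted in the acceptance suite at
the 2% level for `R >= 2 sigma`).

`sigma` is a free parameter of every fit.  It absorbs both the scanner PSF
and the partial-volume blur of the anisotropic grid, which is why fitted
values (~1.1–1.2 mm) exceed the nominal rendering PSF of 1.0 mm.

### Fitting

Each segment fit minimizes the squared intensity residual over a cylindrical
region of interest coaxial with the current tangent (radius `2.5 * R_init`
so the ROI always samples background, half-length 2 mm, sample spacing
0.7 mm in-plane / 1 mm axially, trilinear image interpolation; samples
outside the volume are dropped, and fewer than 50 valid samples is an
error).  Free parameters: in-plane center offset (2), tangent tilt (2),
`R`, `a0`, `a1`, `sigma`; the along-axis position is fixed by the tracking
step.  Bounded trust-region least squares (`scipy.optimize.least_squares`,
`trf`, numerical Jacobian, `xtol/ftol/gtol 1e-10`, max 200 evaluations)
with `R` in `[0.4 * min(spacing), 30] mm` and `sigma` in `[0.2, 4] mm`.
Optimizer failure, nonpositive contrast, or `R` pinned at a bound is
reported as `converged=False`, never an exception.

## Seed initialization and tracking

From one user seed: tangent from the principal eigenvector of the
intensity-weighted second-moment matrix in a 10 mm sphere; `a0`/`a1` from
the 10th/95th intensity percentiles there; radius from the median
half-contrast crossing along 16 normal-plane rays.  A seed whose local
contrast is below 5% of the local intensity scale is rejected ("seed not in
vessel").

Tracking marches in 1 mm steps both proximally and distally, each fit
initialized by extrapolating the previous one along its tangent.  Stop
rules (configuration defaults; the anatomical truth being tracked defines
none): fit non-convergence; contrast below 15% of the seed contrast; image
intensity at the fitted center below seed background + 50% of seed contrast
(this is the rule that actually fires at a vessel end, where the on-axis
intensity collapses within one blur width); bend > 60° per step; advance
along the march direction < 0.2 mm; leaving the volume; 200 mm length cap.
Tracking is deterministic given volume and seed.

## Refinement, centerline, diameters

Refinement is two-step: (1) the chain of fitted centers is smoothed
per-coordinate with a cubic smoothing spline over arclength
(`make_smoothing_spline`, GCV-selected penalty) and tangents are recomputed
from the spline; (2) every segment is refit with the tangent frozen and only
in-plane center, `R`, `a0`, `a1`, `sigma` free.  A per-station fallback
keeps the previous fit whenever the constrained refit would increase the
residual, so refinement cannot degrade the chain; degenerate spline
geometry returns the input unchanged with a warning flag.

The centerline runs along the geometric centroid of each cross-section
(polar sampling of the half-occupancy region; for the circular model this
coincides with the fitted center, so the operation matters mainly in
image-driven mode).  Arclength is cumulative chord length.  The average
diameter at each 1 mm station is the mean of opposing-ray pairs among 36
equiangular rays cast in the normal plane to the half-occupancy boundary
(sub-voxel by linear interpolation).  In the default model-driven mode the
boundary is the deblurred model indicator, so each ray returns the fitted
`R`: the reported diameter is vessel geometry, not blurred-image geometry.
Image-driven mode locates the half-contrast crossing of the image itself
and inherits a small inward bias of order `sigma^2/(2R)`.

### Blow-out QC

Poor bolus timing can merge a segmentation into the adjacent ascending
aorta.  Stations whose diameter exceeds 1.5x a running reference median are
flagged `suspect-merge` and excluded from measurement.  The reference is
the median of the 5 preceding unflagged stations *lagged by a 5-station
guard gap*: the local fit smears a merge into a ramp several stations wide,
and an unlagged reference absorbs the ramp and never fires.  Both traversal
directions are scanned so a blow-out at either chain end is caught.  A
vessel with more than 20% flagged stations inside its measurement window is
excluded outright (the study excluded affected vessels entirely; the 20%
rule is our operationalization).

## Volumetry

Landmarks (pulmonary valve level, MPA bifurcation, upper-lobe take-offs)
are supplied as world points and projected to centerline arclength (0.1 mm
resampling, ties toward smaller `s`, > 20 mm distance is an error).
Windows: MPA `[s_valve + 5 mm, s_bif - 5 mm]`; RPA/LPA `[s_bif,
s_takeoff]`.  Whether the branch windows also carry 5 mm insets is not
specified by the source protocol; we apply none.  Volume is the trapezoidal
integral of `pi (d/2)^2` over the 1 mm stations (partial end intervals
included; areas, not diameters, are interpolated at window ends and across
flagged stations, which makes the integral exactly additive over abutting
windows).  `mm^3 = ul`.  Length is centerline arclength in the window
(cm).  Diameter summaries are mean/min/max over unflagged stations.
Indexing: volume / (length x BSA) in ul/(cm·m²), diameters / BSA in mm/m²,
BSA by Du Bois (`0.007184 * W^0.425 * H^0.725`).

## Statistics

* Group comparison: two-sided independent-samples t-test, Welch by default
  (the source protocol does not name the variant; pooled available by flag).
* Agreement: Shrout–Fleiss single-rater ICCs from the two-way ANOVA mean
  squares — intraobserver defaults to ICC(3,1) (fixed rater, consistency;
  same reader twice), interobserver to ICC(2,1) (random raters, absolute
  agreement); ICC(1,1) available.  Verified against `pingouin` and a hand
  sums-of-squares oracle.  Bland–Altman limits of agreement are
  `mean ± 1.96 x SD` of paired differences (sample SD).
* ROC: AUC as the Mann–Whitney pair statistic with ties counted 0.5
  (identical to the empirical-ROC trapezoid; both code paths are compared
  in tests), 95% CI by the DeLong structural-components estimator truncated
  to [0, 1].  Cutoff classification reports sensitivity/specificity/PPV/NPV
  with 0/0 as undefined (NaN), at the sex-independent cutoffs 2500
  ul/(cm·m²) for the RPA/LPA volume average and 12.5 mm/m² for the manual
  RPA/LPA diameter.  No multiple-testing correction is applied, matching
  the source analysis.

## Synthetic phantoms

Tube phantoms emulate a bright vessel on darker background: an analytic
tube (straight, circular arc, or helix centerline; constant or linearly
tapered radius) is rasterized by supersampled occupancy (default 4³ samples
per voxel), scaled to `[a0, a1]`, blurred with a Gaussian PSF and corrupted
with seeded additive Gaussian noise.  Defaults mirror the target
acquisition: voxel spacing (1.04, 1.04, 1.6) mm, `sigma_psf = 1 mm`.  The
source data's SNR and vessel contrast are unreported; phantoms default to
contrast 90 on background 10 with noise SD 4.5 (contrast/noise 20, a good
breath-hold contrast-enhanced acquisition).  Analytic truth accompanies
every phantom: volume over any arclength window is `pi ∫ r(s)² ds` — exact
for straight tubes, exact for arcs by the Pappus centroid theorem, and
exact for any gently curved centerline with normal-disk cross-sections by
the tube formula, which is how arc and helix membership are defined
(normal-plane end caps).  A supersampled voxel-count oracle provides an
independent volume reference.

The cohort simulator draws per-subject true values from per-group normal
distributions with the reported group means/SDs (indexed volumes, e.g. MPA
5508 ± 1236 patients vs 3438 ± 749 controls; BSA-corrected diameters
likewise), three reads per subject (reader 1 twice, reader 2 once; the
oblique-reformation read once) with independent Gaussian reader noise.
Default reader noise is 1.5% of the control-group mean for automated reads
and 4% for manual reads, chosen so simulated ICCs land in the reported
regimes (≈0.998 automated, ≈0.96 manual).  Normality of the measurements is
an assumption the generator inherits from the source analysis; noise is
additive Gaussian rather than Rician, a simplification.

### What the phantoms do not show

Phantoms contain one vessel (plus at most one bifurcation), no neighboring
mediastinal structures, no motion or flow artifacts, no intensity
inhomogeneity, and circular cross-sections matching the fitted model.
Passing the geometry tests therefore demonstrates correctness of the
estimator chain under the model's assumptions, not clinical accuracy on
patient MRAs — the reported patient-level numbers (AUC 0.998 etc.) derive
from data that is not available, and the simulated cohorts reproduce their
statistical structure, not the images behind them.

## Problem sizes and numerics

Default test phantoms are 60 mm tubes on the acquisition grid (~25x25x45
voxels), tracked at 1 mm steps (~60 fits plus a constrained refit each);
cohort simulations use the study's n = 20/21 and 200 seeds for the
recovery sweep.  Tolerances asserted: profile fidelity 2% of contrast;
straight-phantom window volume 3% and mean diameter 2%; arc volume 4%;
trapezoid-vs-voxel-count 1.5% across five shapes; AUC pair-vs-trapezoid
1e-12; ICC vs hand ANOVA 1e-10.  Ties in landmark projection break toward
smaller arclength; degenerate windows, empty cross-sections and
excluded-vessel propagation are handled explicitly (see the respective
docstrings).

## Known limitations

* Elliptical or free-form cross-sections are not modeled; non-circular
  vessels bias diameters toward the model's circular equivalent.
* Branch measurement windows start at the bifurcation, so their first
  stations sit inside the junction union, where the circular model sees the
  merged lumen and reports inflated diameters; on Y-phantoms this inflates
  branch volumes by tens of percent over the child-exclusive truth while
  parent windows (inset 5 mm from the bifurcation) are unaffected.  Real
  protocols mitigate this with reader verification of the branch origin.
* The original clinical software's exact parameterization and tracking
  internals are unpublished; this is a faithful implementation of the
  described behavior, not a port, and equivalence cannot be claimed.
* Automatic landmark detection is out of scope: valve, bifurcation and
  take-off points are supplied as world coordinates.
* DICOM ingestion and MRA subtraction are out of scope (NIfTI in, analysis
  on unsubtracted intensities).
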