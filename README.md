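# pavol — automated 3D volumetry of central pulmonary arteries

Pulmonary hypertension (mean pulmonary artery pressure ≥ 25 mmHg at right
heart catheterization) dilates the central pulmonary arteries, and
three-dimensional measures of that dilation are stronger predictors of the
disease than single diameters read off axial slices.  `pavol` implements
the full measurement chain for contrast-enhanced MR angiography: from one
seed point per vessel it segments the main, right and left pulmonary
arteries (MPA, RPA, LPA) with a model-based tracker, extracts a centroid
centerline, and measures landmark-bounded volumes, lengths and per-mm
average diameters; it then indexes the measurements to vessel length and
body surface area and runs the cohort statistics — group t-tests,
Shrout–Fleiss ICCs, Bland–Altman limits of agreement, ROC/AUC with DeLong
confidence intervals and fixed-cutoff classification.

The package is aimed at researchers evaluating morphometric imaging
biomarkers: it ships digital tube phantoms with analytic ground truth and a
cohort simulator, so every estimator is testable without patient data.

## The model

A local vessel segment is a cylinder of radius `R` blurred by an isotropic
Gaussian PSF of width `σ`.  At distance `d` from the axis the expected
intensity is

    I(d) = a0 + (a1 − a0) · P( χ'²₂(d²/σ²) ≤ R²/σ² )

— the exact disk–Gaussian convolution (noncentral-χ² CDF, equivalently the
Rice CDF `1 − Q₁(d/σ, R/σ)`), which tends to the edge response
`Φ((R−d)/σ)` for `R ≫ σ`.  This model is fitted by bounded nonlinear least
squares in a local region of interest; tracking chains such fits at 1 mm
steps proximally and distally from the seed, a spline-based two-step
refinement smooths the chain and refits with frozen tangents, and the
average diameter is reported every 1 mm along the centerline.  Volume over
an arclength window `[s₁, s₂]` is `∫ π (d(s)/2)² ds` (trapezoidal on the
1 mm stations); indexed volume is `V / (L · BSA)` in µl/(cm·m²) with BSA by
Du Bois.  See `docs/methods.md` for the full account.

## Worked example

Render a noisy 60 mm phantom tube of radius 5 mm on the MRA acquisition
grid (1.04 × 1.04 × 1.6 mm voxels, PSF 1 mm, contrast/noise 20), segment it
from a single seed, and measure a landmark-bounded window:

```python
import numpy as np
from pavol import (TubeSpec, render_tube, track, refine, centroid_centerline,
                   diameter_profile, flag_blowouts, LandmarkSet, measure_vessel,
                   du_bois_bsa, index_measurements)

spec = TubeSpec.straight(start=(0, 0, 0), direction=(0, 0, 1), length=60.0,
                         radius=5.0, a0=10.0, a1=100.0, psf_sigma=1.0,
                         noise_sd=4.5, seed=7)
vol, truth = render_tube(spec)

seg = track(vol, seed=(0.3, 0.2, 30.0))
seg = refine(vol, seg)
seg = centroid_centerline(vol, seg)
seg = diameter_profile(seg)
seg = flag_blowouts(seg)

landmarks = LandmarkSet(valve=(0, 0, 5.0), bifurcation=(0, 0, 55.0))
m = measure_vessel(seg, "MPA", landmarks)       # window [s_valve+5, s_bif−5]
bsa = du_bois_bsa(weight_kg=70, height_cm=180)
idx = index_measurements(m, bsa)
print(f"volume  {m.volume_ul:8.1f} ul   (analytic {spec.analytic_volume_ul(10, 50):.1f} ul)")
print(f"length  {m.length_cm:8.2f} cm")
print(f"diam    {m.mean_d:.2f} / {m.min_d:.2f} / {m.max_d:.2f} mm (mean/min/max)")
print(f"BSA     {bsa:8.3f} m^2")
print(f"indexed {idx['vol3d']:8.1f} ul/(cm m^2)")
```

prints

```
volume    3145.0 ul   (analytic 3141.6 ul)
length      4.00 cm
diam    10.01 / 9.90 / 10.10 mm (mean/min/max)
BSA        1.886 m^2
indexed    416.8 ul/(cm m^2)
```

The measured window volume is within 0.2% of the analytic cylinder volume
and the mean diameter within 0.1% of the true 10 mm.  The MPA window
applies the protocol's 5 mm insets from the valve and bifurcation levels;
RPA/LPA windows run from the bifurcation to the upper-lobe take-off.

Cohort-level analysis takes a tidy table (`subject, group, vessel, method,
read, value`); `pavol.simulate_cohort()` generates one with the study's
group means/SDs, and `pavol.group_summary()` / `pavol.roc_report()` produce
the group-comparison and ROC tables.

## Command line

```sh
pavol phantom --spec phantom.yaml --out-dir out/ --seed 1   # render + truth
pavol segment --config run.yaml --out-dir out/              # track + measure
pavol stats --cohort cohort.csv --out-dir out/              # tables + ROC
pavol demo --out-dir out/ --seed 1                          # end to end
```

Per-vessel failures are logged and marked excluded without aborting the
run; all outputs regenerate byte-identically from the same config and seed.

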