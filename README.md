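# cinestrain

Myocardial feature tracking and strain analysis for cine cardiovascular
MR (CMR), built around a non-rigid, elastic B-spline image-registration
tracker, with synthetic phantoms for validation and a full test–retest
variability toolbox.

## Who this is for

Quantifying regional left-ventricular function from standard bSSFP cine
images — without dedicated strain sequences — requires estimating the
myocardial motion field between frames, propagating manually drawn
end-diastolic contours through the cycle, and reducing the result to
Lagrangian strain over the AHA 16-segment model. This package implements
that pipeline end to end for researchers who want a transparent,
scriptable reference implementation, plus the agreement statistics
(Bland–Altman, CR, CV, ICC) needed to report intra-/inter-observer and
inter-study variability of strain measurements.

## The method

**Tracking.** The inter-frame deformation is a cubic B-spline
tensor-product transform: the displacement at position *p* is
*u(p) = Σᵢⱼ β₃((pₓ−oₓ)/hₓ − i) β₃((p_y−o_y)/h_y − j) c*ᵢⱼ, with
control-point displacements *c*ᵢⱼ on a regular grid. Each consecutive
frame pair is registered by minimising

    E(c) = SSD(fixed, moving ∘ (id + u_c)) + λ · ∫ ‖∇²u_c‖² dx

over a coarse-to-fine image pyramid with L-BFGS, using the entire image
content (blood pool, myocardium, background) rather than boundaries
only. An optional *coherent* mode refines the whole sequence jointly
with a temporal penalty μ·Σₜ‖c(t+1) − c(t)‖², which suppresses
frame-to-frame jitter while keeping the physiological deformation.

**Strain.** Cumulative ED→t transforms are composed, ED endo-/epicardial
contours are propagated, and Lagrangian strain (relative to frame 0) is
computed per AHA segment: circumferential strain Ecc from midwall
arc-length change, radial strain Err from spoke wall-thickness change
(72 spokes from the ED endocardial centroid), longitudinal strain Ell
from arc-length change of long-axis wall segments. Global strain per
level is the unweighted mean of its segments at end-systole (ES), with
ES detected as the minimum of the mean global Ecc curve unless supplied.

**Validation.** Synthetic short-axis (contracting annulus) and long-axis
(shortening truncated-ellipse shell) cine phantoms carry an exact,
closed-form material map: ground-truth strain is known analytically,
so the whole pipeline can be checked for parameter recovery.

**Variability.** For repeated readings the package computes bias and
95% limits of agreement (bias ± 1.96·SD of the paired differences),
coefficient of variation (SD of differences / |pooled mean|),
coefficient of repeatability (CR = 2.77·SD of differences), and the
two-way absolute-agreement single-measurement ICC with 95% CI, together
with paired t-tests of the bias, two-tailed F-tests between
variabilities, and D'Agostino–Pearson normality checks.

## Worked example

```python
from cinestrain import (PhantomSpec, PipelineConfig, generate_sax_phantom,
                        track_slice, summarize)

spec = PhantomSpec(seed=1)           # 160x160 px, 1.6 mm, 30 frames, ES at 10
seq, truth = generate_sax_phantom(spec)
result = track_slice(seq, truth.ed_endo, truth.ed_epi, PipelineConfig(), level="mid")
ecc = next(c for c in result.curves if c.component == "Ecc_SAX")
err = next(c for c in result.curves if c.component == "Err_SAX")
print(f"ES global Ecc: {summarize(ecc, 10).es_global:+.2f}%  (truth {truth.ecc_by_layer['mid'][10]:+.2f}%)")
print(f"ES global Err: {summarize(err, 10).es_global:+.2f}%  (truth {truth.true_err[10,0]:+.2f}%)")
```

prints (about a minute on one CPU):

```
ES global Ecc: -11.50%  (truth -11.67%)
ES global Err: +28.48%  (truth +30.00%)
```

The phantom contracts from endo/epi radii 25/35 mm at end-diastole to
20/33 mm at end-systole, i.e. a true wall-thickening strain of +30%
(endocardial Ecc −20%, midwall Ecc −11.67%). The tracker recovers the
midwall circumferential strain within 0.2 strain points and radial
strain within 1.6 — radial strain is the harder component because it
depends on both boundaries.

The same workflow is available from the shell:

```bash
cinestrain simulate --view sax --seed 1 --out phantom/
cinestrain track --cine phantom/cine.nii.gz --endo phantom/ed_endo.json \
                 --epi phantom/ed_epi.json --level mid --out run/
cinestrain stats --readings readings.csv --out variability.csv
```

`track` writes propagated contours, tidy strain and strain-rate CSVs, a
summary JSON and a MANIFEST with per-stage timings; `stats` turns a tidy
CSV of repeated strain readings into an agreement table (bias, LOA, CV,
CR, ICC with CI, bias t-test) with one row per component × grouping.

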