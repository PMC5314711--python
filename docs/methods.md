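# Methods

## Deformation model and registration

Inter-frame motion is modelled with a cubic B-spline tensor-product
transform on a regular control grid (default spacing 8 px = 12.8 mm at
1.6 mm pixels; the grid extends one cell beyond each image edge plus the
cubic support margin, so every pixel — and any slightly-drifting tracked
point — is spanned). A pair of frames is registered by minimising

    E(c) = SSD + lambda * bending + [mu * temporal terms]

* **Similarity.** Mean squared intensity difference (SSD) over the full
  image domain, after linearly rescaling the joint intensity range of
  the two frames to [0, 1]. No myocardial mask is applied: the blood
  pool and background textures contribute to the data term. A
  normalised-cross-correlation option (`similarity="NCC"`) exists for
  robustness to global intensity drift; SSD is the default for
  same-sequence cine pairs.
* **Regularisation.** The bending energy — the integral of the squared
  second spatial derivatives of the displacement field — approximated
  as a knot-point Riemann sum. At a knot the spline's second
  derivatives are exact 3×3 stencils of the control displacements
  (second difference along the axis, B-spline smoothing [1/6, 4/6, 1/6]
  across it, central differences for the mixed term), so the penalty is
  zero for every affine field and matches a dense evaluation of the
  field at the knots. Default weight lambda = 1e-6: with SSD on [0, 1]
  intensities the data term is O(1e-3–1e-4), and this weight leaves the
  composed ED→ES field on the default phantom within 0.2 px of truth
  while suppressing gross non-smoothness; much larger weights visibly
  bias the recovered contraction. Exposed in `RegistrationParams`.
* **Optimisation.** L-BFGS with the analytic gradient of SSD + bending
  (the SSD gradient separates into basis-matrix products, so one
  evaluation is two small GEMMs plus cubic interpolation), over a
  coarse-to-fine image pyramid (default 3 levels, factors 4/2/1; the
  control grid is fixed in mm across levels). Iteration cap 100 per
  level, relative-cost tolerance 1e-10 (cost magnitudes are O(1e-4), so
  looser tolerances stop the optimiser prematurely). Registration is
  fully deterministic; if the optimiser fails to improve on its
  initialisation the cheaper of {identity, init} is returned with a
  warning flag rather than an exception.
* **Warm starting and temporal coherence.** Sequential mode registers
  consecutive pairs, each initialised from the previous solution.
  Coherent mode then runs block-coordinate refinement sweeps (default
  2) over the whole sequence, adding mu * ||c_t − c_{t−1}||² +
  mu * ||c_t − c_{t+1}||² to each block. Because a cardiac cycle's
  incremental deformations are roughly zero-mean, an aggressive
  temporal weight collapses the entire sequence toward zero motion;
  the default mu = 5e-7 was chosen on heavy-noise phantoms as the
  largest weight that still improves tracked-contour accuracy over
  sequential mode (it reduces the temporal roughness
  sum ||c(t+1) − c(t)||² by an order of magnitude). If a refinement
  ever increased roughness the sequential solution would be kept.
* **Composition and propagation.** Cumulative ED→t motion is the
  forward composition x_t = x_{t−1} + u_{t−1}(x_{t−1}), evaluating each
  pairwise B-spline exactly at the tracked positions (no intermediate
  dense-field resampling). No drift correction is applied, so the
  composed field at the last frame is not forced back to identity —
  residual drift is visible as nonzero strain at the final frame.
  Contours are resampled to 200 (SAX) / 150 (LAX) points before
  propagation; dense `DeformationField` grids use cubic interpolation
  when sampled at contour points, and out-of-domain points are clamped
  to the border with a warning flag.

## Strain

All strain is Lagrangian: material membership is frozen at end-diastole
(frame 0) and values are percent change relative to frame 0.

* **Segments.** Basal and mid short-axis levels use six 60° sectors
  (anterior, anteroseptal, inferoseptal, inferior, inferolateral,
  anterolateral, starting at the manually placed mid-septal reference
  axis); the apical level uses four 90° sectors. The slice level is an
  input label — the anatomical criterion (papillary-muscle position) is
  visual and not automated. Long-axis walls split into basal/mid/apical
  thirds per side plus an apical cap, seven equal-arc-length segments.
* **Ecc** is the relative arc-length change of the midwall contour's
  material edges per sector (edges assigned by their ED midpoint angle
  about the ED centroid). The wall layer feeding Ecc/Ell is
  configurable (endo | mid | epi); midwall is the default as the
  conventional compromise between the steep endocardial and shallow
  epicardial gradients.
* **Err** casts 72 spokes from the ED endocardial centroid, finds the
  exact ED ray/polygon intersections on both contours, and tracks those
  material points by linear interpolation along the propagated
  contours; per-spoke thickness change is averaged per sector. Spokes
  failing to cross both contours are dropped; a sector with more than
  half its spokes dropped is flagged missing and excluded from global
  means.
* **Ell** is the relative arc-length change of the seven material
  sub-arcs of the long-axis midline.
* **Rates and summaries.** Strain rate uses central differences on the
  frame times (one-sided at the ends). End-systole defaults to the
  frame minimising the mean global Ecc across available SAX slices
  (ties break to the earliest frame); a user-supplied ES frame always
  wins. Global strain per level is the unweighted mean of non-missing
  segments at ES.

Uniform scaling of all contours by s changes Ecc, Ell and Err by
exactly (s−1)·100 — the suite asserts this identity — and rigid motions
change strain only through contour re-parameterisation (< 0.1 strain
points).

## Phantoms

The synthetic phantoms emulate the acquisition geometry of a clinical
bSSFP cine protocol: 1.6 × 1.6 mm pixels, 30 cardiac phases, one slice
per file; the default image is 160 × 160 px with a 1 s cycle.

* **Short-axis**: an annulus with ED endo/epi radii 25/35 mm
  contracting to 20/33 mm at ES (frame 10), i.e. true wall-thickening
  Err = +30% and endocardial Ecc = −20% (midwall −11.67%). The wall's
  radial material map is linear in ED radius; inside the blood pool and
  outside the wall it is continued with slope-matched (C¹) quadratics
  that relax to the identity 25 mm beyond the epicardium — the blood
  and near-field tissue follow the wall smoothly, and the whole-image
  map stays monotone and analytically invertible. An optional solid
  rotation can be superimposed.
* **Long-axis**: a truncated-ellipse shell (midline semi-axes 40/22 mm,
  8 mm wall, base plane at half the long semi-axis) deforming by a
  uniform isotropic scaling 1 − f·a(t) about the image centre, so the
  midline arc length — and hence Ell in every segment — changes by
  exactly −f·100 at ES.
* **Activation** a(t) is a half-sine rising to 1 at the ES frame and
  mirrored back to 0 at the last frame, so the cycle is closed and
  tracking drift is measurable.
* **Intensity** is a seeded Gaussian random field smoothed to a 6 mm
  correlation length riding on SSFP-like class means (blood 0.95,
  myocardium 0.6, background 0.2); frames are generated by sampling the
  ED image at the exact inverse material map (cubic interpolation), so
  the texture is advected with the motion by construction. Seeded
  Gaussian noise (default SD 0.02, ≈2% of the intensity range) is added
  per frame; the same seed reproduces frames bit-for-bit.

What the phantoms do *not* model: through-plane motion, papillary
muscles, trabeculation, MR physics (k-space truncation, banding, flow
artifacts), heart-rate variability, or observer contouring error.
Passing recovery tests therefore demonstrates correctness of the
tracking-and-strain machinery under known 2D motion, not clinical
accuracy on patient images.

## Variability statistics

Differences are computed between paired readings after harmonization
(only items present in every compared reading are kept). SD uses the
n−1 denominator throughout — the CR convention 2.77 ≈ 1.96·√2 presumes
it. CV divides by the absolute pooled mean so negative-valued strain
components yield positive CV. The ICC is the two-way random,
absolute-agreement, single-measurement form ICC(2,1) (computed through
pingouin) with the F-distribution 95% CI; absolute agreement is the
stricter, conventional choice for method-agreement studies, and the
consistency form can be obtained by centring the readings. For more
than two readings the default pairing compares each reading against the
first (the multi-acquisition convention); consecutive pairing is
available. No multiple-testing correction is applied. `cr_from_loa`
recovers CR from printed bias/LOA summaries
(SD = LOA width / (2·1.96)), which allows published agreement tables to
be audited for internal consistency without the underlying data.

## Numerical and design notes

* Coordinates are physical mm, origin at the image centre, x right /
  y down; angles are measured counter-clockwise (in these axes) from
  the mid-septal reference direction.
* Closed (SAX) contours must be counter-clockwise by the shoelace sign;
  endo/epi pairing is by polar angle about the ED endo centroid (SAX,
  valid for star-shaped LV sections) or normalised arc length (LAX).
* Out-of-domain image sampling replicates the border (no NaNs);
  out-of-grid B-spline evaluation raises a domain error, and the
  composition/propagation paths clamp to the spanned domain instead.
* Degenerate statistics inputs have explicit contracts: zero-variance
  differences give p = 1 (zero mean) or p = 0 (nonzero mean) for the
  paired t; zero pooled mean flags CV as missing; zero total variance
  makes the ICC a validation error.
* Problem sizes in the test and acceptance runs (96–160 px phantoms,
  5–30 frames, 1000-replicate null simulations) were chosen so the full
  validation completes in a few minutes on one CPU while keeping every
  contract at the default study geometry.

## Known limitations

* 2D per-slice tracking only; no through-plane or 3D registration, no
  diffeomorphic guarantee (large inter-frame motion could fold).
* Radial strain inherits error from both boundaries; on the default
  phantom it is recovered within ~1.5 strain points, versus ~0.2 for
  Ecc/Ell — mirroring the component ordering of variability seen in
  practice.
* The temporal-coherence formulation (quadratic consecutive-difference
  penalty with block refinement) is this package's concrete choice for
  a sequence-level regulariser; other formulations exist.
* Segment strain near the B-spline control spacing (≈13 mm) is
  band-limited: deformation detail finer than the grid cannot be
  represented.
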