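# Methods

`taucl` re-implements, end to end and on synthetic phantoms, an analysis in
which the three-dimensional topography of tau-PET uptake is mapped to a
scalar amyloid burden (Centiloid, CL) by a convolutional neural network,
and the learned mapping is then interpreted voxel-wise: gradient saliency
maps, voxel-wise general linear models under family-wise-error control,
cluster occlusion with out-of-sample R², and "strength of association"
curves across the CL continuum.  This note records the model, the
assumptions, the parameters that matter, and the design decisions taken
where the design was genuinely open.

## The phantom generator

Real tau/amyloid imaging cohorts are access-restricted, so every stage is
exercised on seeded synthetic cohorts (`taucl.synthetic`) whose statistical
structure is the one the analysis is designed to detect:

* **Cohort.** `n_subjects = 150` subjects with amyloid Centiloid, age
  (normal, 70.5 ± 7.5 y) and sex (Bernoulli 0.5).  CL follows, by default,
  a two-component mixture calibrated to a 49 % amyloid-positivity rate at
  the conventional CL = 25 threshold: Aβ− values from a truncated normal
  N(2, 10) on [−10, 25) and Aβ+ values from N(70, 35) truncated to
  [25, 140].  A uniform distribution on [cl_low, cl_high] is available as
  `cl_distribution="uniform"`.  The mixture matters scientifically: with a
  uniform CL on [−10, 140] only ~23 % of subjects lie below the
  changepoint, the sub-changepoint band then carries almost none of the
  squared-error loss, and no regression model is incentivised to use the
  low-CL region — the informativeness crossover cannot be learned.
  Train/validation/test proportions default to 109/12/13 of 134.
* **Atlas.** A deterministic ellipsoidal brain mask containing a
  cerebellar-like reference region (for SUVR), a large
  "fronto-parietal/cingulate-like" region (`effect_low`, 1306 voxels at
  the default grid), two "medial-temporal-like" spheres
  (`effect_high_left/right`, 305 voxels each), two null regions, a
  CL-independent off-target hot spot, and a catch-all "other brain"
  parcel.  Default grid 32×40×32 at 2 mm — small enough that the full CNN
  study runs on one CPU in about a minute per instance; the grid is a
  config option, not a constraint of the code.
* **Planted signal.**  In-mask voxel value
  `baseline_r + A_low·g_low(CL)·1[low] + A_high·g_high(CL)·1[high]
  + b_region + ε`, truncated at 0, where

  - `g_low(CL) = clip((CL − cl_low)/(changepoint − cl_low), 0, 1)` — a ramp
    saturating at the changepoint (default 25 CL),
  - `g_high(CL) = logistic((CL − changepoint)/τ)` with τ = 10 CL,
  - `A_low = 0.8`, `A_high = 0.5` SUV.  The amplitudes are set analytically
    so that regional *information* dominance switches exactly at the
    changepoint: below it the ramp's slope `A_low/35 ≈ 0.023` SUV/CL must
    exceed the logistic's peak slope `A_high/(4τ) = 0.0125` SUV/CL, i.e.
    `A_low > (35/40)·A_high`; above the changepoint the ramp is flat and
    the logistic always dominates.
  - `b_region ~ N(0, subject_offset_ratio·noise_sd)` is a per-subject,
    per-effect-system regional offset (default SD 0.03 SUV).  It emulates
    between-subject biological heterogeneity; unlike i.i.d. voxel noise it
    does not average away over a region's voxels, so a region is only
    informative about CL where its planted response has appreciable slope.
    Without it, the regional mean over hundreds of voxels is a
    near-noiseless function of CL and the saturating high-CL region alone
    pins CL across the whole continuum.
  - `ε ~ N(0, noise_sd)` i.i.d. voxel noise, default 0.3 SUV on a baseline
    of 1.0 — deliberately noisy, as high-resolution unsmoothed OSEM
    reconstructions are.
  - `baseline_r`: per-region baseline multipliers (±15 %, hashed from the
    region name).  Spatially normalised brains are not homogeneous, and
    this contrast is what allows a translation-equivariant CNN to form
    location-specific features at all; on a perfectly homogeneous
    background the low-CL region at low CL is statistically identical to
    background everywhere and focal attribution is impossible in
    principle.
  - The hot spot (+3.0 SUV, CL-independent, an off-target-binding
    analogue such as meningeal tracer uptake) pins each image's maximum so
    that the per-image [0, 1] scaling denominator does not leak regional
    burden into every voxel.

  All randomness derives from `(master seed, subject id)` hashes, so
  volumes are bit-reproducible independently of generation order, and all
  subject-level noise scales with `noise_sd` — noiseless configurations
  reproduce the generative formula exactly, which the analytic unit tests
  exploit.

**What the phantom does not emulate:** PET noise physics (Poisson counts,
partial volume, scanner PSF), anatomical realism, spatial noise
correlation, registration error, or longitudinal dynamics.  Passing tests
therefore demonstrate the *statistical machinery* — not that the pipeline
would produce the same anatomical findings on real scans.

## Preprocessing

CNN inputs are min–max scaled to [0, 1] within the brain mask
(out-of-mask voxels forced to 0; a constant image degenerates to zeros
with a warning).  The linear comparison arm uses SUVR: voxel value divided
by the mean over the cerebellar-like reference region.  Gaussian smoothing
uses a separable kernel with σ = FWHM/(voxel·2√(2 ln 2)) per axis and an
edge-renormalised truncated kernel (no wrap, no mass drained into the
background).

## The CNN regressor

A compact NumPy network (`taucl.nn`): stride-2 3³ convolutions
(8/16/32 channels, ReLU), then a dense head on the *flattened* final
feature map (one weight per spatial cell), a 32-unit hidden layer, and a
scalar output.  Convolutions are im2col/GEMM; every layer implements an
exact backward pass, and backpropagating to the input yields the exact
gradient of the prediction with respect to every voxel — the saliency
computation reuses the training code path, so the finite-difference oracle
in the tests checks the same gradients the analysis consumes.

The flattened (position-aware) head rather than global average pooling is
a deliberate choice: GAP has no position-specific parameters, and its
input-gradient field is diffuse regardless of the data; on
template-registered images, absolute position is meaningful and
position-specific weights are what make focal attribution possible.  A
GAP head remains available (`head_style="gap"`).

Training: RMSprop (ρ = 0.9) on mean squared error over internally
standardised targets, learning rate 3e-3 halved after 10 epochs without
validation improvement (floor 1e-4), batch size 8, at most 250 epochs with
early stopping after 30 epochs without improvement; the parameters of the
best validation epoch are kept.  Seeded initialisation and shuffling make
training bit-reproducible.  Optional decoupled L2 weight decay is off by
default.  Cross-validation follows a seeded K-fold plan over the non-test
cohort (K = 10 by default, matching the reference design); the best
instance is the arg-min of the mean of validation and test RMSE, ties
broken toward the lowest fold id.  Out-of-sample R² is
`1 − SS_res/SS_tot` with SS_tot around the evaluation split's own mean —
it may be negative, and post-occlusion values routinely are.

## Saliency and the voxel-wise GLMs

Per subject and per instance, saliency is |∂ŷ/∂x| at the observed scaled
input (signed maps behind a flag), masked to the brain and smoothed
(default 2 mm FWHM).  Saliency (or SUVR) is then regressed voxel-wise on
CL with age and sex as nuisance covariates; the t-contrast on CL is
thresholded by permutation maxT: Freedman–Lane permutation of
reduced-model residuals, threshold at the ⌈(1−α)M⌉-th smallest of M
max-t values (the identity permutation included, making the rejection
rule exact under exchangeability), α = 0.05.  Permutation was chosen over
random-field theory because it is assumption-light and its error control
is directly testable by simulation; a Bonferroni threshold is provided as
a conservative cross-check.  Suprathreshold voxels are segmented by
26-connected components (6/18 selectable) and components smaller than the
volume-scaled extent (200 voxels at 1 mm³ ⇒ 25 voxels at 2 mm) are
discarded.  Cross-instance consistency is summarised by pairwise Dice on
binarised cluster masks and a per-voxel consensus count.

Desk-scale analysis choices, recorded in output provenance: on the 2 mm
grid the saliency smoothing kernel is scaled like the extent threshold
(2 mm FWHM at 1 mm voxels ⇒ 4 mm at 2 mm voxels), and the planted
low-CL region's saliency *decreases* with CL (the model needs it less as
CL grows), so recovery analyses use the two-sided contrast; the one-sided
positive contrast remains the configuration default.

## Occlusion and strength of association

A cluster is occluded by setting its voxels to 0 — the minimum of the
scaled input, i.e. absent signal (mean-fill behind a flag) — and
predictions are recomputed with unchanged weights.  Importance is the drop
in per-split R².  The strength of association of a cluster is the LOESS
smoothing (tricube weights, local degree 1, span 0.5, 100-point grid over
the observed CL range, no extrapolation) of |ŷ_full − ŷ_occluded| against
measured CL, pooled over splits, with mean and standard error across
cross-validation instances.  Clusters are decomposed into anatomical
sub-clusters by atlas intersection (exact partition).  The crossover
estimator reports the CL at which the low-CL region's curve hands
dominance to the high-CL region's (last above-to-below sign change,
linearly interpolated).

## Problem sizes

The test suite and the acceptance script run, per seed, the full default
cohort (n = 150, 32×40×32 at 2 mm) with two trained instances of a K = 5
fold plan and 200 permutations — sizes chosen so a complete three-seed
study takes a few minutes on one CPU.  K = 10 remains the configuration
default.  FWER calibration uses 500 pure-noise replicates (n = 30, 100
voxels, 100 permutations), for which the expected family-wise error of
the threshold rule is exactly 5 %.

## Numerical notes and degenerate inputs

Exact-fit voxels (zero residual variance up to round-off) get t = ±∞ and
are flagged rather than dropped.  Zero-variance evaluation targets make R²
undefined (NaN with a warning).  Constant images scale to zeros with a
warning rather than failing batch jobs.  LOESS refuses degenerate
(all-equal) abscissae and falls back to weighted means when a
neighbourhood's span collapses.  `n! ≤ n_perm` triggers exhaustive
permutation enumeration with a warning.  Networks run in float32 for
training; float64 is used where gradients are compared against oracles.

## Known limitations

* The saliency-GLM clusters of a small CNN on this phantom do not tile the
  planted regions: the model reads a sufficient subset of each redundant
  region (attributions are focal by nature) and its gradient field bleeds
  into neighbouring tissue.  Planted-voxel coverage of ~60–80 % with
  Dice ~0.2–0.4 against the planted masks is typical; the cluster tables
  should be read as "where the model looks", not as segmentation of the
  ground truth.
* Strength-of-association curves measure prediction *change under an
  out-of-distribution perturbation* (zero-filled regions), not information
  content; their magnitudes depend on the fill convention.
* With a logistic high-CL response (τ = 10 CL) and subject-level
  heterogeneity, CL above ~70 is close to unidentifiable from the phantom;
  validation R² ≈ 0.75–0.85 is the realistic ceiling at the default
  conditions, and per-fold performance varies noticeably between seeds.
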