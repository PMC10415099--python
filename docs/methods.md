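# Methods

## Problem and scope

Acute ischemic stroke restricts water diffusion: within minutes of onset,
infarcted tissue turns hyperintense on the DWI trace image (b = 1000 s/mm²)
and its apparent diffusion coefficient drops from the parenchymal range
(roughly 700–900 × 10⁻⁶ mm²/s) toward 400–600 × 10⁻⁶ mm²/s. Commercial
stroke software exploits this with a fixed threshold — ADC ≤ 620 × 10⁻⁶
mm²/s — to delineate the lesion automatically. `adcseg` implements such a
thresholding pipeline in full, plus the evaluation machinery (voxelwise ROC
threshold discovery, Dice, Bland–Altman, standardized regression) needed to
study how the approach behaves, and a synthetic phantom generator so the
entire stack can be exercised and verified without patient data.

The package deliberately starts *after* preprocessing: DICOM conversion,
brain extraction, registration to a common 2 mm grid and any reorientation
are upstream concerns. All volumes in one analysis must share one grid;
this is checked, never resampled.

## Segmentation pipeline

Stages, in order, with their tunables (`SegmentationConfig`):

| stage | default | notes |
|---|---|---|
| ratio image trace/ADC | — | 0 where ADC ≤ 0 or outside brain |
| slice normalization | axial slices (axis 2) | divide by in-brain slice mean; empty/zero-mean slices stay 0 |
| Gaussian smoothing | FWHM 5 voxels | σ = FWHM/2.3548 ≈ 2.12; zero-padded boundaries, kernel truncated at 6σ |
| mirror subtraction | axis 0 | max(0, I − flip(I)); negatives clipped — only ipsilateral hyperintensity is meaningful |
| intensity threshold | 0.75, inclusive (≥) | on the mirror-subtracted image |
| dilation | 1 iteration, 6-connected | restricted to the brain mask |
| ADC band gate | [200, 620] × 10⁻⁶ mm²/s, both ends inclusive | the fixed acute-infarct band |
| trace-percentile cleanup | 95th percentile of parenchymal trace, strict `<` removal | linear-interpolation percentile convention |

Interpretation choices where the procedure is conventionally stated loosely:

- **"5 voxel" Gaussian kernel** is read as FWHM = 5 voxels. σ, FWHM and
  truncation width are all plausible readings; FWHM is the common
  neuroimaging convention, and the width is configurable.
- **"Partial" dilation** is implemented as N iterations of 6-connected
  (face-adjacent) binary dilation constrained to the brain mask, N = 1 by
  default — "partial" read as "not growing beyond the brain".
- **Percentile reference population.** A percentile computed inside the
  candidate mask itself would by construction delete that fraction of any
  lesion, so the default population is the brain parenchyma
  (`percentile_population="parenchyma"`); the mask-internal alternative is
  retained as a config option.
- **Parenchyma vs CSF** is decided by an ADC rule (brain voxels with
  ADC < 2000 × 10⁻⁶ mm²/s are parenchyma) rather than a tissue
  segmentation: free water diffuses near 3000 × 10⁻⁶ mm²/s, several SDs
  above any parenchymal value, so a cutoff anywhere in ~1500–2500 separates
  the compartments; 2000 is the default.
- **Ties**: the intensity threshold and both ADC band edges are inclusive;
  the percentile cleanup removes strictly-below voxels.
- The 0.75 intensity threshold is a calibrated operating point inherited
  from the method being studied; it is exposed as configuration, not
  re-derived here.
- The mirror plane is the array flip along the configured left–right axis,
  which presumes prior registration to a symmetric grid (true for both the
  standard-space use case and the phantoms, which place the mid-sagittal
  plane exactly between the two central voxel columns).

The final mask can legitimately be empty — small or ADC-atypical lesions
fall below the intensity threshold or outside the band; this is a measured
failure mode, not an error.

## ROC threshold analysis

The classifier is `ADC ≤ t` for t on an ascending grid, by default
0…1500 × 10⁻⁶ mm²/s in steps of 1 (integer thresholds match how such
optima are conventionally reported). Within a search region — whole-brain
parenchyma, or the reference lesion dilated by `roc_dilate_iterations`
6-connected steps (default 6, which excludes a median of ≈96% of
parenchyma on default phantom cohorts) — sensitivity and specificity are
computed against the reference lesion; the negative class is the search
region minus the lesion. The operating threshold maximizes the Youden
index, ties resolved toward the lowest threshold. AUC uses the trapezoidal
rule over (1−specificity, sensitivity) with (0,0) and (1,1) appended.
Pooling sums TP/FP/FN/TN across subjects per threshold before recomputing
rates, so subjects contribute in proportion to their voxel counts; the
pooled optimum can never exceed the mean of the individual optima.

## Agreement and regression statistics

- **Dice** 2TP/(2TP+FP+FN). Two empty masks return 1.0 with a warning
  (agreement on absence); a warning rather than an error because cohort
  loops must not abort on a no-detection case.
- **Bland–Altman** differences are first-minus-second argument (call it
  with (reference, automated) to get reference-minus-automated bias);
  limits are bias ± 1.96 × sample SD (n−1). The attached linear fit
  regresses the first series on the second, with the reference on the
  x-axis — the one-method-as-reference variant rather than the classic
  pair-mean axis. Two pairs suffice for the closed-form bias/limits,
  though the limits only become a meaningful agreement interval at
  realistic n.
- **Standardized regression** z-scores response and predictors before OLS,
  so coefficients are standardized effects, invariant to affine rescaling
  of any predictor. CIs are 95% Wald intervals, p-values two-sided t-tests,
  no multiple-testing correction. Incomplete cases are dropped and counted.
  Near-collinearity (condition number > 1e8) raises an error naming the
  most-correlated predictor pair.

## Phantom generator

The phantom reproduces the *statistical* structure the algorithm assumes,
not anatomy:

- **Geometry.** An ellipsoidal brain (semi-axes 0.42 × grid, ~950 mL at the
  default 64×76×64 grid at 2 mm) centred on the grid, mirror-symmetric
  about the mid-sagittal plane; two symmetric ventricle-like CSF
  ellipsoids; one lesion ellipsoid (optionally `n_foci` scattered blobs,
  for exercising the scattered-voxel cleanup) strictly inside the brain —
  enforced, since a lesion touching the brain edge would break the
  mirror-subtraction premise.
- **ADC field.** Voxelwise normal draws per compartment, clipped at 0:
  parenchyma N(850, 60), lesion N(500, 60), CSF centred at 3000 (all
  × 10⁻⁶ mm²/s). Lesion and parenchyma defaults bracket the ADC contrast
  regime of acute territorial infarcts; their equal-density point (675)
  is what individual ROC optima should recover. The background texture is
  drawn on one hemisphere and mirrored, so everything outside the lesion is
  *exactly* symmetric — bilateral tissue is homologous, and this makes the
  mirror-subtraction null testable exactly rather than statistically.
- **Signal.** Mono-exponential decay, trace = b0·exp(−b·ADC·10⁻⁶) with
  b = 1000 s/mm² and b0 = 1000 inside the brain, then additive Gaussian
  noise (SD 20, i.e. ~5% of parenchymal trace signal — a moderately noisy
  but usable DWI) on b0 and trace independently, clipped at 0. With
  `noise_sd = 0` the decay identity holds to machine precision. Gaussian
  rather than Rician noise is adequate at this SNR for exercising
  thresholds; the noise model is isolated in one place if Rician is wanted.
- **Cohorts.** `generate_cohort` draws per-case truth volumes log-uniform
  over a range (default 1–30 mL, matching the skewed, few-mL-median volume
  distribution of acute stroke admissions), solves the lesion ellipsoid
  scale by bisection so the voxelized volume hits the target to within a
  voxel where the lattice allows, jitters per-case lesion/parenchyma ADC
  means (SD 25 × 10⁻⁶ mm²/s) for between-subject variability, randomizes
  hemisphere and position, and derives per-case seeds from one master seed
  (all below 2³¹). Identical spec + seed is bit-identical by contract.

What the phantom does **not** model: gyral/tissue texture, partial-volume
edges, bias fields, susceptibility artifacts, T2 shine-through, perfusion,
or realistic ventricle shape. Consequently phantom performance is an upper
bound: clean compartments and exact background symmetry make both the
segmentation (Dice ≈ 0.85–0.95 for 5–20 mL lesions) and the ROC separation
(AUC ≈ 1) far better than on patients. Passing tests demonstrate that the
implementation does what it claims under its own assumptions — not that
the method performs at any particular level clinically. The qualitative
behaviours do transfer: sub-0.5 mL lesions are smoothed below the intensity
threshold and frequently yield zero overlap, lesions with ADC above the
620 gate are rejected despite trace hyperintensity, and pooled thresholds
fit no individual subject exactly.

## Problem sizes and numerics

The default experiment (`RunConfig`) is a 20-case cohort on the 64×76×64
grid — small enough that the full pipeline, per-case ROC sweeps over ~10⁵
parenchymal voxels × 1501 thresholds, pooling and regressions complete in
seconds, while large enough for stable medians and standardized
coefficients at cohort level. ROC counting is exact (sorted values +
binary search, no binning); percentiles use linear interpolation; Youden
ties take the lowest threshold; volumes are float64 throughout. NaN voxels
in loaded files become 0 (brain-extraction borders routinely produce NaN);
ADC maps stored in mm²/s are auto-rescaled by 10⁶ when the 99th percentile
of positive voxels is below 10 — the two unit dialects differ by six
orders of magnitude, so the heuristic cannot misfire on plausible data.

## Known limitations

- Registration quality is assumed; a tilted mid-sagittal plane degrades
  mirror subtraction and is not detected.
- The CSF/parenchyma ADC rule mislabels voxels in chronic lesions or severe
  leukoaraiosis, which the phantom does not represent.
- Pooled ROC weights subjects by voxel count, so large lesions dominate the
  generalized threshold.
- The regression battery is descriptive (no cross-validation, no multiple
  testing correction), mirroring exploratory practice.
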