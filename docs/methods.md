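# Methods

## Relaxometry

Per-voxel model: `SI(TSL) = S0 · exp(−TSL/T)` with `T` the T1ρ (or T2)
relaxation time in ms and TSL the spin-lock (or echo) time. The fit is
nonlinear least squares (Levenberg–Marquardt, `scipy.optimize.curve_fit`)
initialised from the log-linear regression of ln SI on TSL; if the
nonlinear solver fails the log-linear estimate is kept as a fallback.
Design choices:

- **TSL grid** default `[2, 10, 20, 40, 60]` ms, configurable. This is a
  typical clinical spin-lock ladder; the fitter is agnostic to the grid.
- **Clamp** `T ∈ [1, 500]` ms. In-vivo NP means span roughly 35–150 ms,
  so the clamp is generous; estimates *at* a bound are flagged invalid
  (they indicate no measurable decay or a diverged fit, e.g. a flat
  series).
- **Background masking**: voxels whose mean signal is below `3 × σ_noise`
  (σ configurable) are skipped; `fit_map` additionally requires the
  first-acquisition signal to exceed that threshold. Invalid voxels
  carry NaN, never silent zeros.
- **Noise model** for synthesis: additive Gaussian on magnitude
  (adequate at SNR ≳ 10); a Rician option exists behind a config flag
  for low-SNR experiments.
- **Two-point path**: with exactly two acquisitions the closed-form
  log-ratio `T = ΔTSL / ln(S1/S2)` is used (testing convenience).

Precision at the default conditions: at SNR 50 (S0/σ) on the default
grid the Cramér–Rao bound gives a per-voxel sd(T) of ≈2.6 ms at
T = 55 ms and ≈4.8 ms at T = 85 ms; the fitter's observed per-voxel MAE
(≈2.9 ms on the phantom) sits essentially on that floor. ROI *means*
over hundreds of voxels are correspondingly recovered to a few tenths of
a ms, which is the quantity that matters downstream.

## Disc geometry and the NP region

Disc voxel coordinates (voxel centers, 0-based, scaled to mm) are pooled
across the four mid-sagittal slices and the in-plane (AP × SI)
second-moment tensor about the centroid is diagonalised. The principal
frame puts the major axis — anterior–posterior for disc-shaped masks —
first, with the sign convention that it points anterior→posterior. The
NP is defined spatially: voxels whose major-axis coordinate lies within
the central 40 % of the disc's AP bounding interval (boundary
inclusive). Alternatives considered and the choices made:

- 40 % of *extent*, not a 40 % voxel-count quantile: "central
  anterior–posterior 40 %" reads as a spatial fraction; for convex
  masks the resulting |NP|/|disc| area fraction is ~0.45–0.48 because
  the band crosses the thickest part of the disc.
- Pooled (one frame per disc) rather than per-slice standardization,
  since one NP-T1ρ value is produced per disc.
- Voxels are *classified*, never resampled, so biomarkers average
  original voxel values with no interpolation bias.
- Near-isotropic tensors (eigenvalue ratio < 1.05, circle-like masks)
  keep the identity rotation and flag the disc; <3 voxels or collinear
  sets raise a degenerate-geometry error.

## Biomarkers

Per disc: mean ± sample SD (ddof = 1) of T1ρ over valid NP voxels, the
whole-disc mean, and the valid-voxel count. Records with fewer than 10
valid NP voxels (configurable) are flagged incomplete and excluded from
the models, not silently dropped. Validity filtering is an addition of
this pipeline and can be disabled via the config.

## Cohort statistics

- **Mixed model**: REML random-intercept model,
  fixed effects = full factorial age × sex × level × group (40 columns).
  Age is centred at the sample mean; sex and group are effect-coded at
  ±1/2 (so a code of 0 yields the sex-/group-averaged prediction and a
  unit contrast equals the M−F / control−cLBP difference); level is
  treatment-coded with L1–L2 as reference. Wald (normal) CIs and
  p-values, two-sided α = 0.05, no multiple-testing correction.
- **Derived quantities** are linear contrasts averaged over the observed
  covariate rows: the marginal age slope is the observation-weighted
  average of cell-specific slopes (obtained by differentiating the
  design row with respect to age); sex and group contrasts analogously.
  Standard errors by the delta method on the fixed-effects covariance.
- **Level-wise models**: OLS of the outcome on age + sex + group +
  age×group within one level (one disc per subject per level, so no
  random effect); t-based CIs. Group contrasts are evaluated at the age
  centre, sex-averaged; per-group slopes come from the interaction term.
- **Rank deficiency**: an empty sex × group × level cell aborts with the
  cell named. Non-convergence of the mixed model is flagged on the fit
  and never silently replaced by a different estimator.
- The outcome column is a parameter, so every model reruns unchanged
  with NP-T2 substituted for NP-T1ρ.
- **Cochran–Armitage trend test** (authored here; none of the installed
  packages provides it): score statistic with scores 1..K on the 2×K
  group × grade table, two-sided normal p; cross-checked in the tests
  against a label-permutation oracle.
- Remaining description statistics: pooled-variance t tests, chi-square
  without continuity correction, Pearson r per group × level with
  t-transform p-values, density-normalised per-grade voxel histograms
  (2 ms bins), squared Pearson correlation for paired T1ρ/T2 voxels,
  and an age-adjusted OLS association helper that refuses fewer than 10
  complete cases.

## Synthetic cohort generator

One subject row and up to five disc rows per subject; deterministic per
seed. Defaults encode the emulated study conditions:

- 53 control / 80 cLBP; sex split 26 F/27 M and 35 F/45 M; ages
  truncated-normal on [19, 75] with the location solved numerically so
  the *truncated* mean is 43.9 y (SD 13.4). L1–L2 is dropped for
  5 control and 10 cLBP subjects, giving 650 discs (260/390 per group).
- Disc mean structure: control level means {81.0, 79.0, 77.0, 75.0,
  69.8} ms at the mean age (sex-averaged) with cLBP gaps {4.5, 4.2,
  4.0, 3.8, 11.3} ms; the L5–S1 values are published numbers, the upper
  levels are calibrations placing the group marginal means near
  76.4/70.8 ms. Age slope −1.0 ms/yr in every cell except cLBP L5–S1
  (−0.3 ms/yr); sex effect ±8.1/2 ms about the sex average;
  subject-intercept SD 12 ms; residual SD 13 ms (within-group SD
  ≈ 22.5 ms in total, matching the reported spread).
- NP-T2 disc means are affine in true NP-T1ρ (intercept 0.26, slope
  0.85, residual SD 9 ms), placing the group means near 65.2/60.4 ms.
- Pfirrmann grades band a latent score = true NP-T1ρ minus a 7 ms shift
  in the cLBP arm, at cuts {95, 80, 62, 48} ms, with 10 % one-grade
  misclassification. The banding and cuts are inventions (no published
  grading model exists to copy); the cLBP shift represents structural
  deterioration beyond what the NP-T1ρ mean captures and is calibrated
  so the simulated ordinal group separation matches the published grade
  tables (trend |z| ≈ 6–7, rejection at α = 10⁻⁴ in ≥95 % of seeds).
  Grade-table marginals are therefore more degenerated in the cLBP arm
  than a pure T1ρ banding would give.
- Voxel tables: ~225 NP voxels per disc (Poisson), scattering around
  the disc's true mean with a grade-dependent SD (16 → 6 ms from grade
  I to V: heterogeneity shrinks with structural deterioration); voxel
  T2 is affine in voxel T1ρ with noise scaled to plant a squared
  correlation of 0.80 over the pooled table.

What the generator does *not* emulate: real spine anatomy, longitudinal
change, Modic changes, non-Gaussian biomarker noise, informative
missingness, or any coupling between pain scores and imaging beyond the
group label. Passing recovery tests therefore demonstrates that the
*machinery* is unbiased and correctly calibrated under the planted
model, not that the clinical effect sizes would replicate in new data.

## Phantom generator

Five elliptical "discs" (semi-axes 24 × 7 voxels, 1 mm spacing, four
slices) with the NP as the central AP 40 % band at 85 ms vs a 55 ms
annulus (T2: 65/45 ms), signal S0 = 1000, Gaussian noise σ = S0/SNR
(default SNR 50). The NP/annulus transition is smoothed over ≈0.75
voxels — a partial-volume-like edge that keeps ROI means stable under
sub-voxel changes in band placement; the recorded per-disc NP truth is
the mean of the true map over the true NP band (≈83.6 ms with the
default smoothing), and recovery is always measured against that
recorded truth. Discs can be analytically rotated in-plane (no
resampling) to exercise rotation invariance of the geometry stage.

## Problem sizes and numerical choices

- Recovery and coverage studies use 200 replicate seeds (the default
  seed first); Monte-Carlo SEs from those replicates are the tolerance
  for recovery checks.
- The grid-search oracle in the tests profiles S0 in closed form and
  scans T densely (0.01 ms), which keeps the oracle global — the SSE
  valley runs diagonally through (S0, T) and box refinement can lose it.
- Ties/degenerate inputs: flat decay series clamp to t_max and are
  invalid; zero-variance cells return undefined correlations rather
  than NaN arithmetic; empty histogram grades are omitted with a logged
  notice.

## Known limitations

- Wald/normal inference for the mixed model (no Satterthwaite df); with
  133 subjects the coverage measured across replicates is 93–96 %.
- The marginal "age slope" from the full interaction model is the
  observation-weighted average of cell slopes; under the planted design
  that average is 0.914 ms/yr, slightly below the 1.0 ms/yr cell slope
  because one cell (cLBP L5–S1) is flatter.
- The relaxometry per-voxel precision is noise-bound (see the
  Cramér–Rao numbers above); ROI means, not voxel values, are the
  reliable output at clinical SNR.
- B0/B1 correction, multi-exponential decay, cross-TSL registration and
  automatic segmentation are out of scope; masks are inputs.
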