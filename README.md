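# discqmri

Quantitative-MRI analysis of lumbar intervertebral disc degeneration:
voxel-wise T1ρ/T2 relaxation-time mapping, geometric nucleus-pulposus
(NP) ROI extraction, per-disc biomarkers, and the cohort statistics that
separate pathological degeneration in chronic low back pain (cLBP) from
normal aging.

## The problem

T1ρ relaxation times track proteoglycan and water content in the disc
nucleus, so the mean NP-T1ρ of a disc is a continuous biomarker of
*biochemical* degeneration — changes that precede the structural
deterioration visible on conventional T2-weighted MRI (Pfirrmann
grading). Distinguishing the biochemical decline that comes with normal
aging from the excess decline associated with cLBP requires (a) reliable
voxel-wise relaxometry, (b) a reproducible, operator-free NP region, and
(c) statistical models that handle repeated measures (five discs per
subject) and age × sex × level × group structure.

This package implements that pipeline end to end and — because clinical
MRI data cannot ship with it — drives every stage with a synthetic
phantom and cohort generator that plants known ground truth, so each
stage is verified by parameter recovery.

## The model

**Relaxometry.** Each voxel's signal across spin-lock times follows the
mono-exponential decay

    SI(TSL) = S0 · exp(−TSL / T1ρ)

fitted per voxel by Levenberg–Marquardt nonlinear least squares,
initialised from the log-linear regression of ln SI on TSL, with
clamping to [1, 500] ms, background-noise masking, and validity flags.

**NP geometry.** Each disc mask (pooled over the four mid-sagittal
slices) is rotated into its principal-axis frame via the eigenvectors of
the second-moment (rotational inertia) tensor of the voxel coordinates;
the NP is the central anterior–posterior 40 % of the disc's extent along
the major axis. Voxels are classified by rotated coordinates — no
intensity resampling.

**Cohort statistics.** NP-T1ρ is modelled with a random-intercept
linear mixed model (REML) whose fixed effects are the full factorial
age × sex × level × group (all two-, three- and four-way interactions);
marginal quantities (observation-weighted age slope, age-adjusted sex
and group contrasts, covariate-specific predictions) are derived as
linear contrasts with delta-method CIs. Level-wise OLS models
(age + sex + group + age×group) probe the level-specific age–group
interaction. Supporting tests: Student's t, chi-square, Cochran–Armitage
trend (ordinal Pfirrmann tables), Pearson correlations per group×level,
grade-wise voxel histograms, and the voxel-wise T1ρ–T2 correlation.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/03_cohort_models.py
```

prints (default seed 20230101):

```
subjects: 133 (80 cLBP, 61 F); mean age 45.8 y
disc records: 650; NP voxels: 146059
NP-T1rho by group (ms):
         mean   std
cLBP     66.3  21.9
control  77.3  22.8

--- outcome: np_t1rho_mean ---
marginal age slope: -1.00 ms/yr (95% CI -1.20 to -0.81)
sex contrast (M-F): +8.37 ms (p=0.00032)
L5-S1 group gap (control-cLBP): +13.15 ms (p=5.9e-05)
L5-S1 slopes: control -1.18, cLBP -0.39 ms/yr (interaction p=0.0038)
L5-S1 predictions (sex-averaged):
  group  age  estimate  ci_low  ci_high
control 30.0      87.4    79.8     95.1
control 50.0      63.8    58.2     69.3
   cLBP 50.0      53.9    49.9     58.0
```

Reading: NP-T1ρ declines ~1 ms per year of age; males run ~8 ms higher
than females at a given age; at L5–S1 the cLBP group sits >10 ms below
controls after age/sex adjustment, and its age slope is much flatter
than the control slope — the planted "pathology vs normal aging"
signature, recovered by the fitted models. The phantom pipeline
(`analysis/02_phantom_relaxometry.py`) recovers each disc's planted NP
mean within ~0.4 ms at SNR 50, and
`analysis/05_recovery_study.py` summarises bias and 95 % CI coverage of
every planted effect across 200 replicate cohorts.

A `discqmri` command-line front end wraps the same stages
(`discqmri simulate cohort|phantom`, `fit-map`, `extract-roi`,
`biomarkers`, `analyze`, `run-all`).

## Layout

- `src/discqmri/` — library: `relaxometry`, `geometry`, `biomarkers`,
  `stats`, `synthetic`, `replication`, `config`, `io`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing under `results/`
- `tests/` — pytest suite (unit, property and end-to-end recovery tests)
- `docs/methods.md` — modelling and calibration notes;
  `docs/data_dictionary.md` — column definitions of the exported tables
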