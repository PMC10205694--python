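# Data dictionary

## subjects.csv (one row per subject)

| column | type | description |
| --- | --- | --- |
| subject_id | str | `S001`.. unique id |
| age | float | years |
| sex | {F, M} | sex |
| group | {control, cLBP} | study arm (cLBP = chronic low back pain) |
| odi | float | Oswestry Disability Index, 0–100 |
| vas | float | Visual Analog Scale pain score, 0–10 |
| bmi | float | kg/m²; missing (empty) for 14 controls |

## discs.csv (one row per subject × level; 650 rows under defaults)

| column | type | description |
| --- | --- | --- |
| subject_id, age, sex, group | | as above, repeated per disc |
| level | {L1L2..L5S1} | lumbar disc level |
| true_np_t1rho | float ms | generator truth (systematic + subject effect, no residual) |
| np_t1rho_mean | float ms | observed mean NP-T1ρ — the primary biomarker |
| np_t1rho_sd | float ms | within-NP voxel SD (heterogeneity) |
| wholedisc_t1rho_mean | float ms | mean T1ρ over the whole disc mask |
| np_t2_mean, wholedisc_t2_mean | float ms | T2 analogues |
| pfirrmann | int 1–5 | structural degeneration grade (I–V) |
| n_valid_voxels | int | valid NP voxels contributing to the mean |
| incomplete | bool | true when n_valid_voxels < the minimum (default 10) |

## voxels.csv (one row per valid NP voxel)

| column | type | description |
| --- | --- | --- |
| subject_id, level, pfirrmann | | disc identifiers |
| t1rho_voxel | float ms | voxel T1ρ |
| t2_voxel | float ms | paired voxel T2 (planted R² = 0.80 with T1ρ) |

## Phantom pipeline outputs

`disc_biomarkers.csv`: `level, np_t1rho_mean, np_t1rho_sd,
wholedisc_t1rho_mean, n_valid_voxels, incomplete` (as above, no
subject metadata). `geometry_report.json`: per level the in-plane
rotation angle (deg), inertia-tensor eigenvalues, AP extent (mm), voxel
counts and the degenerate (near-isotropic) flag. NIfTI maps
`map_t1rho_{t_ms,s0,fit_r2,valid}.nii.gz` carry the voxel-wise fit.

## Model outputs

`coefficients_<outcome>.csv`: term, estimate, se, ci_low, ci_high, p —
term names encode the coding (`sex[M-F]`, `group[ctl-cLBP]`,
`level[L2L3]`…, products joined with `:`).
`predictions_<outcome>.csv`: level, group, age, sex ("averaged"),
estimate, se, ci_low, ci_high, p.
`pearson_<outcome>.csv`: group, level, n, r, p.
`group_comparisons.csv`: variable, test, control, clbp, statistic, p.
`report_<outcome>.json`: the assembled analysis report (marginal slope,
contrasts, level-wise summaries, variance components, provenance).
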