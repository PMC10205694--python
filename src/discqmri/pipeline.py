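"""End-to-end orchestration: images -> maps -> ROIs -> disc table -> models.

Each stage failure is re-raised as :class:`PipelineError` carrying the
stage name, so a broken input surfaces with the stage that hit it.  All
tabular outputs embed a provenance block (config hash + seed) via a
sibling ``provenance.json``; CSV payloads themselves are deterministic
for a fixed seed and config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarkers as bm
from . import io as dio
from . import stats as st
from . import synthetic as syn
from .config import RunConfig
from .geometry import LEVELS, extract_np, standardize_disc

log = logging.getLogger("discqmri")

__all__ = ["PipelineError", "simulate_phantom_inputs", "run_phantom_pipeline", "analyze_cohort", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(name, str(exc)) from exc

        return wrapper

    return deco


def simulate_phantom_inputs(out_dir: str | Path, spec=None, seed: int = 7) -> dict:
    """Write phantom series + segmentation NIfTI files and the truth record."""
    spec = spec or syn.PhantomSpec()
    phantom = syn.generate_phantom(spec, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dio.write_series(phantom.t1rho_series, out_dir, "series_t1rho")
    dio.write_series(phantom.t2_series, out_dir, "series_t2")
    dio.write_segmentation(phantom.seg, out_dir / "segmentation.nii.gz")
    truth = {"np_true_means_t1rho": phantom.np_true_means, "seed": seed}
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return {"dir": str(out_dir), "truth": truth}


@_stage("relaxometry")
def _fit_stage(series, config: RunConfig):
    from .relaxometry import fit_map

    return fit_map(series, config=config.fit_config())


@_stage("disc_geometry")
def _geometry_stage(seg, config: RunConfig):
    regions = {}
    geometry_report = {}
    for level in seg.levels_present():
        std = standardize_disc(seg, level)
        region = extract_np(std, config.np_fraction)
        regions[level] = region
        ang = float(np.degrees(np.arctan2(std.rotation[1, 0], std.rotation[0, 0])))
        geometry_report[level] = {
            "angle_deg": ang,
            "eigenvalues": [float(e) for e in std.eigenvalues],
            "ap_extent_mm": [float(x) for x in std.ap_extent_mm],
            "n_voxels": int(std.coords_std.shape[0]),
            "n_np_voxels": region.n_voxels,
            "degenerate": bool(std.degenerate),
        }
    return regions, geometry_report


@_stage("biomarkers")
def _biomarker_stage(rmap, seg, regions, config: RunConfig) -> pd.DataFrame:
    rows = []
    for level in LEVELS:
        if level not in regions:
            continue
        summ = bm.disc_biomarkers(rmap, regions[level], seg, min_voxels=config.min_voxels)
        rows.append(
            {
                "level": level,
                "np_t1rho_mean": summ.np_mean,
                "np_t1rho_sd": summ.np_sd,
                "wholedisc_t1rho_mean": summ.wholedisc_mean,
                "n_valid_voxels": summ.n_valid_voxels,
                "incomplete": summ.incomplete,
            }
        )
    return pd.DataFrame(rows)


def run_phantom_pipeline(in_dir: str | Path, out_dir: str | Path, config: RunConfig | None = None) -> pd.DataFrame:
    """Images-to-disc-table pipeline on a phantom input directory."""
    config = config or RunConfig()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        series = dio.read_series(in_dir / "series_t1rho.nii.gz")
        seg = dio.read_segmentation(in_dir / "segmentation.nii.gz", config.axis_convention)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("io", str(exc)) from exc

    rmap = _fit_stage(series, config)
    regions, geo = _geometry_stage(seg, config)
    table = _biomarker_stage(rmap, seg, regions, config)

    dio.write_map(rmap, out_dir, "map_t1rho")
    table.to_csv(out_dir / "disc_biomarkers.csv", index=False)
    (out_dir / "geometry_report.json").write_text(json.dumps(geo, indent=2))
    _provenance(out_dir, config)
    log.info("phantom pipeline complete: %d discs", len(table))
    return table


def analyze_cohort(
    discs: pd.DataFrame,
    out_dir: str | Path | None = None,
    outcome: str = "np_t1rho_mean",
    voxels: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> dict:
    """The study's statistical analysis on a disc-level table.

    Fits the full mixed model and the five level-wise models, derives the
    marginal age slope, sex and group contrasts, the level-wise L5-S1
    quantities and the standard predictions, plus Pearson correlations.
    With a voxel table, adds grade-wise histograms and the voxel-level
    T1rho-T2 correlation.  Writes tidy CSV/JSON artifacts when
    ``out_dir`` is given and returns the report dict.
    """
    config = config or RunConfig()
    try:
        mixed = st.fit_mixed_model(discs, outcome=outcome, age_center=config.age_center)
        report: dict = {
            "outcome": outcome,
            "n_obs": mixed.n_obs,
            "n_subjects": mixed.n_subjects,
            "converged": mixed.converged,
            "variance_components": {
                "subject_intercept_sd": mixed.subject_sd,
                "residual_sd": mixed.resid_sd,
            },
            "marginal_age_slope": st.marginal_age_slope(mixed),
            "sex_contrast_M_minus_F": st.sex_contrast(mixed),
            "group_contrast_ctl_minus_clbp": st.group_contrast(mixed),
        }
        levelwise = {}
        predictions = []
        for level in LEVELS:
            try:
                fit = st.fit_levelwise_model(discs, level, outcome=outcome, age_center=config.age_center)
            except ValueError:
                continue
            slopes = st.per_group_age_slopes(fit)
            levelwise[level] = {
                "group_contrast": st.group_contrast(fit),
                "age_group_interaction_p": float(fit.pvalues["age:group[ctl-cLBP]"]),
                "slope_control": slopes["control"],
                "slope_cLBP": slopes["cLBP"],
            }
            for group, age in (("control", 30.0), ("control", 50.0), ("cLBP", 50.0)):
                pred = st.predict(fit, age=age, group=group)
                predictions.append(
                    {"level": level, "group": group, "age": age, "sex": "averaged", **pred}
                )
        report["levelwise"] = levelwise
        pearson = st.pearson_by_group_level(discs, outcome=outcome)
        if voxels is not None:
            hist, summary = st.pfirrmann_voxel_histograms(voxels)
            report["pfirrmann_voxel_summary"] = summary.to_dict(orient="records")
            if "t2_voxel" in voxels.columns:
                report["voxel_t1r_t2"] = st.voxelwise_t1r_t2_correlation(
                    voxels["t1rho_voxel"], voxels["t2_voxel"]
                )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cohort_stats", str(exc)) from exc

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _diagnostics_plot(mixed, out_dir / f"diagnostics_{outcome}.png")
        mixed.coefficients_frame().to_csv(out_dir / f"coefficients_{outcome}.csv")
        pd.DataFrame(predictions).to_csv(out_dir / f"predictions_{outcome}.csv", index=False)
        pearson.to_csv(out_dir / f"pearson_{outcome}.csv", index=False)
        if voxels is not None:
            hist.to_csv(out_dir / "pfirrmann_histograms.csv", index=False)
        (out_dir / f"report_{outcome}.json").write_text(json.dumps(report, indent=2, default=float))
        _provenance(out_dir, config)
    return report


def run_pipeline(config: RunConfig, work_dir: str | Path, phantom_spec=None) -> dict:
    """Simulate-then-analyze smoke pipeline: phantom imaging path plus the
    synthetic cohort statistics, all under ``work_dir``."""
    work_dir = Path(work_dir)
    inputs = work_dir / "inputs"
    outputs = work_dir / "outputs"
    phantom_spec = phantom_spec or syn.PhantomSpec()
    simulate_phantom_inputs(inputs, spec=phantom_spec, seed=config.seed)
    phantom_cfg = RunConfig(**{**config.to_dict(), "noise_sigma": phantom_spec.sigma})
    table = run_phantom_pipeline(inputs, outputs / "phantom", phantom_cfg)

    subjects, discs = syn.generate_cohort(seed=config.seed)
    voxels = syn.generate_voxels(discs, seed=config.seed)
    cohort_dir = outputs / "cohort"
    cohort_dir.mkdir(parents=True, exist_ok=True)
    subjects.to_csv(cohort_dir / "subjects.csv", index=False)
    discs.to_csv(cohort_dir / "discs.csv", index=False)
    report = analyze_cohort(discs, cohort_dir, voxels=voxels, config=config)
    return {"phantom_discs": len(table), "cohort_report": report}


def _diagnostics_plot(fit, path: Path) -> None:
    """Residual QQ and residual-vs-fitted panels for a cohort model fit."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats as sps

    y = fit.data[fit.outcome].to_numpy(dtype=float)
    fitted = fit.design_matrix.to_numpy() @ fit.params.to_numpy()
    resid = y - fitted  # marginal residuals (subject effect not removed)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    sps.probplot(resid, dist="norm", plot=axes[0])
    axes[0].set_title("residual QQ")
    axes[1].scatter(fitted, resid, s=6, alpha=0.5)
    axes[1].axhline(0.0, color="k", lw=0.8)
    axes[1].set_xlabel("fitted (ms)")
    axes[1].set_ylabel("residual (ms)")
    axes[1].set_title("residuals vs fitted")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _provenance(out_dir: Path, config: RunConfig) -> None:
    (out_dir / "provenance.json").write_text(
        json.dumps({"config_hash": config.hash(), "seed": config.seed, "config": config.to_dict()}, indent=2)
    )
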