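"""Cohort statistics for disc biomarkers.

The centrepiece is a random-intercept linear mixed model of NP-T1rho (or
NP-T2) on age, sex, spinal level and study group with the full factorial
interaction structure: every two- and three-way interaction plus the
four-way age x sex x level x group term.  Because the model is saturated
in interactions, single coefficients are not directly interpretable;
marginal quantities (the observation-weighted age slope, the age-adjusted
sex and group contrasts, covariate-specific predictions) are derived as
linear contrasts of the fixed effects with delta-method standard errors.

Coding conventions (documented in every ModelFit):

* age is centred at the sample mean (so intercept-level contrasts are
  "at the mean age");
* sex and group are effect-coded at +/- 1/2 (M/control = +1/2), so
  setting the code to 0 in a prediction row yields the sex- or
  group-averaged prediction, and a contrast row with the code set to 1
  yields the male-minus-female (control-minus-cLBP) difference;
* spinal level is treatment-coded with L1-L2 as reference.

Per-level models are ordinary least squares with age, sex, group and the
age x group interaction (one disc per subject per level, so no random
effect is needed).  The module also provides the supporting tests used in
cohort description: Student's t, chi-square, the Cochran-Armitage trend
test for ordinal grade distributions, Pearson correlations per group and
level, grade-wise voxel histograms, and the voxel-wise T1rho-T2
correlation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .geometry import LEVELS

__all__ = [
    "ModelFit",
    "TrendTestResult",
    "fit_mixed_model",
    "fit_levelwise_model",
    "predict",
    "marginal_age_slope",
    "sex_contrast",
    "group_contrast",
    "pearson_by_group_level",
    "cochran_armitage_trend",
    "group_comparison_suite",
    "pfirrmann_voxel_histograms",
    "voxelwise_t1r_t2_correlation",
    "adjusted_association",
]

SEX_CODE = {"M": 0.5, "F": -0.5}
GROUP_CODE = {"control": 0.5, "cLBP": -0.5}


@dataclass
class ModelFit:
    """A fitted cohort model plus the metadata needed for contrasts."""

    formula: str
    outcome: str
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper
    pvalues: pd.Series
    cov: np.ndarray  # fixed-effects covariance, param order
    age_center: float
    design_kind: str  # "full_factorial" | "levelwise"
    level: str | None
    subject_sd: float | None
    resid_sd: float
    n_obs: int
    n_subjects: int
    converged: bool
    design_matrix: pd.DataFrame = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)
    df_resid: float | None = None

    def coefficients_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "ci_low": self.conf_int["lower"],
                "ci_high": self.conf_int["upper"],
                "p": self.pvalues,
            }
        )
        out.index.name = "term"
        return out


@dataclass
class TrendTestResult:
    statistic: float
    p: float
    direction: str  # "increasing" | "decreasing" | "none"


# ---------------------------------------------------------------------------
# Design matrices


def _full_factorial_design(
    df: pd.DataFrame, age_center: float, age_block: str = "value"
) -> pd.DataFrame:
    """40-column design: {1, age} x {1, sex} x {1, group} x {1, L2..L5} products.

    ``age_block`` selects the age factor's columns: "value" -> (1, age_c)
    for the model itself, "deriv" -> (0, 1) whose dot with beta gives the
    per-row age slope.  Similar derivative blocks are used for the sex and
    group contrasts by the contrast helpers.
    """
    return _factorial_blocks(df, age_center, {"age": age_block})


def _factorial_blocks(df: pd.DataFrame, age_center: float, mode: dict) -> pd.DataFrame:
    n = len(df)
    age_c = df["age"].to_numpy(dtype=float) - age_center
    sex_e = df["sex"].map(SEX_CODE).to_numpy(dtype=float)
    group_e = df["group"].map(GROUP_CODE).to_numpy(dtype=float)
    if np.isnan(sex_e).any() or np.isnan(group_e).any():
        raise ValueError("sex must be F/M and group control/cLBP")
    ones, zeros = np.ones(n), np.zeros(n)

    def block(name, base_one, base_var, labels):
        m = mode.get(name, "value")
        if m == "value":
            return [base_one, base_var], labels
        if m == "deriv":
            return [zeros, ones], labels
        raise ValueError(m)

    age_cols, age_lab = block("age", ones, age_c, ["", "age"])
    sex_cols, sex_lab = block("sex", ones, sex_e, ["", "sex[M-F]"])
    grp_cols, grp_lab = block("group", ones, group_e, ["", "group[ctl-cLBP]"])

    lvl = df["level"].to_numpy()
    unknown = set(lvl) - set(LEVELS)
    if unknown:
        raise ValueError(f"unknown level labels {sorted(unknown)}")
    lvl_cols = [ones] + [(lvl == name).astype(float) for name in LEVELS[1:]]
    lvl_lab = [""] + [f"level[{name}]" for name in LEVELS[1:]]

    cols, names = [], []
    for (a, al), (s, sl), (g, gl), (l, ll) in itertools.product(
        zip(age_cols, age_lab), zip(sex_cols, sex_lab), zip(grp_cols, grp_lab), zip(lvl_cols, lvl_lab)
    ):
        cols.append(a * s * g * l)
        label = ":".join(x for x in (al, sl, gl, ll) if x)
        names.append(label or "Intercept")
    return pd.DataFrame(np.column_stack(cols), columns=names, index=df.index)


def _levelwise_design(df: pd.DataFrame, age_center: float) -> pd.DataFrame:
    age_c = df["age"].to_numpy(dtype=float) - age_center
    sex_e = df["sex"].map(SEX_CODE).to_numpy(dtype=float)
    group_e = df["group"].map(GROUP_CODE).to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "Intercept": 1.0,
            "age": age_c,
            "sex[M-F]": sex_e,
            "group[ctl-cLBP]": group_e,
            "age:group[ctl-cLBP]": age_c * group_e,
        },
        index=df.index,
    )


def _usable(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    df = table.copy()
    if "incomplete" in df.columns:
        df = df[~df["incomplete"].astype(bool)]
    df = df[np.isfinite(df[outcome].astype(float))]
    return df


# ---------------------------------------------------------------------------
# Model fits


def fit_mixed_model(
    table: pd.DataFrame,
    outcome: str = "np_t1rho_mean",
    age_center: float | None = None,
) -> ModelFit:
    """Random-intercept mixed model with the full age x sex x level x group
    fixed-effect factorial, fitted by REML.

    Incomplete records (``incomplete`` column true, or missing outcome)
    are excluded before fitting.  Rank deficiency from an empty
    sex x group x level cell raises with the offending cell named.
    Non-convergence is flagged on the returned fit, never silently
    replaced by a different estimator.
    """
    df = _usable(table, outcome)
    if df["subject_id"].nunique() < 4:
        raise ValueError("need at least 2 subjects per group")
    center = float(df["age"].mean()) if age_center is None else float(age_center)

    cells = df.groupby(["sex", "group", "level"], observed=True).size()
    expected = itertools.product(("F", "M"), ("control", "cLBP"), LEVELS)
    empty = [c for c in expected if c not in cells.index]
    if empty:
        raise ValueError(f"empty design cell(s) {empty}: full factorial model is rank deficient")

    X = _full_factorial_design(df, center)
    y = df[outcome].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X.to_numpy(), groups=df["subject_id"].to_numpy())
        res = model.fit(reml=True)
    k = X.shape[1]
    names = list(X.columns)
    params = pd.Series(res.fe_params, index=names)
    cov = np.asarray(res.cov_params())[:k, :k]
    bse = pd.Series(np.sqrt(np.clip(np.diag(cov), 0.0, None)), index=names)
    z = params / bse
    pvals = pd.Series(2 * sps.norm.sf(np.abs(z)), index=names)
    ci = pd.DataFrame(
        {"lower": params - 1.959964 * bse, "upper": params + 1.959964 * bse}, index=names
    )
    return ModelFit(
        formula=f"{outcome} ~ (age + sex + group + level)^4 + (1 | subject)",
        outcome=outcome,
        params=params,
        bse=bse,
        conf_int=ci,
        pvalues=pvals,
        cov=cov,
        age_center=center,
        design_kind="full_factorial",
        level=None,
        subject_sd=float(np.sqrt(max(float(np.asarray(res.cov_re)[0, 0]), 0.0))),
        resid_sd=float(np.sqrt(res.scale)),
        n_obs=len(df),
        n_subjects=int(df["subject_id"].nunique()),
        converged=bool(res.converged),
        design_matrix=X,
        data=df,
    )


def fit_levelwise_model(
    table: pd.DataFrame,
    level: str,
    outcome: str = "np_t1rho_mean",
    age_center: float | None = None,
) -> ModelFit:
    """OLS of the outcome on age, sex, group and age x group at one level."""
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    df = _usable(table, outcome)
    df = df[df["level"] == level]
    if df.empty:
        raise ValueError(f"no records at level {level}")
    if df["subject_id"].duplicated().any():
        raise ValueError(f"multiple records per subject at {level}; level-wise model expects one")
    center = float(df["age"].mean()) if age_center is None else float(age_center)
    X = _levelwise_design(df, center)
    y = df[outcome].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int()
    ci.columns = ["lower", "upper"]
    return ModelFit(
        formula=f"{outcome} ~ age + sex + group + age:group  [{level}]",
        outcome=outcome,
        params=res.params,
        bse=res.bse,
        conf_int=ci,
        pvalues=res.pvalues,
        cov=np.asarray(res.cov_params()),
        age_center=center,
        design_kind="levelwise",
        level=level,
        subject_sd=None,
        resid_sd=float(np.sqrt(res.mse_resid)),
        n_obs=len(df),
        n_subjects=int(df["subject_id"].nunique()),
        converged=True,
        design_matrix=X,
        data=df,
        df_resid=float(res.df_resid),
    )


# ---------------------------------------------------------------------------
# Derived quantities (contrasts, predictions)


def _crit(fit: ModelFit) -> float:
    if fit.df_resid is not None:
        return float(sps.t.ppf(0.975, fit.df_resid))
    return 1.959964


def _contrast(fit: ModelFit, w: np.ndarray) -> dict:
    est = float(w @ fit.params.to_numpy())
    se = float(np.sqrt(max(float(w @ fit.cov @ w), 0.0)))
    c = _crit(fit)
    if fit.df_resid is not None:
        p = 2 * sps.t.sf(abs(est / se), fit.df_resid) if se > 0 else np.nan
    else:
        p = 2 * sps.norm.sf(abs(est / se)) if se > 0 else np.nan
    return {"estimate": est, "se": se, "ci_low": est - c * se, "ci_high": est + c * se, "p": p}


def marginal_age_slope(fit: ModelFit) -> dict:
    """Observation-weighted mean of the cell-specific age slopes (ms/year)."""
    if fit.design_kind == "full_factorial":
        D = _factorial_blocks(fit.data, fit.age_center, {"age": "deriv"})
    else:
        D = fit.design_matrix.copy()
        D["Intercept"] = 0.0
        D["sex[M-F]"] = 0.0
        D["group[ctl-cLBP]"] = 0.0
        D["age"] = 1.0
        D["age:group[ctl-cLBP]"] = fit.data["group"].map(GROUP_CODE).to_numpy()
    w = D.to_numpy().mean(axis=0)
    return _contrast(fit, w)


def sex_contrast(fit: ModelFit) -> dict:
    """Age-adjusted male-minus-female difference, averaged over observations."""
    if fit.design_kind == "full_factorial":
        D = _factorial_blocks(fit.data, fit.age_center, {"sex": "deriv"})
        w = D.to_numpy().mean(axis=0)
    else:
        w = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
    return _contrast(fit, w)


def group_contrast(fit: ModelFit, at_age: float | None = None) -> dict:
    """Age- and sex-adjusted control-minus-cLBP difference.

    For the full model the contrast is averaged over the observed
    covariate distribution; for a level-wise fit it is evaluated at
    ``at_age`` (default: the age centre) with sex averaged out.
    """
    if fit.design_kind == "full_factorial":
        D = _factorial_blocks(fit.data, fit.age_center, {"group": "deriv"})
        w = D.to_numpy().mean(axis=0)
    else:
        age_c = 0.0 if at_age is None else float(at_age) - fit.age_center
        w = np.array([0.0, 0.0, 0.0, 1.0, age_c])
    return _contrast(fit, w)


def predict(
    fit: ModelFit,
    age: float,
    group: str,
    sex: str | None = None,
    level: str | None = None,
) -> dict:
    """Point prediction (ms) with its 95% CI at given covariates.

    ``sex=None`` gives the sex-averaged prediction (effect code 0);
    likewise ``group`` must always be named.  For the full-factorial fit
    a ``level`` is required.
    """
    if group not in GROUP_CODE:
        raise ValueError(f"unknown group {group!r}")
    if sex is not None and sex not in SEX_CODE:
        raise ValueError(f"unknown sex {sex!r}")
    age_c = float(age) - fit.age_center
    sex_e = 0.0 if sex is None else SEX_CODE[sex]
    group_e = GROUP_CODE[group]
    if fit.design_kind == "levelwise":
        w = np.array([1.0, age_c, sex_e, group_e, age_c * group_e])
    else:
        if level is None:
            raise ValueError("level is required for predictions from the full model")
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}")
        row = pd.DataFrame(
            {"age": [age], "sex": ["M"], "group": [group], "level": [level]}
        )
        base = _factorial_blocks(row, fit.age_center, {})
        # Rebuild with the requested (possibly averaged) sex code.
        sex_block = _factorial_blocks(row, fit.age_center, {"sex": "deriv"})
        w = base.to_numpy()[0] + (sex_e - SEX_CODE["M"]) * sex_block.to_numpy()[0]
    return _contrast(fit, w)


def per_group_age_slopes(fit: ModelFit) -> dict:
    """Control and cLBP age slopes from a level-wise fit (ms/year)."""
    if fit.design_kind != "levelwise":
        raise ValueError("per-group slopes are defined for level-wise fits")
    out = {}
    for g, code in GROUP_CODE.items():
        w = np.array([0.0, 1.0, 0.0, 0.0, code])
        out[g] = _contrast(fit, w)
    return out


# ---------------------------------------------------------------------------
# Correlations and simple tests


def pearson_by_group_level(
    table: pd.DataFrame, outcome: str = "np_t1rho_mean"
) -> pd.DataFrame:
    """Pearson r of the outcome vs age within each group x level cell."""
    rows = []
    df = _usable(table, outcome)
    for (group, level), cell in df.groupby(["group", "level"], observed=True):
        if len(cell) < 3:
            continue
        x = cell["age"].to_numpy(dtype=float)
        y = cell[outcome].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"group": group, "level": level, "n": len(cell), "r": np.nan, "p": np.nan})
            continue
        r, p = sps.pearsonr(x, y)
        rows.append({"group": group, "level": level, "n": len(cell), "r": r, "p": p})
    return pd.DataFrame(rows)


def cochran_armitage_trend(
    counts: np.ndarray, scores: np.ndarray | None = None
) -> TrendTestResult:
    """Cochran-Armitage test for trend in a 2 x K table of ordered categories.

    ``counts`` rows are the two groups, columns the ordered categories
    (default scores 1..K).  The statistic is the standardised score
    difference; the p-value is two-sided normal.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] < 2:
        raise ValueError("counts must be a 2 x K table with K >= 2")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    col_tot = counts.sum(axis=0)
    row_tot = counts.sum(axis=1)
    if np.any(row_tot == 0) or col_tot.sum() == 0:
        raise ValueError("zero-margin table")
    K = counts.shape[1]
    s = np.arange(1, K + 1, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    n = col_tot.sum()
    n1 = row_tot[0]
    t_obs = float(s @ counts[0])
    mean = n1 * float(s @ col_tot) / n
    var = (
        n1
        * (n - n1)
        / (n**2 * (n - 1))
        * (n * float((s**2) @ col_tot) - float(s @ col_tot) ** 2)
    )
    if var <= 0:
        return TrendTestResult(0.0, 1.0, "none")
    z = (t_obs - mean) / np.sqrt(var)
    p = float(2 * sps.norm.sf(abs(z)))
    direction = "none" if z == 0 else ("increasing" if z > 0 else "decreasing")
    return TrendTestResult(float(z), p, direction)


def group_comparison_suite(
    subjects: pd.DataFrame,
    discs: pd.DataFrame,
    continuous: tuple = ("age", "odi", "vas", "bmi"),
    outcomes: tuple = ("np_t1rho_mean", "np_t2_mean"),
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Cohort-description table: per-variable group comparisons.

    Student's t for continuous subject measures, chi-square (no
    continuity correction) for sex, Cochran-Armitage trend for Pfirrmann
    grade, and the mixed-model group contrast for imaging outcomes.
    Missing columns are skipped with a logged notice.
    """
    rows = []
    ctl = subjects[subjects["group"] == "control"]
    pat = subjects[subjects["group"] == "cLBP"]

    for var in continuous:
        if var not in subjects.columns:
            if log is not None:
                log.append(f"column {var!r} absent; skipped")
            continue
        a = ctl[var].dropna().to_numpy(dtype=float)
        b = pat[var].dropna().to_numpy(dtype=float)
        t, p = sps.ttest_ind(a, b)
        rows.append(
            {
                "variable": var,
                "test": "t",
                "control": a.mean(),
                "clbp": b.mean(),
                "statistic": t,
                "p": p,
            }
        )

    sex_tab = pd.crosstab(subjects["group"], subjects["sex"]).loc[["control", "cLBP"]]
    chi2, p, _, _ = sps.chi2_contingency(sex_tab.to_numpy(), correction=False)
    rows.append(
        {
            "variable": "sex",
            "test": "chi2",
            "control": float(sex_tab.loc["control", "F"]),
            "clbp": float(sex_tab.loc["cLBP", "F"]),
            "statistic": chi2,
            "p": p,
        }
    )

    if "pfirrmann" in discs.columns:
        tab = (
            pd.crosstab(discs["group"], discs["pfirrmann"])
            .reindex(index=["control", "cLBP"], columns=[1, 2, 3, 4, 5], fill_value=0)
            .to_numpy()
        )
        res = cochran_armitage_trend(tab)
        rows.append(
            {
                "variable": "pfirrmann",
                "test": "cochran_armitage",
                "control": np.nan,
                "clbp": np.nan,
                "statistic": res.statistic,
                "p": res.p,
            }
        )

    for outcome in outcomes:
        if outcome not in discs.columns:
            if log is not None:
                log.append(f"outcome {outcome!r} absent; skipped")
            continue
        fit = fit_mixed_model(discs, outcome=outcome)
        con = group_contrast(fit)
        rows.append(
            {
                "variable": outcome,
                "test": "mixed_model_contrast",
                "control": discs.loc[discs["group"] == "control", outcome].mean(),
                "clbp": discs.loc[discs["group"] == "cLBP", outcome].mean(),
                "statistic": con["estimate"],
                "p": con["p"],
            }
        )
    return pd.DataFrame(rows)


def pfirrmann_voxel_histograms(
    voxels: pd.DataFrame,
    value_col: str = "t1rho_voxel",
    bin_width: float = 2.0,
    log: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Density-normalised per-grade histograms of NP voxel values.

    Returns (histogram long table, per-grade summary).  Empty grades are
    omitted with a notice.
    """
    vals = voxels[value_col].to_numpy(dtype=float)
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    hist_rows, summary_rows = [], []
    for grade in range(1, 6):
        sel = voxels["pfirrmann"] == grade
        v = vals[sel.to_numpy()]
        if v.size == 0:
            if log is not None:
                log.append(f"Pfirrmann grade {grade}: no voxels, omitted")
            continue
        density, _ = np.histogram(v, bins=edges, density=True)
        hist_rows.append(
            pd.DataFrame(
                {
                    "pfirrmann": grade,
                    "bin_left": edges[:-1],
                    "bin_right": edges[1:],
                    "density": density,
                }
            )
        )
        summary_rows.append(
            {"pfirrmann": grade, "n_voxels": v.size, "mean": v.mean(), "sd": v.std(ddof=1)}
        )
    return pd.concat(hist_rows, ignore_index=True), pd.DataFrame(summary_rows)


def voxelwise_t1r_t2_correlation(t1rho: np.ndarray, t2: np.ndarray) -> dict:
    """Squared Pearson correlation of paired voxel T1rho / T2 values."""
    t1rho = np.asarray(t1rho, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    ok = np.isfinite(t1rho) & np.isfinite(t2)
    t1rho, t2 = t1rho[ok], t2[ok]
    if t1rho.size < 3:
        raise ValueError("need at least 3 paired voxels")
    if np.std(t1rho) == 0 or np.std(t2) == 0:
        return {"r2": np.nan, "r": np.nan, "p": np.nan, "n": int(t1rho.size), "defined": False}
    r, p = sps.pearsonr(t1rho, t2)
    return {"r2": float(r**2), "r": float(r), "p": float(p), "n": int(t1rho.size), "defined": True}


def adjusted_association(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    adjusters: tuple = ("age",),
    min_cases: int = 10,
) -> dict:
    """OLS association of ``outcome`` with ``exposure``, adjusted.

    Complete cases only; refuses (raises) below ``min_cases``.  Returns
    the exposure coefficient with CI and p.
    """
    cols = [outcome, exposure, *adjusters]
    df = table[cols].dropna()
    if len(df) < min_cases:
        raise ValueError(f"only {len(df)} complete cases (<{min_cases}); refusing to fit")
    X = sm.add_constant(df[[exposure, *adjusters]].astype(float))
    res = sm.OLS(df[outcome].astype(float), X).fit()
    ci = res.conf_int().loc[exposure]
    return {
        "estimate": float(res.params[exposure]),
        "se": float(res.bse[exposure]),
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "p": float(res.pvalues[exposure]),
        "n": int(len(df)),
    }
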