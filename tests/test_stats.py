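import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from discqmri import stats as st
from discqmri import synthetic as syn
from discqmri.geometry import LEVELS

from _oracles import permutation_trend_p


def noise_free_table(fixed_age: float | None = None, seed: int = 0) -> pd.DataFrame:
    kwargs = dict(subject_sd=0.0, resid_sd=0.0)
    if fixed_age is not None:
        kwargs.update(age_sd=0.0, age_min=fixed_age, age_max=fixed_age)
    _, discs = syn.generate_cohort(syn.CohortSpec(**kwargs), seed=seed)
    return discs


class TestMixedModel:
    def test_noise_free_exact_recovery(self):
        discs = noise_free_table()
        fit = st.fit_mixed_model(discs, age_center=syn.AGE_CENTER)
        spec = syn.CohortSpec()
        # every fitted cell mean and slope reproduces the generator exactly
        for group in ("control", "cLBP"):
            for level in LEVELS:
                pred = st.predict(fit, age=50.0, group=group, sex=None, level=level)
                planted = spec.cell_mean(group, level) + spec.cell_slope(group, level) * (50.0 - 43.9)
                assert pred["estimate"] == pytest.approx(planted, abs=1e-7)
        assert st.sex_contrast(fit)["estimate"] == pytest.approx(8.1, abs=1e-7)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-3)

    def test_marginal_slope_is_observation_weighted_cell_average(self):
        discs = noise_free_table()
        fit = st.fit_mixed_model(discs)
        n_clbp_l5s1 = ((discs["group"] == "cLBP") & (discs["level"] == "L5S1")).sum()
        planted = -(1.0 * (len(discs) - n_clbp_l5s1) + 0.3 * n_clbp_l5s1) / len(discs)
        assert st.marginal_age_slope(fit)["estimate"] == pytest.approx(planted, abs=1e-7)

    def test_matches_ols_when_one_record_per_subject(self):
        # keep a single disc per subject (levels cycled) -> random intercept
        # is unidentifiable, subject SD ~ 0, contrasts equal the OLS ones
        _, discs = syn.generate_cohort(syn.CohortSpec(subject_sd=0.0), seed=4)
        k = discs.groupby("subject_id").cumcount()
        sizes = discs.groupby("subject_id")["level"].transform("size")
        codes = discs["subject_id"].astype("category").cat.codes
        keep = discs[k == (codes % sizes)]
        assert not keep["subject_id"].duplicated().any()
        fit = st.fit_mixed_model(keep)
        X = fit.design_matrix.to_numpy()
        beta = np.linalg.lstsq(X, keep["np_t1rho_mean"].to_numpy(), rcond=None)[0]
        ols_fit_params = pd.Series(beta, index=fit.params.index)
        w_fit = st.group_contrast(fit)["estimate"]
        # same contrast weights applied to the OLS solution
        D = st._factorial_blocks(fit.data, fit.age_center, {"group": "deriv"})
        w = D.to_numpy().mean(axis=0)
        assert w_fit == pytest.approx(float(w @ ols_fit_params.to_numpy()), abs=1e-4)

    def test_empty_cell_raises_named_error(self):
        _, discs = syn.generate_cohort(seed=1)
        drop = (discs["sex"] == "F") & (discs["group"] == "control") & (discs["level"] == "L5S1")
        with pytest.raises(ValueError, match="L5S1"):
            st.fit_mixed_model(discs[~drop])

    def test_variance_components_recovered(self, default_cohort):
        _, discs = default_cohort
        fit = st.fit_mixed_model(discs)
        assert fit.subject_sd == pytest.approx(12.0, abs=2.5)
        assert fit.resid_sd == pytest.approx(13.0, abs=2.0)
        assert fit.converged

    def test_t2_outcome_runs_unchanged(self, default_cohort):
        _, discs = default_cohort
        fit = st.fit_mixed_model(discs, outcome="np_t2_mean")
        slope = st.marginal_age_slope(fit)
        # T2 is an affine (slope 0.85) image of T1rho, so the planted age
        # slope scales accordingly
        assert slope["estimate"] == pytest.approx(0.85 * -0.914, abs=3 * slope["se"])


class TestLevelwiseModel:
    def test_noise_free_exact_recovery(self):
        discs = noise_free_table()
        fit = st.fit_levelwise_model(discs, "L5S1", age_center=syn.AGE_CENTER)
        slopes = st.per_group_age_slopes(fit)
        assert slopes["control"]["estimate"] == pytest.approx(-1.0, abs=1e-8)
        assert slopes["cLBP"]["estimate"] == pytest.approx(-0.3, abs=1e-8)
        assert st.group_contrast(fit, at_age=43.9)["estimate"] == pytest.approx(11.3, abs=1e-8)

    def test_duplicate_subject_rejected(self, default_cohort):
        _, discs = default_cohort
        dup = pd.concat([discs, discs[discs["level"] == "L5S1"].head(1)])
        with pytest.raises(ValueError, match="one"):
            st.fit_levelwise_model(dup, "L5S1")

    def test_prediction_at_center_reference_equals_design_identity(self, default_cohort):
        _, discs = default_cohort
        fit = st.fit_levelwise_model(discs, "L3L4")
        pred = st.predict(fit, age=fit.age_center, group="control")
        expected = fit.params["Intercept"] + 0.5 * fit.params["group[ctl-cLBP]"]
        assert pred["estimate"] == pytest.approx(float(expected), abs=1e-10)

    def test_unknown_labels_rejected(self, default_cohort):
        _, discs = default_cohort
        fit = st.fit_levelwise_model(discs, "L5S1")
        with pytest.raises(ValueError):
            st.predict(fit, age=40, group="patients")
        with pytest.raises(ValueError):
            st.predict(fit, age=40, group="control", sex="X")


class TestTrendTest:
    def test_printed_grade_counts_strongly_significant(self):
        counts = np.array([[64, 114, 60, 14, 8], [37, 172, 82, 72, 27]])
        res = st.cochran_armitage_trend(counts)
        assert res.p < 1e-4
        assert res.direction == "decreasing"  # fewer high grades in row 1 (control)

    def test_identical_rows_give_null(self):
        res = st.cochran_armitage_trend(np.array([[10, 20, 30], [10, 20, 30]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_against_permutation_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(6):
            counts = rng.integers(2, 40, size=(2, 5))
            res = st.cochran_armitage_trend(counts)
            p_perm = permutation_trend_p(counts, n_perm=20000, seed=1)
            assert abs(res.p - p_perm) < 0.02

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            st.cochran_armitage_trend(np.array([[0, 0, 0], [1, 2, 3]]))


class TestGroupComparisons:
    def test_printed_sex_table_chi_square(self):
        subjects = pd.DataFrame(
            {
                "group": ["control"] * 53 + ["cLBP"] * 80,
                "sex": ["F"] * 26 + ["M"] * 27 + ["F"] * 35 + ["M"] * 45,
                "age": 40.0,
            }
        )
        chi2, p, _, _ = sps.chi2_contingency(
            pd.crosstab(subjects["group"], subjects["sex"]).to_numpy(), correction=False
        )
        assert p == pytest.approx(0.55, abs=0.01)

    def test_t_equals_pooled_variance_closed_form(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        t, p = sps.ttest_ind(a, b)
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_hand), 4), abs=1e-12)

    def test_suite_assembles_all_tests(self, default_cohort):
        subjects, discs = default_cohort
        log: list[str] = []
        out = st.group_comparison_suite(subjects, discs, log=log)
        assert set(out["test"]) == {"t", "chi2", "cochran_armitage", "mixed_model_contrast"}
        assert (out["p"].between(0, 1)).all()
        row = out[out["variable"] == "pfirrmann"].iloc[0]
        assert row["p"] < 1e-4

    def test_identical_groups_null(self):
        subjects = pd.DataFrame(
            {
                "group": ["control"] * 10 + ["cLBP"] * 10,
                "sex": (["F"] * 5 + ["M"] * 5) * 2,
                "age": np.tile(np.arange(30.0, 40.0), 2),
            }
        )
        out = st.group_comparison_suite(subjects, pd.DataFrame(), continuous=("age",), outcomes=())
        age_row = out[out["variable"] == "age"].iloc[0]
        assert age_row["p"] == pytest.approx(1.0)
        assert out[out["variable"] == "sex"]["statistic"].iloc[0] == pytest.approx(0.0)


class TestCorrelations:
    def test_exact_line_gives_r_minus_one(self, default_cohort):
        _, discs = default_cohort
        df = discs[discs["level"] == "L5S1"].copy()
        df["np_t1rho_mean"] = 100.0 - df["age"]
        out = st.pearson_by_group_level(df)
        assert np.allclose(out["r"], -1.0)

    def test_null_correlation_unbiased(self):
        rng = np.random.default_rng(3)
        rs = []
        for _ in range(1000):
            x, y = rng.normal(size=(2, 50))
            rs.append(sps.pearsonr(x, y)[0])
        assert abs(np.mean(rs)) < 0.05

    def test_default_cohort_l5s1_pattern(self):
        # control strongly age-correlated, cLBP weakly (flattened slope +
        # same noise) in most seeds
        weaker = 0
        n = 30
        for seed in range(n):
            _, discs = syn.generate_cohort(seed=400 + seed)
            out = st.pearson_by_group_level(discs).set_index(["group", "level"])
            r_ctl = out.loc[("control", "L5S1"), "r"]
            r_pat = out.loc[("cLBP", "L5S1"), "r"]
            weaker += abs(r_pat) < abs(r_ctl)
            if seed == 0:
                assert 0.45 <= abs(r_ctl) <= 0.8
        assert weaker >= 0.9 * n

    def test_voxel_r2_exact_and_null(self):
        x = np.linspace(40, 120, 100)
        assert st.voxelwise_t1r_t2_correlation(x, 0.8 * x)["r2"] == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 10000))
        assert st.voxelwise_t1r_t2_correlation(a, b)["r2"] < 0.01


class TestHistograms:
    def test_density_normalisation_and_conservation(self):
        rng = np.random.default_rng(2)
        voxels = pd.DataFrame(
            {
                "pfirrmann": np.repeat([2, 3], 500),
                "t1rho_voxel": np.concatenate(
                    [rng.uniform(60, 70, 500), rng.uniform(50, 60, 500)]
                ),
            }
        )
        hist, summary = st.pfirrmann_voxel_histograms(voxels)
        for grade, sub in hist.groupby("pfirrmann"):
            integral = (sub["density"] * (sub["bin_right"] - sub["bin_left"])).sum()
            assert integral == pytest.approx(1.0, abs=1e-9)
        assert summary["n_voxels"].sum() == len(voxels)

    def test_empty_grade_omitted_with_notice(self):
        voxels = pd.DataFrame({"pfirrmann": [1] * 20, "t1rho_voxel": np.linspace(80, 120, 20)})
        log: list[str] = []
        _, summary = st.pfirrmann_voxel_histograms(voxels, log=log)
        assert summary["pfirrmann"].tolist() == [1]
        assert len(log) == 4


class TestAdjustedAssociation:
    def test_exposure_equals_outcome(self, default_cohort):
        subjects, _ = default_cohort
        df = subjects.assign(outcome=subjects["bmi"])
        res = st.adjusted_association(df, "outcome", "bmi", adjusters=("age",))
        assert res["estimate"] == pytest.approx(1.0, abs=1e-10)
        assert res["p"] < 1e-10

    def test_matches_normal_equations_on_small_fixture(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "y": rng.normal(60, 10, 12),
                "x": rng.normal(25, 4, 12),
                "age": rng.uniform(20, 70, 12),
            }
        )
        res = st.adjusted_association(df, "y", "x", adjusters=("age",))
        X = np.column_stack([np.ones(12), df["x"], df["age"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
        assert res["estimate"] == pytest.approx(beta[1], abs=1e-10)

    def test_refuses_below_min_cases(self):
        df = pd.DataFrame({"y": np.arange(5.0), "x": np.arange(5.0), "age": np.arange(5.0)})
        with pytest.raises(ValueError, match="complete cases"):
            st.adjusted_association(df, "y", "x")

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            df = pd.DataFrame(
                {
                    "y": rng.normal(size=40),
                    "x": rng.normal(size=40),
                    "age": rng.normal(size=40),
                }
            )
            rejections += st.adjusted_association(df, "y", "x")["p"] < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)
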