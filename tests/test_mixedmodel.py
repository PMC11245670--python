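"""Mixed-model fitting, stepwise selection, variance-explained, LOOCV."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from lrspipe import mixedmodel


def simulate_3level(rng, n_farms=20, per_farm=40, beta_thi=0.0,
                    farm_sd=100.0, dam_sd=60.0, resid_sd=300.0,
                    extra_noise_cols=0):
    n = n_farms * per_farm
    farm = np.repeat([f"F{i:02d}" for i in range(n_farms)], per_farm)
    dam_idx = np.repeat(np.arange(n_farms), per_farm) * 1000 \
        + rng.integers(0, per_farm // 2, n)
    thi = rng.normal(55.0, 3.0, n)
    farm_eff = dict(zip(np.unique(farm), rng.normal(0, farm_sd, n_farms)))
    dams = np.unique(dam_idx)
    dam_eff = dict(zip(dams, rng.normal(0, dam_sd, len(dams))))
    y = (1500.0 + beta_thi * (thi - 55.0)
         + np.array([farm_eff[f] for f in farm])
         + np.array([dam_eff[d] for d in dam_idx])
         + rng.normal(0, resid_sd, n))
    df = pd.DataFrame({"outcome_lrs": y, "mean_thi_t3": thi,
                       "farm_id": farm, "dam_id": dam_idx})
    for k in range(extra_noise_cols):
        df[f"noise{k}"] = rng.normal(0, 1, n)
    return df


class TestFitLmm:
    def test_zero_variance_components_recovered_near_zero(self):
        rng = np.random.default_rng(1)
        df = simulate_3level(rng, farm_sd=0.0, dam_sd=0.0, resid_sd=300.0)
        fit = mixedmodel.fit_lmm(df, "outcome_lrs", ["mean_thi_t3"])
        vc = fit.variance_components
        total = sum(vc.values())
        # null components collapse to a small share of the total variance
        assert vc["farm"] / total < 0.05
        assert vc["dam"] / total < 0.10
        assert vc["resid"] ** 0.5 == pytest.approx(300.0, rel=0.1)

    def test_reduces_to_ols_when_no_group_structure(self):
        rng = np.random.default_rng(2)
        df = simulate_3level(rng, farm_sd=0.0, dam_sd=0.0, resid_sd=100.0,
                             beta_thi=-4.0)
        fit = mixedmodel.fit_lmm(df, "outcome_lrs", ["mean_thi_t3"],
                                 grouping=("dam_id",))
        import statsmodels.formula.api as smf
        ols = smf.ols("outcome_lrs ~ mean_thi_t3", df).fit()
        assert fit.params["mean_thi_t3"] == pytest.approx(
            ols.params["mean_thi_t3"], abs=0.05)

    def test_matches_lme4_maximum_likelihood(self, tmp_path):
        """Independent oracle: identical ML fit from lme4 via Rscript."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(3)
        df = simulate_3level(rng, n_farms=15, per_farm=30, beta_thi=-5.0)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- lmer(outcome_lrs ~ mean_thi_t3 + (1|farm_id) + (1|dam_id),"
            "          data=d, REML=FALSE);"
            "cat(fixef(m)['mean_thi_t3'], as.numeric(logLik(m)),"
            "    sigma(m), sep='\\n')")
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True).stdout.split()
        r_beta, r_llf, r_sigma = map(float, out[-3:])
        fit = mixedmodel.fit_lmm(df, "outcome_lrs", ["mean_thi_t3"])
        assert fit.params["mean_thi_t3"] == pytest.approx(r_beta, abs=1e-2)
        assert fit.llf == pytest.approx(r_llf, abs=0.05)
        assert fit.variance_components["resid"] ** 0.5 == \
            pytest.approx(r_sigma, rel=1e-3)

    def test_categorical_term_gets_joint_wald_p(self):
        rng = np.random.default_rng(4)
        df = simulate_3level(rng)
        df["preg_cat"] = rng.choice(["2", "3", "4plus"], len(df))
        fit = mixedmodel.fit_lmm(df, "outcome_lrs", ["preg_cat"])
        assert "preg_cat" in fit.term_pvalues
        assert 0.0 <= fit.term_pvalues["preg_cat"] <= 1.0


class TestForwardSelect:
    def test_strong_predictor_selected_first(self):
        rng = np.random.default_rng(5)
        df = simulate_3level(rng, beta_thi=-30.0, extra_noise_cols=2)
        fit, trace = mixedmodel.forward_select(
            df, "outcome_lrs", ["noise0", "mean_thi_t3", "noise1"],
            continuous=[])
        entered = trace[trace["decision"] == "entered"]
        assert entered["candidate"].iloc[0] == "mean_thi_t3"
        assert fit.params["mean_thi_t3"] == pytest.approx(-30.0, abs=6.0)

    def test_empty_candidates_gives_intercept_only(self):
        rng = np.random.default_rng(6)
        df = simulate_3level(rng)
        fit, trace = mixedmodel.forward_select(df, "outcome_lrs", [])
        assert list(fit.params.index) == ["Intercept"]
        assert len(trace) == 0

    def test_subgroup_allows_single_member(self):
        rng = np.random.default_rng(7)
        df = simulate_3level(rng)
        x = rng.normal(0, 1, len(df))
        df["y_min"] = x + rng.normal(0, 0.2, len(df))
        df["y_max"] = x + rng.normal(0, 0.2, len(df))
        df["outcome_lrs"] += 80.0 * x
        fit, trace = mixedmodel.forward_select(
            df, "outcome_lrs", ["y_min", "y_max"],
            subgroups={"yield": ["y_min", "y_max"]}, continuous=[])
        assert sum(t in fit.terms for t in ("y_min", "y_max")) == 1
        assert (trace["decision"] == "withdrawn (subgroup)").sum() == 1

    def test_polynomial_term_detected(self):
        rng = np.random.default_rng(8)
        df = simulate_3level(rng, farm_sd=20.0, dam_sd=20.0, resid_sd=100.0)
        x = df["mean_thi_t3"] - 55.0
        df["outcome_lrs"] += -20.0 * x + 15.0 * x ** 2
        fit, trace = mixedmodel.forward_select(
            df, "outcome_lrs", ["mean_thi_t3"], continuous=["mean_thi_t3"])
        assert "I(mean_thi_t3 ** 2)" in fit.terms

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            mixedmodel.forward_select(pd.DataFrame(), "y", [], threshold=1.5)

    def test_trace_is_deterministic(self):
        rng = np.random.default_rng(9)
        df = simulate_3level(rng, beta_thi=-10.0, extra_noise_cols=1)
        _, t1 = mixedmodel.forward_select(df, "outcome_lrs",
                                          ["mean_thi_t3", "noise0"],
                                          continuous=[])
        _, t2 = mixedmodel.forward_select(df, "outcome_lrs",
                                          ["mean_thi_t3", "noise0"],
                                          continuous=[])
        pd.testing.assert_frame_equal(t1, t2)


class TestVarianceExplained:
    def test_null_fixed_effects_give_zero_marginal(self):
        rng = np.random.default_rng(10)
        df = simulate_3level(rng)
        fit = mixedmodel.fit_lmm(df, "outcome_lrs", [])
        marg, cond = mixedmodel.variance_explained(fit)
        assert marg == pytest.approx(0.0, abs=1e-12)
        assert cond >= marg

    def test_conditional_ge_marginal_always(self):
        rng = np.random.default_rng(11)
        for rep in range(3):
            df = simulate_3level(rng, beta_thi=rng.uniform(-20, 0))
            fit = mixedmodel.fit_lmm(df, "outcome_lrs", ["mean_thi_t3"])
            marg, cond = mixedmodel.variance_explained(fit)
            assert cond >= marg - 1e-12

    def test_known_variance_shares_recovered(self):
        rng = np.random.default_rng(12)
        df = simulate_3level(rng, n_farms=40, per_farm=60, beta_thi=-40.0,
                             farm_sd=100.0, dam_sd=80.0, resid_sd=200.0)
        fit = mixedmodel.fit_lmm(df, "outcome_lrs", ["mean_thi_t3"])
        marg, cond = mixedmodel.variance_explained(fit)
        var_fix = (40.0 * 3.0) ** 2
        denom = var_fix + 100.0 ** 2 + 80.0 ** 2 + 200.0 ** 2
        assert marg == pytest.approx(var_fix / denom, rel=0.15)
        assert cond == pytest.approx(
            (var_fix + 100.0 ** 2 + 80.0 ** 2) / denom, rel=0.15)


class TestLoocv:
    def test_fold_count_equals_group_count(self):
        rng = np.random.default_rng(13)
        df = simulate_3level(rng, n_farms=6, per_farm=25, beta_thi=-10.0)
        folds, pooled = mixedmodel.loocv_by_group(
            df, "outcome_lrs", ["mean_thi_t3"])
        assert len(folds) == 6
        assert set(pooled["group"]) == set(df["farm_id"])

    def test_identical_groups_give_identical_fold_estimates(self):
        rng = np.random.default_rng(14)
        base = simulate_3level(rng, n_farms=1, per_farm=40, beta_thi=-5.0,
                               farm_sd=0.0)
        clone = base.copy()
        clone["farm_id"] = "F99"
        clone["dam_id"] = clone["dam_id"] + 5_000_000
        df = pd.concat([base, clone], ignore_index=True)
        folds, _ = mixedmodel.loocv_by_group(df, "outcome_lrs", ["mean_thi_t3"])
        assert folds["rmse"].iloc[0] == pytest.approx(folds["rmse"].iloc[1],
                                                      rel=1e-6)

    def test_null_data_pooled_rmse_near_outcome_sd(self):
        rng = np.random.default_rng(15)
        df = simulate_3level(rng, n_farms=10, per_farm=50, beta_thi=0.0,
                             farm_sd=0.0, dam_sd=0.0, resid_sd=250.0)
        folds, pooled = mixedmodel.loocv_by_group(df, "outcome_lrs", [])
        rmse = np.sqrt(np.mean((pooled["observed"] - pooled["predicted"]) ** 2))
        assert rmse == pytest.approx(df["outcome_lrs"].std(), rel=0.1)

    def test_single_group_rejected(self):
        rng = np.random.default_rng(16)
        df = simulate_3level(rng, n_farms=1, per_farm=30)
        with pytest.raises(ValueError):
            mixedmodel.loocv_by_group(df, "outcome_lrs", [])


class TestSpearman:
    def test_identical_and_reversed_columns(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                           "b": [1.0, 2.0, 3.0, 4.0],
                           "c": [4.0, 3.0, 2.0, 1.0]})
        m = mixedmodel.spearman_matrix(df)
        assert m.loc["a", "b"] == pytest.approx(1.0)
        assert m.loc["a", "c"] == pytest.approx(-1.0)

    def test_hand_ranked_oracle(self):
        df = pd.DataFrame({"x": [10.0, 20.0, 30.0, 40.0, 50.0],
                           "y": [1.0, 3.0, 2.0, 5.0, 4.0]})
        # ranks of y: 1,3,2,5,4 against 1..5 -> rho = 1 - 6*sum(d^2)/(n^3-n)
        d2 = sum((a - b) ** 2 for a, b in zip([1, 2, 3, 4, 5], [1, 3, 2, 5, 4]))
        expected = 1 - 6 * d2 / (5 ** 3 - 5)
        m = mixedmodel.spearman_matrix(df)
        assert m.loc["x", "y"] == pytest.approx(expected)

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "k": [7.0, 7.0, 7.0]})
        m = mixedmodel.spearman_matrix(df)
        assert "k" in m.attrs["constant_columns"]
        assert np.isnan(m.loc["a", "k"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            mixedmodel.spearman_matrix(pd.DataFrame({"a": [1.0, 2.0]}))
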