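"""Cohort GLM: cluster-robust covariance, estimated means, contrasts,
diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from omiflim import GlmSpec, cluster_robust_cov, diagnostics, fit_glm


def _clustered_table(rng, n_larvae=10, cells=20, effect=1.0, larva_sd=0.2, cell_sd=0.3):
    rows = []
    for l in range(n_larvae):
        treat = "b" if l % 2 else "a"
        b_l = rng.normal(0, larva_sd)
        for c in range(cells):
            y = np.exp(np.log(1.0) + (np.log(effect) if treat == "b" else 0.0)
                       + b_l + rng.normal(0, cell_sd))
            rows.append({"y": y, "treatment": treat, "larva_id": f"L{l}", "day_id": "d0"})
    return pd.DataFrame(rows)


class TestFitGlm:
    def test_one_sample_reduces_to_t_interval(self):
        rng = np.random.default_rng(0)
        y = rng.normal(5.0, 2.0, 40)
        tab = pd.DataFrame({"y": y, "g": "only"})
        spec = GlmSpec(outcome="y", treatment="g", block=None, cluster=None)
        res = fit_glm(tab, spec)
        m = res.group_means.iloc[0]
        se = y.std(ddof=1) / np.sqrt(40)
        tcrit = sps.t.ppf(0.975, 39)
        assert m["mean"] == pytest.approx(y.mean(), rel=1e-10)
        assert m["ci_low"] == pytest.approx(y.mean() - tcrit * se, rel=1e-8)
        assert m["ci_high"] == pytest.approx(y.mean() + tcrit * se, rel=1e-8)

    def test_balanced_day_shift_leaves_contrast_unchanged(self):
        rng = np.random.default_rng(1)
        base = _clustered_table(rng, n_larvae=8, cells=10, effect=0.8)
        shifted = []
        for d, delta in enumerate((0.0, 0.5, -0.3)):
            part = base.copy()
            part["y"] = part["y"] + delta
            part["day_id"] = f"d{d}"
            part["larva_id"] = part["larva_id"] + f"-{d}"
            shifted.append(part)
        tab = pd.concat(shifted, ignore_index=True)
        spec = GlmSpec(outcome="y", treatment="treatment", block="day_id", cluster="larva_id")
        res_block = fit_glm(tab, spec)
        flat = pd.concat([base] * 3, ignore_index=True)
        flat["larva_id"] = tab["larva_id"]
        flat["day_id"] = "d0"
        res_flat = fit_glm(flat, GlmSpec(outcome="y", treatment="treatment",
                                         block="day_id", cluster="larva_id"))
        a = res_block.contrasts.iloc[0]["estimate"]
        b = res_flat.contrasts.iloc[0]["estimate"]
        assert a == pytest.approx(b, rel=1e-10)

    def test_log_transform_reports_ordered_positive_ratio_ci(self):
        rng = np.random.default_rng(2)
        tab = _clustered_table(rng, effect=0.85)
        spec = GlmSpec(outcome="y", treatment="treatment", block=None,
                       cluster="larva_id", log_transform=True)
        res = fit_glm(tab, spec)
        c = res.contrasts.iloc[0]
        assert c["type"] == "ratio"
        assert 0 < c["ci_low"] < c["estimate"] < c["ci_high"]
        assert np.all(res.group_means["mean"] > 0)

    def test_interaction_included_for_two_factors(self):
        rng = np.random.default_rng(3)
        tab = _clustered_table(rng, n_larvae=16, cells=8)
        tab["time"] = np.where(np.arange(len(tab)) % 2 == 0, "t24", "t72")
        spec = GlmSpec(outcome="y", treatment=("treatment", "time"), block=None,
                       cluster="larva_id", interaction=True)
        res = fit_glm(tab, spec)
        assert any(":" in name for name in res.params.index)
        assert len(res.group_means) == 4

    def test_rank_deficient_design_names_aliased_terms(self):
        tab = pd.DataFrame(
            {"y": np.arange(8.0), "treatment": ["a"] * 4 + ["b"] * 4,
             "day_id": ["d0"] * 4 + ["d1"] * 4,  # perfectly confounded with treatment
             "larva_id": ["L0", "L1"] * 4}
        )
        with pytest.raises(ValueError, match="aliased"):
            fit_glm(tab, GlmSpec(outcome="y"))

    def test_nonpositive_outcome_under_log_rejected(self):
        tab = _clustered_table(np.random.default_rng(4))
        tab.loc[0, "y"] = 0.0
        with pytest.raises(ValueError, match="nonpositive"):
            fit_glm(tab, GlmSpec(outcome="y", block=None, log_transform=True))

    def test_missing_column_rejected(self):
        tab = _clustered_table(np.random.default_rng(5))
        with pytest.raises(ValueError, match="genotype"):
            fit_glm(tab, GlmSpec(outcome="y", treatment="genotype", block=None))


class TestClusterRobustCov:
    def test_singleton_clusters_equal_hc1(self):
        rng = np.random.default_rng(6)
        n = 60
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(size=n) * (1 + 0.5 * np.abs(x))
        X = sm.add_constant(x)
        fit = sm.OLS(y, X).fit()
        V = cluster_robust_cov(fit, np.arange(n))
        V_hc1 = fit.get_robustcov_results(cov_type="HC1").cov_params()
        assert np.allclose(V, V_hc1, rtol=1e-10)

    def test_matches_statsmodels_cluster_covariance(self):
        rng = np.random.default_rng(7)
        tab = _clustered_table(rng)
        model = smf.ols("y ~ C(treatment)", data=tab)
        fit = model.fit()
        V_own = cluster_robust_cov(fit, tab["larva_id"].to_numpy())
        V_sm = model.fit(
            cov_type="cluster",
            cov_kwds={"groups": pd.Categorical(tab["larva_id"]).codes},
        ).cov_params()
        assert np.allclose(V_own, np.asarray(V_sm), rtol=1e-8)

    def test_robust_se_exceeds_classical_under_clustering(self):
        wins = 0
        n_sims = 40
        for s in range(n_sims):
            rng = np.random.default_rng(100 + s)
            # ICC 0.5: larva and cell variance equal
            tab = _clustered_table(rng, n_larvae=12, cells=15, larva_sd=0.3, cell_sd=0.3)
            model = smf.ols("y ~ C(treatment)", data=tab)
            fit = model.fit()
            V = cluster_robust_cov(fit, tab["larva_id"].to_numpy())
            if np.sqrt(V[1, 1]) > fit.bse.iloc[1]:
                wins += 1
        assert wins >= 0.9 * n_sims

    def test_single_cluster_rejected(self):
        fit = sm.OLS(np.arange(4.0), np.ones((4, 1))).fit()
        with pytest.raises(ValueError, match="clusters"):
            cluster_robust_cov(fit, np.zeros(4))


class TestDiagnostics:
    def _result(self, y, x):
        tab = pd.DataFrame({"y": y, "treatment": x})
        return fit_glm(tab, GlmSpec(outcome="y", block=None, cluster=None))

    def test_gaussian_residuals_not_flagged(self):
        rng = np.random.default_rng(8)
        x = np.repeat(["a", "b"], 100)
        y = np.where(x == "b", 2.0, 1.0) + rng.normal(0, 0.1, 200)
        rep = diagnostics(self._result(y, x))
        assert not rep.heteroskedastic

    def test_variance_proportional_to_mean_squared_flagged(self):
        rng = np.random.default_rng(9)
        x = np.repeat(["a", "b"], 100)
        mu = np.where(x == "b", 10.0, 1.0)
        y = mu + rng.normal(0, 1, 200) * mu * 0.3
        rep = diagnostics(self._result(y, x))
        assert rep.heteroskedastic

    def test_residuals_sum_to_zero_with_intercept(self):
        rng = np.random.default_rng(10)
        x = np.repeat(["a", "b"], 50)
        y = rng.normal(5, 1, 100)
        res = self._result(y, x)
        assert abs(res.residuals.sum()) < 1e-8 * np.abs(y).sum()

    def test_tables_are_plot_ready(self):
        rng = np.random.default_rng(11)
        res = self._result(rng.normal(size=60), np.repeat(["a", "b"], 30))
        rep = diagnostics(res)
        assert set(rep.resid_vs_fitted.columns) == {"fitted", "residual"}
        assert len(rep.normal_quantiles) == 60
        assert rep.normal_quantiles["sample_quantile"].is_monotonic_increasing
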