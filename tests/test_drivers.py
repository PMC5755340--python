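import numpy as np
import pandas as pd
import pytest

from stepsel.drivers import (
    all_subsets_aicc,
    build_design,
    displacement_hr_correlation,
    fit_lmm,
    group_importance,
    marginal_variance_explained,
)
from stepsel.simulate import simulate_hr_dataset


@pytest.fixture(scope="module")
def cohort():
    effects = {
        "l_mean": 0.003,
        "beta_cos": 1.0,
        "sex:male": 0.7,
        "season:spring": -0.25,
        "season:summer": -0.4,
        "season:winter": -0.45,
    }
    return simulate_hr_dataset(
        40, true_fixed_effects=effects, random_intercept_sd=0.3,
        residual_sd=0.3, seed=17,
    ), effects


class TestFitLmm:
    def test_zero_random_variance_equals_ols(self):
        df = simulate_hr_dataset(
            20, true_fixed_effects={"l_mean": 0.002}, random_intercept_sd=0.0,
            residual_sd=0.4, seed=2,
        )
        fit = fit_lmm(df, ["l_mean", "sex"])
        X, _ = build_design(df.sort_values("animal"), ["l_mean", "sex"])
        y = df.sort_values("animal")["log_area"].to_numpy()
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        if fit.boundary:
            assert np.allclose(fit.coef.to_numpy(), ols, atol=1e-6)
        else:  # estimated lambda tiny: still effectively OLS
            assert fit.sigma_b2 < 0.02
            assert np.allclose(fit.coef.to_numpy(), ols, atol=1e-2)

    def test_profiled_ml_matches_2d_grid_oracle(self, cohort):
        """Brute-force maximization over (log-lambda, implied sigma_e^2) agrees
        with the scalar profile optimizer to 1e-4 in log-likelihood."""
        df, _ = cohort
        toy = df.iloc[:48]
        fit = fit_lmm(toy, ["l_mean", "sex"])
        from stepsel.drivers import _profile_loglik

        d = toy.sort_values("animal")
        X, _ = build_design(d, ["l_mean", "sex"])
        y = d["log_area"].to_numpy()
        sizes = d.groupby("animal", sort=False).size().to_numpy()
        grid = np.concatenate([[0.0], np.exp(np.linspace(-10, 6, 3000))])
        lls = [_profile_loglik(X, y, sizes, lam)[0] for lam in grid]
        assert fit.loglik == pytest.approx(max(lls), abs=1e-4)
        assert fit.loglik >= max(lls) - 1e-6

    def test_matches_statsmodels_mixedlm(self, cohort):
        import statsmodels.formula.api as smf

        df, _ = cohort
        ref = smf.mixedlm(
            "log_area ~ l_mean + C(sex)", df, groups=df["animal"]
        ).fit(reml=False, method="lbfgs")
        fit = fit_lmm(df, ["l_mean", "sex"])
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-3)
        assert fit.coef["l_mean"] == pytest.approx(ref.params["l_mean"], rel=1e-3)
        assert fit.coef["sex[male]"] == pytest.approx(
            ref.params["C(sex)[T.male]"], rel=1e-3
        )
        assert fit.sigma_e2 == pytest.approx(ref.scale, rel=5e-3)

    def test_reml_matches_statsmodels(self, cohort):
        import statsmodels.formula.api as smf

        df, _ = cohort
        ref = smf.mixedlm(
            "log_area ~ l_mean + C(sex)", df, groups=df["animal"]
        ).fit(reml=True, method="powell")
        fit = fit_lmm(df, ["l_mean", "sex"], reml=True)
        assert fit.coef["l_mean"] == pytest.approx(ref.params["l_mean"], rel=1e-3)
        assert fit.sigma_e2 == pytest.approx(ref.scale, rel=1e-2)
        assert fit.sigma_b2 == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=1e-2, abs=1e-4
        )

    def test_balanced_anova_closed_form(self):
        """Balanced one-way layout: ML variance components have classical
        closed forms from the between/within mean squares."""
        rng = np.random.default_rng(33)
        n_groups, m = 30, 6
        b = rng.normal(0, 0.5, n_groups)
        y = (b[:, None] + rng.normal(0, 0.3, (n_groups, m))).ravel()
        df = pd.DataFrame(
            {"animal": np.repeat([f"g{i}" for i in range(n_groups)], m),
             "log_area": y}
        )
        fit = fit_lmm(df, [])
        grand = y.mean()
        gmeans = y.reshape(n_groups, m).mean(axis=1)
        ssw = ((y.reshape(n_groups, m) - gmeans[:, None]) ** 2).sum()
        sigma_e2 = ssw / (n_groups * (m - 1))
        # ML between-variance: mean squared group deviation minus sigma_e2/m
        sigma_b2 = ((gmeans - grand) ** 2).mean() - sigma_e2 / m
        assert fit.sigma_e2 == pytest.approx(sigma_e2, rel=0.02)
        assert fit.sigma_b2 == pytest.approx(sigma_b2, rel=0.05)

    def test_recovers_generating_parameters(self):
        """Over replicated cohorts the estimates match the truth within
        Monte-Carlo error."""
        truth = {"l_mean": 0.003, "sex:male": 0.7}
        est = {"l_mean": [], "sex[male]": [], "sb2": [], "se2": []}
        for r in range(40):
            df = simulate_hr_dataset(
                40, true_fixed_effects=truth, random_intercept_sd=0.3,
                residual_sd=0.3, seed=700 + r,
            )
            fit = fit_lmm(df, ["l_mean", "sex"])
            est["l_mean"].append(fit.coef["l_mean"])
            est["sex[male]"].append(fit.coef["sex[male]"])
            est["sb2"].append(fit.sigma_b2)
            est["se2"].append(fit.sigma_e2)
        for key, true_val in [("l_mean", 0.003), ("sex[male]", 0.7),
                              ("sb2", 0.09), ("se2", 0.09)]:
            vals = np.asarray(est[key])
            mc_se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - true_val) <= 2 * mc_se + 1e-3

    def test_collinear_predictors_rejected(self, cohort):
        df, _ = cohort
        df = df.assign(l_mean_copy=df["l_mean"])
        from stepsel.drivers import DEFAULT_GROUPS

        with pytest.raises(ValueError, match="collinear"):
            fit_lmm(df, ["l_mean", "l_mean_copy"])

    def test_aicc_approaches_aic_for_large_n(self):
        df = simulate_hr_dataset(100, seed=5)
        fit = fit_lmm(df, ["l_mean"])
        assert fit.aicc - fit.aic < 0.2
        small = fit_lmm(df.iloc[:24], ["l_mean"])
        assert small.aicc - small.aic > fit.aicc - fit.aic


class TestModelSelection:
    def test_strong_groups_selected(self, cohort):
        df, _ = cohort
        _, best, _ = all_subsets_aicc(df)
        assert "movement" in best.groups
        assert "sex" in best.groups
        assert "season" in best.groups

    def test_ranking_table_sorted_and_deterministic(self, cohort):
        df, _ = cohort
        t1, _, _ = all_subsets_aicc(df)
        t2, _, _ = all_subsets_aicc(df)
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1["aicc"].diff().dropna() >= -1e-9).all()
        assert t1["delta_aicc"].iloc[0] == 0.0

    def test_group_importance_ranks_dominant_driver(self, cohort):
        df, _ = cohort
        _, best, _ = all_subsets_aicc(df)
        imp = group_importance(df, best)
        assert imp["delta_aicc"].iloc[0] > 0
        top = imp["group"].iloc[0]
        assert top in {"movement", "sex", "season"}
        missing = imp.loc[~imp["in_best"], "delta_aicc"]
        assert missing.isna().all()


class TestVarianceExplained:
    def test_null_fixed_effects_give_zero(self):
        df = simulate_hr_dataset(20, seed=8)
        fit = fit_lmm(df, [])
        assert marginal_variance_explained(fit) == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_limit_is_one(self):
        df = simulate_hr_dataset(
            20, true_fixed_effects={"l_mean": 0.01}, random_intercept_sd=0.0,
            residual_sd=1e-6, seed=9,
        )
        fit = fit_lmm(df, ["l_mean"])
        assert marginal_variance_explained(fit) > 0.999

    def test_recovers_known_variance_partition(self):
        """Fixed 60% / intercept 20% / residual 20% at n = 160 rows."""
        df = simulate_hr_dataset(
            40, true_fixed_effects={"l_mean": np.sqrt(0.6) / np.sqrt(1 / 12) / 500},
            random_intercept_sd=np.sqrt(0.2), residual_sd=np.sqrt(0.2), seed=10,
        )
        # var(l_mean) = (600-100)^2/12; coefficient chosen so var(fixed) = 0.6
        fit = fit_lmm(df, ["l_mean"])
        assert marginal_variance_explained(fit) == pytest.approx(0.6, abs=0.05)


class TestDisplacementCorrelation:
    def _tables(self, disp, areas):
        d = pd.DataFrame(
            {"animal_id": "a1", "season": [f"s{k}" for k in range(len(disp))],
             "displacement": disp}
        )
        h = pd.DataFrame(
            {"animal_id": "a1", "season": [f"s{k}" for k in range(len(areas))],
             "area90": areas}
        )
        return d, h

    def test_proportional_pairs_give_r_one(self):
        disp = np.array([300.0, 600.0, 1200.0, 2400.0])
        d, h = self._tables(disp, (disp / 100.0) ** 2)
        r, p = displacement_hr_correlation(d, h)
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_error(self):
        d, h = self._tables([300.0, 400.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            displacement_hr_correlation(d, h)

    def test_independent_pairs_small_r(self):
        rng = np.random.default_rng(12)
        rs = []
        for _ in range(50):
            d, h = self._tables(rng.lognormal(6, 0.5, 30), rng.lognormal(0, 0.5, 30))
            r, _ = displacement_hr_correlation(d, h)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.1
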