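import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from scipy.special import digamma

from conftest import clogit_brute_force, simulate_strata
from stepsel.issa import (
    DEFAULT_TERMS,
    MOVEMENT_TERMS,
    build_strata,
    fit_conditional_logit,
    fit_gamma,
    habitat_importance,
    null_loglik,
    sample_available,
    screen_collinearity,
    standardize_strata,
    update_movement_kernel,
)
from stepsel.simulate import SimulationScenario, simulate_track
from stepsel.tracks import build_steps, regularize


# ---------------------------------------------------------------------------
# gamma availability fit
# ---------------------------------------------------------------------------

class TestGammaFit:
    def test_ml_score_equations_hold(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(1.7, 250.0, size=500)
        fit = fit_gamma(x)
        m, g = x.mean(), np.log(x).mean()
        assert abs(np.log(fit.shape) - digamma(fit.shape) - (np.log(m) - g)) < 1e-8
        assert fit.scale == pytest.approx(m / fit.shape, abs=1e-8)

    def test_recovers_parameters_at_large_n(self):
        rng = np.random.default_rng(123)
        fit = fit_gamma(rng.gamma(2.0, 300.0, size=10_000))
        assert 1.9 <= fit.shape <= 2.1
        assert 285.0 <= fit.scale <= 315.0

    def test_exponential_special_case(self):
        rng = np.random.default_rng(5)
        fit = fit_gamma(rng.exponential(200.0, size=5_000))
        assert fit.shape == pytest.approx(1.0, abs=0.05)

    def test_matches_generic_optimizer(self):
        rng = np.random.default_rng(7)
        x = rng.gamma(3.0, 100.0, size=400)
        fit = fit_gamma(x)

        def nll(p):
            return -stats.gamma.logpdf(x, p[0], scale=p[1]).sum()

        res = optimize.minimize(nll, [1.0, x.mean()], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10})
        assert fit.shape == pytest.approx(res.x[0], rel=1e-4)
        assert fit.scale == pytest.approx(res.x[1], rel=1e-4)

    def test_zero_lengths_replaced_not_dropped(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.gamma(2.0, 300.0, size=100), [0.0, 0.0]])
        fit = fit_gamma(x)
        assert fit.n == 102

    def test_degenerate_data_raises(self):
        with pytest.raises(ValueError, match="identical"):
            fit_gamma(np.full(50, 123.0))
        with pytest.raises(ValueError):
            fit_gamma([1.0, 2.0])  # too few


# ---------------------------------------------------------------------------
# availability sampling / covariate extraction / collinearity
# ---------------------------------------------------------------------------

def _steps_fixture(landscape, seed=21, n=120):
    scen = SimulationScenario(selection={}, n_fixes=n, start_xy=(6000, 6000), seed=seed)
    return build_steps(regularize(simulate_track(landscape, scen), 4.0))


class TestSampling:
    def test_stratum_has_n_plus_one_alternatives(self, landscape):
        steps = _steps_fixture(landscape)
        gf = fit_gamma(steps["length"])
        alts = sample_available(steps, gf, n_available=10, seed=1)
        sizes = alts.groupby("stratum").size()
        assert (sizes == 11).all()
        assert (alts.groupby("stratum")["used"].sum() == 1).all()

    def test_alternatives_share_start_point(self, landscape):
        steps = _steps_fixture(landscape)
        gf = fit_gamma(steps["length"])
        alts = sample_available(steps, gf, n_available=5, seed=1)
        assert (alts.groupby("stratum")["x1"].nunique() == 1).all()

    def test_seeded_sampling_is_deterministic(self, landscape):
        steps = _steps_fixture(landscape)
        gf = fit_gamma(steps["length"])
        a = sample_available(steps, gf, n_available=10, seed=42)
        b = sample_available(steps, gf, n_available=10, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_available_turn_angles_uniform(self, landscape):
        """Sampled turn angles pass a uniformity KS test at alpha = 0.01 in
        >= 95% of replicates (test level implies ~99%)."""
        steps = _steps_fixture(landscape, n=100)
        gf = fit_gamma(steps["length"])
        n_pass = 0
        for r in range(40):
            alts = sample_available(steps, gf, n_available=10, seed=100 + r)
            ta = alts.loc[alts["used"] == 0, "turn_angle"].to_numpy()
            p = stats.kstest(ta, "uniform", args=(-np.pi, 2 * np.pi)).pvalue
            n_pass += p > 0.01
        assert n_pass >= 38

    def test_invalid_n_available(self, landscape):
        steps = _steps_fixture(landscape)
        gf = fit_gamma(steps["length"])
        with pytest.raises(ValueError):
            sample_available(steps, gf, n_available=0)


class TestStrataConstruction:
    def test_off_raster_available_dropped_stratum_kept(self, landscape):
        """A start point near the landscape edge loses some available steps but
        the stratum survives while one available alternative remains."""
        scen = SimulationScenario(selection={}, n_fixes=200, seed=3,
                                  start_xy=(600.0, 600.0), scale=300.0)
        steps = build_steps(regularize(simulate_track(landscape, scen), 4.0))
        strata, gf = build_strata(steps, landscape, n_available=10, seed=4)
        sizes = strata.groupby("stratum").size()
        assert sizes.min() >= 2
        assert (strata.groupby("stratum")["used"].sum() == 1).all()
        assert not strata[["slope_raw", "heat_raw", "ndvi_raw"]].isna().any().any()

    def test_standardization_reference_is_all_alternatives(self, landscape):
        steps = _steps_fixture(landscape)
        strata, _ = build_strata(steps, landscape, seed=5)
        std, scaling = standardize_strata(strata)
        for v in ("slope", "heat", "ndvi"):
            assert std[v].mean() == pytest.approx(0.0, abs=1e-10)
            assert std[v].std(ddof=1) == pytest.approx(1.0, rel=1e-10)
            assert np.allclose(std[v + "2"], std[v] ** 2)

    def test_collinearity_screen(self, landscape):
        steps = _steps_fixture(landscape)
        strata, _ = build_strata(steps, landscape, seed=6)
        report = screen_collinearity(strata)
        assert set(report.columns) >= {"var_a", "var_b", "r", "flagged"}
        dup = strata.assign(slope2_raw=strata["slope_raw"])
        rep2 = screen_collinearity(dup, variables=("slope", "slope2", "heat"))
        row = rep2.loc[(rep2["var_a"] == "slope") & (rep2["var_b"] == "slope2")]
        assert row["r"].iloc[0] == pytest.approx(1.0)
        assert bool(row["flagged"].iloc[0])

    def test_independent_covariates_not_flagged(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {
                "stratum": np.repeat(np.arange(200), 5),
                "slope": rng.standard_normal(1000),
                "heat": rng.standard_normal(1000),
                "ndvi": rng.standard_normal(1000),
            }
        )
        rep = screen_collinearity(df)
        assert (rep["r"].abs() < 0.70).all()
        assert not rep["flagged"].any()

    def test_zero_variance_covariate_flagged(self):
        df = pd.DataFrame(
            {
                "stratum": np.repeat(np.arange(10), 3),
                "slope": 1.0,
                "heat": np.arange(30, dtype=float),
                "ndvi": np.arange(30, dtype=float) ** 2,
            }
        )
        rep = screen_collinearity(df)
        assert rep.loc[rep["var_a"] == "slope", "flagged"].all()


# ---------------------------------------------------------------------------
# conditional logistic regression
# ---------------------------------------------------------------------------

class TestConditionalLogit:
    def test_null_loglik_closed_form(self):
        strata = simulate_strata(50, {}, n_available=10, seed=1)
        fit = fit_conditional_logit(strata, terms=("slope",), max_iter=0)
        assert null_loglik([11] * 50) == pytest.approx(-50 * np.log(11))
        # beta stays ~0 under a null design, so logL ~ the closed form
        assert fit.loglik <= -50 * np.log(11) + 1e-9

    @pytest.mark.parametrize("idx,n_cov", [(i, c) for c in (1, 2) for i in range(3)])
    def test_matches_brute_force_on_small_instances(self, idx, n_cov):
        from conftest import toy_clogit_instance

        strata, terms = toy_clogit_instance(idx, n_covariates=n_cov)
        fit = fit_conditional_logit(strata, terms=tuple(terms))
        b_ref, ll_ref = clogit_brute_force(strata, terms)
        assert np.allclose(fit.coef.to_numpy(), b_ref, atol=1e-6)
        assert fit.loglik >= ll_ref - 1e-9

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        strata = simulate_strata(300, {"slope": 0.5, "ndvi": -0.7}, seed=3)
        fit = fit_conditional_logit(strata, terms=("slope", "ndvi"))
        ref = sm.ConditionalLogit(
            strata["used"], strata[["slope", "ndvi"]], groups=strata["stratum"]
        ).fit(disp=False)
        assert np.allclose(fit.coef.to_numpy(), ref.params, atol=5e-4)
        assert np.allclose(fit.se.to_numpy(), ref.bse, atol=1e-3)
        # the Newton fit must do at least as well as the reference optimizer
        assert fit.loglik >= ref.llf - 1e-8
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_invariant_to_within_stratum_constant_shift(self):
        strata = simulate_strata(100, {"heat": -0.6}, seed=4)
        fit1 = fit_conditional_logit(strata, terms=("heat",))
        shifted = strata.copy()
        shifted["heat"] = shifted["heat"] + shifted["stratum"] * 3.7
        fit2 = fit_conditional_logit(shifted, terms=("heat",))
        assert fit2.coef["heat"] == pytest.approx(fit1.coef["heat"], abs=1e-7)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-7)

    def test_bias_shrinks_with_strata_count(self):
        beta = {"slope": 0.5, "heat": -0.5}
        errs = {}
        for S in (500, 5000):
            e = []
            for r in range(3):
                strata = simulate_strata(S, beta, seed=10 * S + r)
                fit = fit_conditional_logit(strata, terms=("slope", "heat"))
                e.append(np.abs(fit.coef.to_numpy() - [0.5, -0.5]).mean())
            errs[S] = np.mean(e)
        assert errs[5000] < errs[500]

    def test_rank_deficiency_names_terms(self):
        strata = simulate_strata(20, {"slope": 0.3}, seed=6)
        strata["slope2"] = 2.0 * strata["slope"]
        with pytest.raises(ValueError, match="slope"):
            fit_conditional_logit(strata, terms=("slope", "slope2"))

    def test_separation_flagged(self):
        strata = simulate_strata(30, {}, n_available=3, seed=7)
        # covariate that perfectly identifies the used alternative; the small
        # scale pushes the diverging estimate far past the |50| guard
        strata["slope"] = 0.1 * strata["used"].astype(float)
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_conditional_logit(strata, terms=("slope",))
        assert "non-identifiable" in fit.flags

    def test_wald_coverage_near_nominal(self):
        """95% Wald intervals cover the truth at about the nominal rate."""
        beta = {"slope": 0.4, "ndvi": -0.6}
        hits, tot = 0, 0
        for r in range(60):
            strata = simulate_strata(400, beta, seed=900 + r)
            fit = fit_conditional_logit(strata, terms=("slope", "ndvi"))
            for term, b in beta.items():
                lo = fit.coef[term] - 1.96 * fit.se[term]
                hi = fit.coef[term] + 1.96 * fit.se[term]
                hits += lo <= b <= hi
                tot += 1
        assert 0.90 <= hits / tot <= 0.99


# ---------------------------------------------------------------------------
# movement-kernel update and habitat importance
# ---------------------------------------------------------------------------

class TestKernelUpdate:
    def test_null_coefficients_give_gamma_mean(self):
        from stepsel.issa import GammaFit

        gf = GammaFit(shape=2.0, scale=300.0, loglik=0.0, n=100)
        coef = pd.Series({"length": 0.0, "log_l": 0.0, "cos_ta": 0.3})
        k = update_movement_kernel(gf, coef)
        assert k.l_mean == pytest.approx(600.0)
        assert k.kappa == 0.3

    def test_direct_formula_arithmetic(self):
        from stepsel.issa import GammaFit

        gf = GammaFit(shape=2.0, scale=100.0, loglik=0.0, n=100)
        coef = pd.Series({"length": 0.001, "log_l": 0.5, "cos_ta": 0.0})
        k = update_movement_kernel(gf, coef)
        assert k.l_mean == pytest.approx(2.5 / 0.009)

    def test_negative_rate_flagged_undefined(self):
        from stepsel.issa import GammaFit

        gf = GammaFit(shape=2.0, scale=100.0, loglik=0.0, n=100)
        coef = pd.Series({"length": 0.02, "log_l": 0.0, "cos_ta": 0.0})
        k = update_movement_kernel(gf, coef)
        assert not k.defined
        assert k.l_mean is None


class TestHabitatImportance:
    def test_identical_models_give_zero_delta(self):
        strata = simulate_strata(100, {"cos_ta": 0.5}, seed=12)
        a = fit_conditional_logit(strata, terms=MOVEMENT_TERMS)
        b = fit_conditional_logit(strata, terms=MOVEMENT_TERMS)
        assert a.aic - b.aic == pytest.approx(0.0, abs=1e-9)

    def test_strong_selection_flagged_important(self):
        strata = simulate_strata(
            400, {"cos_ta": 0.5, "slope": 0.6, "ndvi": 0.5}, seed=13
        )
        imp = habitat_importance(strata)
        assert imp["habitat_important"]
        assert imp["delta_aic"] > 2

    def test_null_selection_rarely_important(self):
        flags = 0
        for r in range(25):
            strata = simulate_strata(300, {"cos_ta": 0.5}, seed=400 + r)
            flags += habitat_importance(strata)["habitat_important"]
        assert flags <= 5  # chi-square(6) tail: ~3% expected
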