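"""Simulation studies validating the estimators against their ground truth.

These routines generate data with known parameters through the package's own
simulator (or directly from the matched-choice model), refit them with the
estimators, and summarize recovery. They back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .drivers import fit_lmm
from .homerange import h_ref, isopleth, kernel_ud
from .issa import (
    DEFAULT_TERMS,
    child_seed,
    fit_conditional_logit,
    fit_issa,
    habitat_importance,
)
from .landscape import SeasonalityParams, generate_landscape
from .simulate import SimulationScenario, simulate_hr_dataset, simulate_track
from .tracks import build_steps, regularize

__all__ = [
    "recovery_landscape",
    "RECOVERY_SELECTION",
    "issa_recovery_study",
    "movement_constraint_study",
    "choice_strata",
    "habitat_importance_rate",
    "kde_isopleth_relative_error",
    "lmm_recovery_study",
]

#: raw-scale selection coefficients of the standard recovery scenario
RECOVERY_SELECTION = {
    "slope": 0.04, "heat": -1.2, "heat2": -0.8, "ndvi": 2.0, "ndvi2": -1.2,
}
RECOVERY_KAPPA = 0.7
RECOVERY_GAMMA = (2.0, 150.0)  # proposal shape, scale (m)


def recovery_landscape(seed: int = 9):
    """Patchy landscape for parameter-recovery studies: a weak altitudinal ramp
    under strong short-range relief, so every habitat covariate varies at the
    step scale and standardized effects are well identified."""
    p = SeasonalityParams(
        altitude_min=2200, altitude_max=2500, relief_corr_cells=2.5, relief_sd=300.0
    )
    return generate_landscape((120, 120), 100.0, p, seed=seed)


def _true_standardized(selection, scaling, kappa, gamma_true, gamma_hat):
    """Map raw-scale simulation truth onto each fit's coefficient scale.

    For a habitat variable with raw coefficients (b1, b2) and standardization
    (mu, sd), exp(b1 v + b2 v^2) in terms of z = (v - mu)/sd has linear
    coefficient sd (b1 + 2 b2 mu) and quadratic coefficient b2 sd^2. The
    movement truths correct the fitted availability gamma toward the true
    proposal: beta_ln(l) = k_true - k_hat, beta_l = 1/theta_hat - 1/theta_true.
    """
    truth = {}
    for v in ("slope", "heat", "ndvi"):
        b1 = selection.get(v, 0.0)
        b2 = selection.get(v + "2", 0.0)
        mu, sd = scaling[v]
        truth[v] = sd * (b1 + 2.0 * b2 * mu)
        truth[v + "2"] = b2 * sd * sd
    truth["cos_ta"] = kappa
    k_true, theta_true = gamma_true
    truth["log_l"] = k_true - gamma_hat.shape
    truth["length"] = 1.0 / gamma_hat.scale - 1.0 / theta_true
    return truth


def issa_recovery_study(
    n_fits: int = 30,
    n_steps: int = 1500,
    candidate_set_size: int = 50,
    seed: int = 0,
    selection: dict | None = None,
) -> pd.DataFrame:
    """Simulate ``n_fits`` animal-season tracks under known coefficients and
    refit each with iSSA. Returns one row per (fit, coefficient) with the
    estimate, its Wald SE and the truth on the fit's own scale."""
    land = recovery_landscape(seed=9)
    sel = RECOVERY_SELECTION if selection is None else selection
    k, theta = RECOVERY_GAMMA
    rows = []
    for r in range(n_fits):
        scen = SimulationScenario(
            selection=sel, shape=k, scale=theta, kappa=RECOVERY_KAPPA,
            n_fixes=n_steps + 1, start_xy=(6000.0, 6000.0),
            candidate_set_size=candidate_set_size,
            seed=child_seed(seed, "recovery-track", r),
        )
        steps = build_steps(regularize(simulate_track(land, scen), 4.0))
        fit = fit_issa(steps, land, n_available=10,
                       seed=child_seed(seed, "recovery-fit", r),
                       compare_habitat=False)
        truth = _true_standardized(sel, fit.scaling, RECOVERY_KAPPA,
                                   RECOVERY_GAMMA, fit.gamma)
        for term in DEFAULT_TERMS:
            rows.append(
                {
                    "replicate": r,
                    "term": term,
                    "estimate": float(fit.coef[term]),
                    "se": float(fit.se[term]),
                    "truth": truth[term],
                }
            )
    df = pd.DataFrame(rows)
    df["error"] = df["estimate"] - df["truth"]
    df["covered"] = (
        (df["estimate"] - 1.96 * df["se"] <= df["truth"])
        & (df["truth"] <= df["estimate"] + 1.96 * df["se"])
    )
    return df


def movement_constraint_study(
    n_reps: int = 20, n_steps: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Habitat selection restricts where an animal can move, so realized steps
    are shorter than the selection-free kernel predicts. Returns per-replicate
    selection-free l_mean and the observed mean step length."""
    land = recovery_landscape(seed=9)
    k, theta = RECOVERY_GAMMA
    rows = []
    for r in range(n_reps):
        scen = SimulationScenario(
            selection=RECOVERY_SELECTION, shape=k, scale=theta,
            kappa=RECOVERY_KAPPA, n_fixes=n_steps + 1, start_xy=(6000.0, 6000.0),
            candidate_set_size=50, seed=child_seed(seed, "constraint", r),
        )
        steps = build_steps(regularize(simulate_track(land, scen), 4.0))
        fit = fit_issa(steps, land, seed=child_seed(seed, "constraint-fit", r),
                       compare_habitat=False)
        rows.append(
            {
                "replicate": r,
                "l_mean": fit.kernel.l_mean,
                "observed_mean": fit.observed_mean_length,
                "defined": fit.kernel.defined,
            }
        )
    return pd.DataFrame(rows)


def choice_strata(
    n_strata: int,
    beta: dict[str, float],
    n_available: int = 10,
    seed=0,
    gamma_shape: float = 2.0,
    gamma_scale: float = 300.0,
) -> pd.DataFrame:
    """Matched strata drawn directly from the conditional-logit model: habitat
    covariates i.i.d. standard normal, movement covariates from the gamma /
    uniform availability distributions, the used alternative sampled with
    probability proportional to exp(x @ beta)."""
    rng = np.random.default_rng(seed)
    n_alt = n_available + 1
    S = n_strata
    lengths = rng.gamma(gamma_shape, gamma_scale, size=(S, n_alt))
    cols = {
        "length": lengths,
        "log_l": np.log(lengths),
        "cos_ta": np.cos(rng.uniform(-np.pi, np.pi, size=(S, n_alt))),
    }
    for v in ("slope", "heat", "ndvi"):
        z = rng.standard_normal((S, n_alt))
        cols[v] = z
        cols[v + "2"] = z * z
    eta = np.zeros((S, n_alt))
    for term, b in beta.items():
        if b:
            eta += b * cols[term]
    w = np.exp(eta - eta.max(axis=1, keepdims=True))
    p = w / w.sum(axis=1, keepdims=True)
    used_idx = (p.cumsum(axis=1) > rng.uniform(size=(S, 1))).argmax(axis=1)
    used = np.zeros((S, n_alt), dtype=int)
    used[np.arange(S), used_idx] = 1
    out = {k: v.ravel() for k, v in cols.items()}
    out["used"] = used.ravel()
    out["stratum"] = np.repeat(np.arange(S), n_alt)
    return pd.DataFrame(out)


def habitat_importance_rate(
    n_reps: int,
    n_strata: int,
    habitat_beta: dict[str, float],
    seed=0,
) -> float:
    """Fraction of replicates where the movement-vs-full AIC comparison calls
    habitat important (delta AIC > 2)."""
    beta = {"cos_ta": 0.5} | habitat_beta
    flags = 0
    for r in range(n_reps):
        strata = choice_strata(n_strata, beta, seed=child_seed(seed, "aic", r))
        flags += habitat_importance(strata)["habitat_important"]
    return flags / n_reps


def kde_isopleth_relative_error(
    n_points: int = 10_000, sigma: float = 400.0, seed=0
) -> float:
    """Relative error of the 90% isopleth area of a KDE of an isotropic normal
    sample against the analytic 2 pi sigma_eff^2 ln(10)."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(0.0, sigma, size=(n_points, 2))
    h = h_ref(pts)
    ud = kernel_ud(pts, h)
    area, _, _ = isopleth(ud, 0.9)
    s_eff2 = pts.var(axis=0, ddof=1).mean() + h * h
    analytic = 2.0 * np.pi * s_eff2 * np.log(10.0) / 1e6
    return area / analytic - 1.0


def lmm_recovery_study(
    n_reps: int = 200,
    n_animals: int = 40,
    seed=0,
    effects: dict[str, float] | None = None,
    random_intercept_sd: float = 0.3,
    residual_sd: float = 0.3,
) -> pd.DataFrame:
    """Repeatedly simulate driver tables and refit the generating mixed model.

    Returns one row per parameter with the truth, mean estimate and
    Monte-Carlo standard error of the mean.
    """
    eff = {"l_mean": 0.003, "sex:male": 0.7} if effects is None else effects
    predictors = sorted({t.split(":")[0] for t in eff})
    est: dict[str, list[float]] = {}
    for r in range(n_reps):
        df = simulate_hr_dataset(
            n_animals, true_fixed_effects=eff,
            random_intercept_sd=random_intercept_sd, residual_sd=residual_sd,
            seed=child_seed(seed, "lmm", r),
        )
        # REML: the reporting convention for variance components (ML is
        # reserved for AICc comparisons across fixed-effect sets)
        fit = fit_lmm(df, predictors, reml=True)
        for term, b in eff.items():
            name = term.replace(":", "[") + "]" if ":" in term else term
            est.setdefault(term, []).append(float(fit.coef[name]))
        est.setdefault("sigma_b2", []).append(fit.sigma_b2)
        est.setdefault("sigma_e2", []).append(fit.sigma_e2)
    truth = dict(eff)
    truth["sigma_b2"] = random_intercept_sd**2
    truth["sigma_e2"] = residual_sd**2
    rows = []
    for k, vals in est.items():
        v = np.asarray(vals)
        rows.append(
            {
                "parameter": k,
                "truth": truth[k],
                "mean_estimate": v.mean(),
                "mc_se": v.std(ddof=1) / np.sqrt(len(v)),
            }
        )
    return pd.DataFrame(rows)
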