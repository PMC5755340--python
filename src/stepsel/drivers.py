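"""Drivers of seasonal home-range size.

Log home-range area per animal-season is modelled with a linear mixed model:
animal identity enters as a random intercept; candidate fixed effects are
season, sex, population nucleus, altitude, selection-free movement (l_mean and
the directional-persistence coefficient), the six habitat-selection
coefficients, and resource-availability summaries (mean and CV of heat load
and NDVI over the available steps). Model selection enumerates predictor
subsets at the group level and ranks them by small-sample corrected AIC
(AICc, maximum-likelihood fits); a group's explanatory importance is the AICc
increase when it is removed from the best model.

The LMM is fitted by profiling the likelihood over the variance ratio
``lambda = sigma_b^2 / sigma_e^2``: given lambda the fixed effects are
generalized-least-squares estimates in closed form, and the scalar profile is
maximized numerically, checking the ``lambda = 0`` boundary explicitly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DEFAULT_GROUPS",
    "DriverModelFit",
    "build_design",
    "fit_lmm",
    "all_subsets_aicc",
    "group_importance",
    "marginal_variance_explained",
    "displacement_hr_correlation",
    "build_driver_table",
]

_FACTORS = ("season", "sex", "nucleus")

DEFAULT_GROUPS: dict[str, list[str]] = {
    "season": ["season"],
    "sex": ["sex"],
    "nucleus": ["nucleus"],
    "altitude": ["altitude"],
    "movement": ["l_mean", "beta_cos"],
    "selection": [
        "sel_slope", "sel_slope2", "sel_heat", "sel_heat2", "sel_ndvi", "sel_ndvi2",
    ],
    "availability": ["heat_mean", "heat_cv", "ndvi_mean", "ndvi_cv"],
}


def build_design(df: pd.DataFrame, predictors: list[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; factors dummy-coded against their first
    (alphabetical) level."""
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    for p in predictors:
        if p in _FACTORS:
            levels = sorted(df[p].astype(str).unique())
            for lv in levels[1:]:
                cols.append((df[p].astype(str) == lv).to_numpy(dtype=float))
                names.append(f"{p}[{lv}]")
        else:
            cols.append(df[p].to_numpy(dtype=float))
            names.append(p)
    return np.column_stack(cols), names


@dataclass
class DriverModelFit:
    groups: tuple[str, ...]
    terms: list[str]
    coef: pd.Series
    se: pd.Series
    sigma_b2: float
    sigma_e2: float
    loglik: float
    n: int
    fitted_fixed: np.ndarray = field(repr=False, default=None)
    boundary: bool = False
    reml: bool = False

    @property
    def n_params(self) -> int:
        return len(self.coef) + 2  # fixed effects + two variance components

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def aicc(self) -> float:
        p = self.n_params
        denom = self.n - p - 1
        if denom <= 0:
            return np.inf
        return self.aic + 2.0 * p * (p + 1) / denom


def _profile_pieces(X, y, group_sizes, lam):
    """Accumulate GLS cross-products under V_i = I + lam * J (per group)."""
    p = X.shape[1]
    XtX = np.zeros((p, p))
    Xty = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    start = 0
    for n_i in group_sizes:
        Xi = X[start:start + n_i]
        yi = y[start:start + n_i]
        c = lam / (1.0 + lam * n_i)
        sx = Xi.sum(axis=0)
        sy = yi.sum()
        XtX += Xi.T @ Xi - c * np.outer(sx, sx)
        Xty += Xi.T @ yi - c * sx * sy
        yty += yi @ yi - c * sy * sy
        logdet += np.log1p(lam * n_i)
        start += n_i
    return XtX, Xty, yty, logdet


def _profile_loglik(X, y, group_sizes, lam, reml=False):
    n, p = X.shape
    XtX, Xty, yty, logdet = _profile_pieces(X, y, group_sizes, lam)
    try:
        beta = np.linalg.solve(XtX, Xty)
    except np.linalg.LinAlgError:
        # extreme variance ratios leave the GLS normal equations near-singular
        beta = np.linalg.lstsq(XtX, Xty, rcond=None)[0]
    rss = yty - 2.0 * beta @ Xty + beta @ XtX @ beta
    rss = max(rss, 1e-300)
    if reml:
        df = n - p
        sigma_e2 = rss / df
        ll = -0.5 * (
            df * np.log(2.0 * np.pi * sigma_e2) + logdet
            + np.linalg.slogdet(XtX)[1] - np.linalg.slogdet(X.T @ X)[1] + df
        )
    else:
        sigma_e2 = rss / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma_e2) + logdet + n)
    return ll, beta, sigma_e2, XtX


def fit_lmm(
    df: pd.DataFrame,
    predictors: list[str],
    response: str = "log_area",
    group: str = "animal",
    groups_label: tuple[str, ...] = (),
    reml: bool = False,
) -> DriverModelFit:
    """Random-intercept linear mixed model by profiled likelihood.

    ML by default (required for AICc comparisons across fixed-effect sets);
    REML available for reporting a final model. A variance-ratio optimum at
    zero is returned with ``boundary=True`` (fixed effects then equal OLS).
    """
    d = df.sort_values(group, kind="stable").reset_index(drop=True)
    if d[group].nunique() < 2:
        raise ValueError("need at least 2 grouping levels (animals)")
    X, names = build_design(d, predictors)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_terms(X, names)
        raise ValueError(f"collinear predictors: {bad}")
    y = d[response].to_numpy(dtype=float)
    sizes = d.groupby(group, sort=False).size().to_numpy()

    def neg(loglam):
        return -_profile_loglik(X, y, sizes, np.exp(loglam), reml)[0]

    res = optimize.minimize_scalar(neg, bounds=(-12.0, 12.0), method="bounded")
    ll_opt = -res.fun
    ll_zero = _profile_loglik(X, y, sizes, 0.0, reml)[0]
    if ll_zero >= ll_opt - 1e-9:
        lam, boundary = 0.0, True
    else:
        lam, boundary = float(np.exp(res.x)), False
    ll, beta, sigma_e2, XtX = _profile_loglik(X, y, sizes, lam, reml)
    cov = np.linalg.inv(XtX) * sigma_e2
    return DriverModelFit(
        groups=tuple(groups_label),
        terms=names,
        coef=pd.Series(beta, index=names),
        se=pd.Series(np.sqrt(np.diag(cov)), index=names),
        sigma_b2=lam * sigma_e2,
        sigma_e2=float(sigma_e2),
        loglik=float(ll),
        n=len(y),
        fitted_fixed=X @ beta,
        boundary=boundary,
        reml=reml,
    )


def _collinear_terms(X: np.ndarray, names: list[str]) -> list[str]:
    import scipy.linalg

    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > max(X.shape) * np.finfo(float).eps * (diag.max() or 1.0)))
    return [names[k] for k in piv[rank:]]


def _terms_for(groups: tuple[str, ...], group_defs: dict[str, list[str]]) -> list[str]:
    terms: list[str] = []
    for g in groups:
        terms.extend(group_defs[g])
    return terms


def all_subsets_aicc(
    df: pd.DataFrame,
    group_defs: dict[str, list[str]] | None = None,
    response: str = "log_area",
    group: str = "animal",
) -> tuple[pd.DataFrame, DriverModelFit, dict[tuple[str, ...], DriverModelFit]]:
    """Fit every predictor-group subset by ML and rank by AICc.

    Ties resolve to fewer parameters, then lexicographically by group names.
    Candidates with non-positive AICc correction denominator are skipped with
    a notice row. Returns (ranking table, best fit, all fits keyed by subset).
    """
    defs = group_defs or DEFAULT_GROUPS
    names = sorted(defs)
    fits: dict[tuple[str, ...], DriverModelFit] = {}
    rows = []
    for r in range(len(names) + 1):
        for combo in itertools.combinations(names, r):
            terms = _terms_for(combo, defs)
            try:
                fit = fit_lmm(df, terms, response=response, group=group,
                              groups_label=combo)
            except ValueError:  # rank-deficient candidate at this sample size
                continue
            if not np.isfinite(fit.aicc):
                continue
            fits[combo] = fit
            rows.append(
                {
                    "groups": "+".join(combo) if combo else "(intercept)",
                    "n_groups": len(combo),
                    "k": fit.n_params,
                    "loglik": fit.loglik,
                    "aicc": fit.aicc,
                    "_combo": combo,
                }
            )
    table = pd.DataFrame(rows).sort_values(
        ["aicc", "k", "groups"], kind="stable"
    ).reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    best = fits[table["_combo"].iloc[0]]
    return table.drop(columns="_combo"), best, fits


def group_importance(
    df: pd.DataFrame,
    best: DriverModelFit,
    group_defs: dict[str, list[str]] | None = None,
    response: str = "log_area",
    group: str = "animal",
) -> pd.DataFrame:
    """AICc increase when removing each predictor group from the best model.

    delta_aicc = AICc(best minus group) - AICc(best); larger means more
    important. Groups absent from the best model get NaN (not applicable).
    """
    defs = group_defs or DEFAULT_GROUPS
    rows = []
    for g in sorted(defs):
        if g not in best.groups:
            rows.append({"group": g, "delta_aicc": np.nan, "in_best": False})
            continue
        reduced = tuple(x for x in best.groups if x != g)
        fit = fit_lmm(
            df, _terms_for(reduced, defs), response=response, group=group,
            groups_label=reduced,
        )
        rows.append(
            {"group": g, "delta_aicc": float(fit.aicc - best.aicc), "in_best": True}
        )
    return pd.DataFrame(rows).sort_values(
        "delta_aicc", ascending=False, na_position="last"
    ).reset_index(drop=True)


def marginal_variance_explained(fit: DriverModelFit) -> float:
    """Proportion of variance explained by the fixed effects:
    var(X beta) / (var(X beta) + sigma_b^2 + sigma_e^2)."""
    vf = float(np.var(fit.fitted_fixed, ddof=1)) if len(fit.fitted_fixed) > 1 else 0.0
    return vf / (vf + fit.sigma_b2 + fit.sigma_e2)


def displacement_hr_correlation(
    displacements: pd.DataFrame,
    hr_table: pd.DataFrame,
    area_col: str = "area90",
) -> tuple[float, float]:
    """Pearson correlation of log median daily net displacement vs log home-range
    area over matched animal-seasons. Returns (r, p)."""
    merged = displacements.merge(hr_table, on=["animal_id", "season"])
    merged = merged.loc[(merged["displacement"] > 0) & (merged[area_col] > 0)]
    if len(merged) < 3:
        raise ValueError("need at least 3 matched animal-season pairs")
    r, p = stats.pearsonr(
        np.log(merged["displacement"]), np.log(merged[area_col])
    )
    return float(r), float(p)


def build_driver_table(
    issa_fits: list,
    hr_estimates: list,
    metadata: pd.DataFrame,
    altitudes: dict[tuple[str, str], float] | None = None,
    area_fraction: float = 0.9,
) -> pd.DataFrame:
    """Assemble the per animal-season driver table from upstream results.

    ``metadata`` maps animal_id -> sex, nucleus. Selection coefficients are the
    standardized iSSA estimates; availability summaries are the mean and CV of
    raw heat load and NDVI over the available alternatives (NDVI shifted to
    [0, 2] before its CV so the mean stays away from zero); ``altitudes`` maps
    (animal_id, season) to the mean fix altitude (m).
    """
    meta = metadata.set_index("animal_id")
    hr = {(e.animal_id, e.season): e for e in hr_estimates}
    rows = []
    for f in issa_fits:
        key = (f.animal_id, f.season)
        if key not in hr:
            continue
        e = hr[key]
        if area_fraction not in e.areas_km2 or f.kernel.l_mean is None:
            continue
        avail = f.strata.loc[f.strata["used"] == 0]
        heat = avail["heat_raw"].to_numpy()
        ndvi01 = avail["ndvi_raw"].to_numpy() + 1.0
        altitude = float(altitudes.get(key, np.nan)) if altitudes else np.nan
        rows.append(
            {
                "animal": f.animal_id,
                "season": f.season,
                "sex": meta.loc[f.animal_id, "sex"],
                "nucleus": meta.loc[f.animal_id, "nucleus"],
                "altitude": altitude,
                "l_mean": f.kernel.l_mean,
                "beta_cos": f.kernel.kappa,
                "sel_slope": f.coef["slope"],
                "sel_slope2": f.coef["slope2"],
                "sel_heat": f.coef["heat"],
                "sel_heat2": f.coef["heat2"],
                "sel_ndvi": f.coef["ndvi"],
                "sel_ndvi2": f.coef["ndvi2"],
                "heat_mean": float(heat.mean()),
                "heat_cv": float(heat.std(ddof=1) / heat.mean()),
                "ndvi_mean": float(avail["ndvi_raw"].mean()),
                "ndvi_cv": float(ndvi01.std(ddof=1) / ndvi01.mean()),
                "log_area": float(np.log(e.areas_km2[area_fraction])),
            }
        )
    return pd.DataFrame(rows)
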