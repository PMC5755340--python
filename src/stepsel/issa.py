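"""Integrated step-selection analysis (iSSA).

For each animal-season the analysis:

1. fits a gamma distribution to observed step lengths by maximum likelihood
   (the availability distribution for step lengths);
2. pairs every observed step that has a defined turn angle with N available
   steps sharing its start point, lengths drawn from the fitted gamma and turn
   angles from a uniform distribution on (-pi, pi];
3. extracts habitat covariates (slope, heat load, time-matched NDVI) at every
   end point, centres/standardizes them over all alternatives within the
   animal-season, and adds quadratic terms;
4. fits the matched conditional-logistic likelihood with movement covariates
   (step length l, ln l, cos turn angle) on natural scale plus the standardized
   habitat terms;
5. updates the selection-free movement kernel: the modified gamma has shape
   ``k + beta_ln(l)`` and rate ``1/theta - beta_l``, giving the selection-free
   mean step length ``l_mean = (k + beta_ln(l)) / (1/theta - beta_l)``; the
   coefficient of cos(turn angle) is the von Mises concentration of
   directional persistence over the uniform proposal.

Habitat importance is judged by the AIC difference between the movement-only
model and the movement + habitat model on identical strata.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .landscape import Landscape

__all__ = [
    "GammaFit",
    "ClogitResult",
    "IssaFit",
    "MOVEMENT_TERMS",
    "HABITAT_TERMS",
    "fit_gamma",
    "sample_available",
    "extract_covariates",
    "build_strata",
    "standardize_strata",
    "screen_collinearity",
    "fit_conditional_logit",
    "null_loglik",
    "update_movement_kernel",
    "habitat_importance",
    "fit_issa",
    "child_seed",
]

log = logging.getLogger(__name__)

MOVEMENT_TERMS = ("length", "log_l", "cos_ta")
HABITAT_TERMS = ("slope", "slope2", "heat", "heat2", "ndvi", "ndvi2")
_HABITAT_VARS = ("slope", "heat", "ndvi")
DEFAULT_TERMS = MOVEMENT_TERMS + HABITAT_TERMS


def child_seed(master: int, *keys) -> np.random.SeedSequence:
    """Deterministic per-(animal, season) child of one master seed."""
    ints = [int(master) & 0x7FFFFFFF]
    for k in keys:
        ints.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k))
    return np.random.SeedSequence(ints)


# ---------------------------------------------------------------------------
# gamma availability distribution
# ---------------------------------------------------------------------------

@dataclass
class GammaFit:
    shape: float
    scale: float
    loglik: float
    n: int

    @property
    def mean(self) -> float:
        return self.shape * self.scale


def _positive_lengths(lengths: np.ndarray) -> np.ndarray:
    """Replace zeros by half the minimum positive length (log/gamma support)."""
    x = np.asarray(lengths, dtype=float)
    x = x[np.isfinite(x)]
    pos = x[x > 0]
    if pos.size == 0:
        raise ValueError("no positive step lengths")
    return np.where(x <= 0, pos.min() / 2.0, x)


def fit_gamma(step_lengths) -> GammaFit:
    """ML gamma fit (location fixed at 0) to observed step lengths."""
    x = _positive_lengths(np.asarray(step_lengths))
    if x.size < 10:
        raise ValueError(f"need >= 10 step lengths, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("all step lengths identical: gamma ML degenerate (shape -> inf)")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    ll = float(stats.gamma.logpdf(x, shape, scale=scale).sum())
    return GammaFit(shape=float(shape), scale=float(scale), loglik=ll, n=int(x.size))


# ---------------------------------------------------------------------------
# availability sampling and covariate extraction
# ---------------------------------------------------------------------------

def sample_available(
    steps: pd.DataFrame,
    gamma_fit: GammaFit,
    n_available: int = 10,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Draw N available steps per observed step.

    Each observed step must have a defined turn angle (first steps of bursts
    are excluded from strata). Available lengths are i.i.d. draws from the
    fitted gamma; available turn angles i.i.d. Uniform(-pi, pi] relative to
    the previous heading; all alternatives share the step's start point.
    Returns a long table with one row per (stratum, alternative), the used
    alternative first (``used == 1``).
    """
    if n_available < 1:
        raise ValueError("n_available must be >= 1")
    rng = np.random.default_rng(seed)
    obs = steps.loc[steps["cos_ta"].notna()].reset_index(drop=True)
    S = len(obs)
    if S == 0:
        raise ValueError("no steps with a defined turn angle")
    prev_heading = obs["heading"].to_numpy() - obs["turn_angle"].to_numpy()

    lengths = rng.gamma(gamma_fit.shape, gamma_fit.scale, size=(S, n_available))
    turns = rng.uniform(-np.pi, np.pi, size=(S, n_available))
    heads = prev_heading[:, None] + turns
    x2 = obs["x1"].to_numpy()[:, None] + lengths * np.cos(heads)
    y2 = obs["y1"].to_numpy()[:, None] + lengths * np.sin(heads)

    n_alt = n_available + 1
    out = obs.loc[obs.index.repeat(n_alt)].reset_index(drop=True)
    out["stratum"] = np.repeat(np.arange(S), n_alt)
    out["alternative"] = np.tile(np.arange(n_alt), S)
    out["used"] = (out["alternative"] == 0).astype(int)
    avail = out["used"] == 0
    out.loc[avail, "length"] = lengths.ravel()
    out.loc[avail, "turn_angle"] = turns.ravel()
    out.loc[avail, "cos_ta"] = np.cos(turns).ravel()
    out.loc[avail, "x2"] = x2.ravel()
    out.loc[avail, "y2"] = y2.ravel()
    out["log_l"] = np.log(_positive_lengths_keep_shape(out["length"].to_numpy()))
    return out


def _positive_lengths_keep_shape(x: np.ndarray) -> np.ndarray:
    pos = x[x > 0]
    floor = pos.min() / 2.0 if pos.size else 1.0
    return np.where(x <= 0, floor, x)


def extract_covariates(
    points: pd.DataFrame, landscape: Landscape, x="x2", y="y2", when="t_end"
) -> pd.DataFrame:
    """slope / heat / time-matched NDVI at end points; off-raster points get NaN."""
    xs = points[x].to_numpy(dtype=float)
    ys = points[y].to_numpy(dtype=float)
    ok = landscape.contains(xs, ys)
    out = pd.DataFrame(index=points.index, columns=list(_HABITAT_VARS), dtype=float)
    if ok.any():
        sub = points.loc[ok]
        out.loc[ok, "slope"] = landscape.value_at("slope", xs[ok], ys[ok])
        out.loc[ok, "heat"] = landscape.value_at("heat", xs[ok], ys[ok])
        # NDVI layer depends on each step's end time
        ndvi = np.empty(int(ok.sum()))
        times = pd.to_datetime(sub[when])
        for li, idx in _group_by_layer(times, landscape):
            pts = sub.iloc[idx]
            ndvi[idx] = landscape.ndvi[li][
                landscape.cell_index(pts[x].to_numpy(), pts[y].to_numpy())
            ]
        out.loc[ok, "ndvi"] = ndvi
    return out


def _group_by_layer(times: pd.Series, landscape: Landscape):
    layers = np.array([landscape.ndvi_layer_index(t.to_pydatetime()) for t in times])
    for li in np.unique(layers):
        yield int(li), np.nonzero(layers == li)[0]


def build_strata(
    steps: pd.DataFrame,
    landscape: Landscape,
    n_available: int = 10,
    seed: int | np.random.SeedSequence | None = None,
    gamma_fit: GammaFit | None = None,
) -> tuple[pd.DataFrame, GammaFit]:
    """Used/available strata with raw habitat covariates for one animal-season.

    The gamma availability distribution is fitted to all observed step lengths
    of the animal-season (including first steps of bursts) unless supplied.
    Strata whose used end point leaves the raster are dropped with a warning;
    available alternatives off-raster are dropped individually, the stratum
    surviving while at least one available alternative remains.
    """
    gf = gamma_fit or fit_gamma(steps["length"].to_numpy())
    alts = sample_available(steps, gf, n_available=n_available, seed=seed)
    cov = extract_covariates(alts, landscape)
    alts = pd.concat([alts, cov.add_suffix("_raw")], axis=1)

    missing = cov.isna().any(axis=1)
    bad_used = alts.loc[missing & (alts["used"] == 1), "stratum"].unique()
    if bad_used.size:
        log.warning("dropping %d strata with used end-point off-raster", bad_used.size)
    alts = alts.loc[~alts["stratum"].isin(bad_used) & ~missing]
    n_avail_left = alts.loc[alts["used"] == 0].groupby("stratum").size()
    keep = n_avail_left.index[n_avail_left >= 1]
    alts = alts.loc[alts["stratum"].isin(keep)].reset_index(drop=True)
    return alts, gf


def standardize_strata(
    strata: pd.DataFrame, variables: tuple[str, ...] = _HABITAT_VARS
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Centre/scale habitat covariates over ALL alternatives (used + available)
    and square the standardized values for the quadratic terms. Returns the
    augmented table and the (mean, sd) pairs used, needed later to place
    relative-selection-strength grids on the raw scale.
    """
    out = strata.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for v in variables:
        raw = out[f"{v}_raw"].to_numpy(dtype=float)
        mu = float(np.mean(raw))
        sd = float(np.std(raw, ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"habitat covariate {v!r} has zero variance; cannot standardize")
        z = (raw - mu) / sd
        out[v] = z
        out[f"{v}2"] = z * z
        scaling[v] = (mu, sd)
    return out, scaling


def screen_collinearity(
    strata: pd.DataFrame,
    variables: tuple[str, ...] = _HABITAT_VARS,
    threshold: float = 0.70,
) -> pd.DataFrame:
    """Pairwise Pearson correlations among habitat covariates over all
    alternatives; |r| >= threshold flagged (report only, fitting proceeds).
    Zero-variance covariates yield an undefined correlation, also flagged.
    """
    if strata["stratum"].nunique() < 3:
        raise ValueError("need at least 3 strata to screen collinearity")
    cols = [f"{v}_raw" if f"{v}_raw" in strata.columns else v for v in variables]
    rows = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            xa = strata[cols[a]].to_numpy(dtype=float)
            xb = strata[cols[b]].to_numpy(dtype=float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(xa, xb)[0, 1])
            rows.append(
                {
                    "var_a": variables[a],
                    "var_b": variables[b],
                    "r": r,
                    "flagged": bool(np.isnan(r) or abs(r) >= threshold),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# conditional logistic regression (matched case-control likelihood)
# ---------------------------------------------------------------------------

@dataclass
class ClogitResult:
    coef: pd.Series
    se: pd.Series
    loglik: float
    n_strata: int
    n_iter: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.coef)


def null_loglik(strata_sizes) -> float:
    """Log-likelihood at beta = 0: uniform choice within each stratum."""
    return float(-np.sum(np.log(np.asarray(strata_sizes, dtype=float))))


def _stratum_blocks(strata_ids: np.ndarray) -> np.ndarray:
    """Start indices of contiguous stratum blocks (input must be grouped)."""
    change = np.nonzero(np.diff(strata_ids))[0] + 1
    return np.concatenate([[0], change])


def fit_conditional_logit(
    strata: pd.DataFrame,
    terms: tuple[str, ...] = DEFAULT_TERMS,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ClogitResult:
    """Newton-Raphson fit of the conditional (matched) logistic likelihood.

    Maximizes ``sum_s [eta_used - log sum_alt exp(eta_alt)]`` with
    ``eta = X @ beta`` (no intercept: it cancels within strata), starting from
    beta = 0 (the uniform-choice null), with step-halving, convergence when the
    gradient max-norm drops below ``tol``. Standard errors come from the
    inverse observed information. Rank deficiency of the within-stratum
    centred design raises an error naming the collinear terms; an estimate
    running past |beta| = 50 is flagged non-identifiable (separation).
    """
    df = strata.sort_values(["stratum", "used"], ascending=[True, False], kind="stable")
    sid = df["stratum"].to_numpy()
    X = df[list(terms)].to_numpy(dtype=float)
    y = df["used"].to_numpy(dtype=float)
    starts = _stratum_blocks(sid)
    sizes = np.diff(np.concatenate([starts, [len(sid)]]))
    if np.any(sizes < 2):
        raise ValueError("every stratum needs >= 2 alternatives")
    n_strata = len(starts)
    used_per = np.add.reduceat(y, starts)
    if not np.allclose(used_per, 1.0):
        raise ValueError("every stratum must contain exactly one used alternative")

    # identifiability: centre within strata, then rank-check
    means = np.add.reduceat(X, starts, axis=0) / sizes[:, None]
    Xc = X - np.repeat(means, sizes, axis=0)
    _, R, piv = scipy.linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > max(Xc.shape) * np.finfo(float).eps * (diag.max() or 1.0)))
    if rank < X.shape[1]:
        bad = [terms[k] for k in piv[rank:]]
        raise ValueError(f"design matrix rank-deficient; collinear terms: {bad}")

    beta = np.zeros(X.shape[1])
    ll = _clogit_loglik(X, y, starts, sizes, beta)
    flags: list[str] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = _clogit_probs(X, starts, sizes, beta)
        grad = X.T @ (y - p)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        M = np.add.reduceat(X * p[:, None], starts, axis=0)  # per-stratum E[x]
        info = (X * p[:, None]).T @ X - M.T @ M
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving on the concave log-likelihood
        for _ in range(30):
            cand = beta + step
            ll_new = _clogit_loglik(X, y, starts, sizes, cand)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta, ll = cand, ll_new
    else:
        it = max_iter
    if np.any(np.abs(beta) > 50):
        flags.append("non-identifiable")
        warnings.warn(
            "conditional-logit coefficient beyond |50|: likely separation; "
            "estimates flagged non-identifiable",
            stacklevel=2,
        )
    p = _clogit_probs(X, starts, sizes, beta)
    M = np.add.reduceat(X * p[:, None], starts, axis=0)
    info = (X * p[:, None]).T @ X - M.T @ M
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return ClogitResult(
        coef=pd.Series(beta, index=list(terms)),
        se=pd.Series(se, index=list(terms)),
        loglik=float(ll),
        n_strata=n_strata,
        n_iter=it,
        converged=converged,
        flags=flags,
    )


def _clogit_probs(X, starts, sizes, beta):
    eta = X @ beta
    emax = np.repeat(np.maximum.reduceat(eta, starts), sizes)
    w = np.exp(eta - emax)
    denom = np.repeat(np.add.reduceat(w, starts), sizes)
    return w / denom


def _clogit_loglik(X, y, starts, sizes, beta):
    eta = X @ beta
    emax = np.maximum.reduceat(eta, starts)
    lse = emax + np.log(np.add.reduceat(np.exp(eta - np.repeat(emax, sizes)), starts))
    return float(np.sum(eta[y == 1]) - np.sum(lse))


# ---------------------------------------------------------------------------
# movement-kernel updating and habitat importance
# ---------------------------------------------------------------------------

@dataclass
class MovementKernel:
    """Selection-free movement kernel implied by an iSSA fit."""

    shape: float  # k + beta_ln(l)
    rate: float  # 1/theta - beta_l
    l_mean: float | None  # shape / rate when both positive, else undefined
    kappa: float  # von Mises concentration = beta_cos over a uniform proposal
    defined: bool


def update_movement_kernel(gamma_fit: GammaFit, coef: pd.Series) -> MovementKernel:
    """Correct the availability gamma with the fitted movement coefficients.

    l_mean = (k + beta_ln(l)) / (1/theta - beta_l); undefined (flagged, never
    silently negative) unless both the updated shape and rate are positive.
    """
    shape = gamma_fit.shape + float(coef.get("log_l", 0.0))
    rate = 1.0 / gamma_fit.scale - float(coef.get("length", 0.0))
    ok = shape > 0 and rate > 0
    return MovementKernel(
        shape=shape,
        rate=rate,
        l_mean=shape / rate if ok else None,
        kappa=float(coef.get("cos_ta", 0.0)),
        defined=ok,
    )


def habitat_importance(
    strata: pd.DataFrame,
    movement_terms: tuple[str, ...] = MOVEMENT_TERMS,
    habitat_terms: tuple[str, ...] = HABITAT_TERMS,
) -> dict:
    """AIC comparison of movement-only vs movement + habitat on identical strata.

    delta_aic = AIC(movement-only) - AIC(movement + habitat); habitat is called
    important when delta_aic > 2.
    """
    fit_move = fit_conditional_logit(strata, terms=movement_terms)
    fit_full = fit_conditional_logit(strata, terms=movement_terms + habitat_terms)
    delta = fit_move.aic - fit_full.aic
    return {
        "delta_aic": float(delta),
        "habitat_important": bool(delta > 2.0),
        "movement_fit": fit_move,
        "full_fit": fit_full,
    }


# ---------------------------------------------------------------------------
# per animal-season driver
# ---------------------------------------------------------------------------

@dataclass
class IssaFit:
    """Complete iSSA result for one animal-season."""

    animal_id: str
    season: str
    result: ClogitResult
    gamma: GammaFit
    kernel: MovementKernel
    scaling: dict[str, tuple[float, float]]
    strata: pd.DataFrame
    observed_mean_length: float
    delta_aic_habitat: float | None = None
    habitat_important: bool | None = None

    @property
    def coef(self) -> pd.Series:
        return self.result.coef

    @property
    def se(self) -> pd.Series:
        return self.result.se

    @property
    def aic(self) -> float:
        return self.result.aic

    def summary_row(self) -> dict:
        row = {
            "animal_id": self.animal_id,
            "season": self.season,
            "n_strata": self.result.n_strata,
            "gamma_shape": self.gamma.shape,
            "gamma_scale": self.gamma.scale,
            "l_mean": self.kernel.l_mean,
            "kappa": self.kernel.kappa,
            "observed_mean_length": self.observed_mean_length,
            "aic": self.aic,
            "delta_aic_habitat": self.delta_aic_habitat,
            "habitat_important": self.habitat_important,
            "converged": self.result.converged,
            "flags": ";".join(self.result.flags),
        }
        for t in self.coef.index:
            row[f"coef_{t}"] = self.coef[t]
            row[f"se_{t}"] = self.se[t]
        return row


def fit_issa(
    steps: pd.DataFrame,
    landscape: Landscape,
    n_available: int = 10,
    seed: int | np.random.SeedSequence | None = None,
    animal_id: str | None = None,
    season: str | None = None,
    compare_habitat: bool = True,
) -> IssaFit:
    """Full iSSA for one animal-season step series."""
    strata, gf = build_strata(steps, landscape, n_available=n_available, seed=seed)
    strata, scaling = standardize_strata(strata)
    res = fit_conditional_logit(strata, terms=DEFAULT_TERMS)
    kernel = update_movement_kernel(gf, res.coef)
    fit = IssaFit(
        animal_id=animal_id or str(steps["animal_id"].iloc[0]),
        season=season or str(steps["season"].iloc[0]),
        result=res,
        gamma=gf,
        kernel=kernel,
        scaling=scaling,
        strata=strata,
        observed_mean_length=float(steps["length"].mean()),
    )
    if compare_habitat:
        imp = habitat_importance(strata)
        fit.delta_aic_habitat = imp["delta_aic"]
        fit.habitat_important = imp["habitat_important"]
    return fit
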