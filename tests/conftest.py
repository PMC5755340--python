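import datetime as dt

import numpy as np
import pandas as pd
import pytest

from stepsel.landscape import SeasonalityParams, generate_landscape


@pytest.fixture(scope="session")
def landscape():
    """Mid-sized patchy landscape: weak N-S ramp, strong correlated relief, so
    habitat covariates vary at the step scale."""
    p = SeasonalityParams(
        altitude_min=2200, altitude_max=2500, relief_corr_cells=2.5, relief_sd=300.0
    )
    return generate_landscape((120, 120), 100.0, p, seed=9)


@pytest.fixture(scope="session")
def mountain_landscape():
    """Default high-relief landscape with a strong altitudinal NDVI cycle."""
    return generate_landscape((100, 100), 100.0, SeasonalityParams(), seed=3)


def make_fixes(times, xy, animal_id="a1"):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "timestamp": pd.to_datetime(times),
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )


def hourly_times(n, start="2005-05-01 00:00", step_h=1.0):
    t0 = pd.Timestamp(start)
    return [t0 + pd.Timedelta(hours=step_h * k) for k in range(n)]


def simulate_strata(
    n_strata,
    beta,
    n_available=10,
    seed=0,
    gamma_shape=2.0,
    gamma_scale=300.0,
):
    """Draw matched strata directly from the conditional-logit model.

    Habitat covariates (slope, heat, ndvi) are i.i.d. standard normal per
    alternative; movement covariates come from the gamma / uniform-turn
    availability distributions; the used alternative is drawn with probability
    proportional to exp(x @ beta). ``beta`` maps term name -> coefficient.
    Returns a long strata table ready for ``fit_conditional_logit``.
    """
    rng = np.random.default_rng(seed)
    n_alt = n_available + 1
    S = n_strata
    lengths = rng.gamma(gamma_shape, gamma_scale, size=(S, n_alt))
    cos_ta = np.cos(rng.uniform(-np.pi, np.pi, size=(S, n_alt)))
    cols = {
        "length": lengths,
        "log_l": np.log(lengths),
        "cos_ta": cos_ta,
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
    out["alternative"] = np.tile(np.arange(n_alt), S)
    return pd.DataFrame(out)


def _separated(X, used_idx):
    """True when some coefficient direction separates the used alternatives:
    along it the likelihood increases without bound (MLE at infinity). Checked
    on a fine direction grid (exact for 1 covariate, dense scan for 2)."""
    n_strata, _, k = X.shape
    diffs = X[np.arange(n_strata), used_idx][:, None, :] - X  # used minus alt
    if k == 1:
        dirs = np.array([[1.0], [-1.0]])
    else:
        ang = np.linspace(0, 2 * np.pi, 721)
        dirs = np.column_stack([np.cos(ang), np.sin(ang)])
    for u in dirs:
        proj = diffs @ u  # (stratum, alt)
        if (proj.min(axis=1) >= -1e-12).all():
            return True
    return False


def toy_clogit_instance(idx, n_covariates=1):
    """Deterministic small conditional-logit instance (<= 5 strata, <= 2
    covariates, small integer covariates) with an interior likelihood maximum.
    Instances where the used alternative always carries an extreme covariate
    value (separation, MLE at infinity) are skipped and regenerated."""
    seed = 1000 * n_covariates + idx
    while True:
        rng = np.random.default_rng(seed)
        n_strata = int(rng.integers(2, 6))
        n_alt = int(rng.integers(3, 5))
        X = rng.integers(-2, 3, size=(n_strata, n_alt, n_covariates)).astype(float)
        eta = X.sum(axis=2) * 0.5
        w = np.exp(eta - eta.max(axis=1, keepdims=True))
        p = w / w.sum(axis=1, keepdims=True)
        used_idx = (p.cumsum(axis=1) > rng.uniform(size=(n_strata, 1))).argmax(axis=1)
        if not _separated(X, used_idx):
            break
        seed += 7919
    terms = ["slope", "heat"][:n_covariates]
    used = np.zeros((n_strata, n_alt), dtype=int)
    used[np.arange(n_strata), used_idx] = 1
    df = pd.DataFrame(
        {t: X[:, :, d].ravel() for d, t in enumerate(terms)}
        | {
            "used": used.ravel(),
            "stratum": np.repeat(np.arange(n_strata), n_alt),
        }
    )
    return df, terms


def clogit_brute_force(strata, terms, lo=-5.0, hi=5.0, rounds=60):
    """Independent likelihood maximizer for <= 2 covariates: coarse grid search
    refined by coordinate-wise golden-section shrinking of the bracket. The
    likelihood itself is written from the matched-choice definition, sharing no
    code with the Newton fitter."""
    from scipy.special import logsumexp

    groups = [
        (g[list(terms)].to_numpy(dtype=float), g["used"].to_numpy())
        for _, g in strata.groupby("stratum")
    ]

    def ll(b):
        b = np.asarray(b, dtype=float)
        total = 0.0
        for Xs, ys in groups:
            eta = Xs @ b
            total += float(eta[ys == 1][0] - logsumexp(eta))
        return total

    k = len(terms)
    grids = [np.linspace(lo, hi, 41) for _ in range(k)]
    if k == 1:
        vals = [ll([b]) for b in grids[0]]
        centre = [grids[0][int(np.argmax(vals))]]
    else:
        best, centre = -np.inf, [0.0] * k
        for b0 in grids[0]:
            for b1 in grids[1]:
                v = ll([b0, b1])
                if v > best:
                    best, centre = v, [b0, b1]
    width = (hi - lo) / 40.0
    while width > 1e-10:
        # sweep coordinates repeatedly at this scale before shrinking, so a
        # correlated ridge is followed rather than abandoned
        for _ in range(200):
            moved = False
            for d in range(k):
                pts = centre[d] + width * np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
                vals = []
                for p in pts:
                    b = list(centre)
                    b[d] = p
                    vals.append(ll(b))
                new = float(pts[int(np.argmax(vals))])
                if new != centre[d]:
                    centre[d] = new
                    moved = True
            if not moved:
                break
        width *= 0.5
    return np.array(centre), ll(centre)
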