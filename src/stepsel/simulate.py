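"""Forward simulation of step-selection movement and of home-range driver tables.

The track simulator is the inverse of the estimator: at every step it proposes a
finite candidate set (lengths from a gamma distribution, turn angles from a von
Mises distribution centred on the previous heading) and realizes one candidate
with probability proportional to ``exp`` of the habitat-selection score at the
candidate end-point. As the candidate-set size C grows this converges to exact
sampling from the continuous step-selection kernel; C = 50 is the default.
Candidates falling off the landscape are discarded and redrawn (availability
truncation), not reflected.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import Landscape

__all__ = [
    "SimulationScenario",
    "SimulationStuckError",
    "simulate_track",
    "simulate_hr_dataset",
    "HABITAT_TERMS",
]

#: habitat terms entering the selection score, in canonical order
HABITAT_TERMS = ("slope", "slope2", "heat", "heat2", "ndvi", "ndvi2")


class SimulationStuckError(RuntimeError):
    """Raised when every candidate leaves the landscape for too many redraws."""


@dataclass
class SimulationScenario:
    """Ground truth for one simulated animal.

    ``selection`` holds raw-scale coefficients for the habitat terms
    (slope, slope2, heat, heat2, ndvi, ndvi2; missing keys mean zero);
    ``shape``/``scale`` parameterize the gamma proposal for step lengths (m);
    ``kappa`` is the von Mises concentration of turn angles (0 = uniform).
    """

    selection: dict[str, float] = field(default_factory=dict)
    shape: float = 2.0
    scale: float = 150.0
    kappa: float = 0.5
    fix_interval_h: float = 4.0
    n_fixes: int = 500
    start_xy: tuple[float, float] = (0.0, 0.0)
    start_time: _dt.datetime = _dt.datetime(2005, 4, 1)
    candidate_set_size: int = 50
    seed: int | np.random.SeedSequence | None = 0
    animal_id: str = "sim01"
    sex: str = "female"
    nucleus: str = "west"
    # optional observation imperfections, off by default
    fix_dropout: float = 0.0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if self.kappa < 0:
            raise ValueError("von Mises concentration must be non-negative")
        if self.candidate_set_size < 1:
            raise ValueError("candidate set size must be >= 1")
        unknown = set(self.selection) - set(HABITAT_TERMS)
        if unknown:
            raise ValueError(f"unknown habitat terms: {sorted(unknown)}")


def _habitat_score(landscape: Landscape, x, y, when, selection: dict[str, float]):
    cov = landscape.covariates_at(x, y, when)
    score = np.zeros(np.shape(np.asarray(x)), dtype=float)
    for name in ("slope", "heat", "ndvi"):
        b1 = selection.get(name, 0.0)
        b2 = selection.get(name + "2", 0.0)
        if b1 or b2:
            v = np.asarray(cov[name], dtype=float)
            score += b1 * v + b2 * v * v
    return score


def simulate_track(landscape: Landscape, scenario: SimulationScenario) -> pd.DataFrame:
    """Simulate one GPS track; returns fixes (animal_id, timestamp, x, y, altitude)."""
    if not bool(np.all(landscape.contains(*scenario.start_xy))):
        raise ValueError("start location must lie inside the landscape")
    rng = np.random.default_rng(scenario.seed)
    C = scenario.candidate_set_size
    x, y = scenario.start_xy
    heading = rng.uniform(-np.pi, np.pi)
    dt = _dt.timedelta(hours=scenario.fix_interval_h)

    xs = np.empty(scenario.n_fixes)
    ys = np.empty(scenario.n_fixes)
    xs[0], ys[0] = x, y
    for step in range(1, scenario.n_fixes):
        when = scenario.start_time + step * dt
        for attempt in range(101):
            lengths = rng.gamma(scenario.shape, scenario.scale, size=C)
            if step == 1:
                cand_heading = rng.uniform(-np.pi, np.pi, size=C)
            else:
                turns = rng.vonmises(0.0, scenario.kappa, size=C) if scenario.kappa > 0 \
                    else rng.uniform(-np.pi, np.pi, size=C)
                cand_heading = heading + turns
            cx = x + lengths * np.cos(cand_heading)
            cy = y + lengths * np.sin(cand_heading)
            ok = landscape.contains(cx, cy)
            if ok.any():
                break
        else:
            raise SimulationStuckError(
                f"all {C} candidates off-landscape for >100 retries at step {step}"
            )
        cx, cy, cand_heading = cx[ok], cy[ok], cand_heading[ok]
        score = _habitat_score(landscape, cx, cy, when, scenario.selection)
        w = np.exp(score - score.max())
        pick = rng.choice(len(cx), p=w / w.sum())
        x, y, heading = cx[pick], cy[pick], cand_heading[pick]
        xs[step], ys[step] = x, y

    times = [scenario.start_time + k * dt for k in range(scenario.n_fixes)]
    keep = np.ones(scenario.n_fixes, dtype=bool)
    if scenario.fix_dropout > 0:
        keep = rng.uniform(size=scenario.n_fixes) >= scenario.fix_dropout
        keep[0] = True
    if scenario.jitter_sd > 0:
        xs = xs + rng.normal(0.0, scenario.jitter_sd, size=xs.shape)
        ys = ys + rng.normal(0.0, scenario.jitter_sd, size=ys.shape)
    fixes = pd.DataFrame(
        {
            "animal_id": scenario.animal_id,
            "timestamp": pd.to_datetime(times),
            "x": xs,
            "y": ys,
            "altitude": landscape.value_at("altitude", xs, ys),
        }
    )
    return fixes.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# driver-table generator (ground truth for the home-range-size mixed model)
# ---------------------------------------------------------------------------

#: numeric predictor columns and the uniform ranges they are drawn from
_PREDICTOR_RANGES: dict[str, tuple[float, float]] = {
    "l_mean": (100.0, 600.0),
    "beta_cos": (0.0, 1.5),
    "sel_slope": (-0.5, 1.5),
    "sel_slope2": (-0.8, 0.2),
    "sel_heat": (-1.5, 0.5),
    "sel_heat2": (-1.0, 0.2),
    "sel_ndvi": (-0.5, 1.5),
    "sel_ndvi2": (-1.0, 0.2),
    "heat_mean": (0.3, 0.7),
    "heat_cv": (0.1, 0.5),
    "ndvi_mean": (0.1, 0.5),
    "ndvi_cv": (0.1, 0.6),
    "altitude": (1700.0, 3000.0),
}

_SEASONS = ("spring", "summer", "autumn", "winter")


def simulate_hr_dataset(
    n_animals: int,
    seasons: tuple[str, ...] = _SEASONS,
    true_fixed_effects: dict[str, float] | None = None,
    random_intercept_sd: float = 0.3,
    residual_sd: float = 0.3,
    seed: int | np.random.SeedSequence | None = 0,
    intercept: float = 0.0,
) -> pd.DataFrame:
    """Draw a per animal-season driver table with a known mixed-model structure.

    ``true_fixed_effects`` maps predictor names to coefficients; factor levels
    use ``season:summer``, ``sex:male``, ``nucleus:east`` keys. The response is
    ``log_area = intercept + X @ beta + b_animal + eps`` with
    ``b_animal ~ N(0, random_intercept_sd^2)`` and ``eps ~ N(0, residual_sd^2)``.
    """
    if n_animals < 2:
        raise ValueError("need at least 2 animals")
    if len(seasons) < 2:
        raise ValueError("need at least 2 seasons")
    if random_intercept_sd < 0 or residual_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    effects = dict(true_fixed_effects or {})
    rng = np.random.default_rng(seed)

    rows = []
    intercepts = rng.normal(0.0, random_intercept_sd, size=n_animals)
    for a in range(n_animals):
        sex = "male" if a % 2 else "female"
        nucleus = "east" if a < n_animals // 2 else "west"
        for s in seasons:
            row = {
                "animal": f"a{a:03d}",
                "season": s,
                "sex": sex,
                "nucleus": nucleus,
            }
            for name, (lo, hi) in _PREDICTOR_RANGES.items():
                row[name] = rng.uniform(lo, hi)
            if nucleus == "east":  # the eastern nucleus sits lower
                row["altitude"] = rng.uniform(1700.0, 2400.0)
            lp = intercept
            for term, beta in effects.items():
                if ":" in term:
                    factor, level = term.split(":", 1)
                    lp += beta * float(row[factor] == level)
                else:
                    lp += beta * row[term]
            row["log_area"] = lp + intercepts[a] + rng.normal(0.0, residual_sd)
            rows.append(row)
    return pd.DataFrame(rows)
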