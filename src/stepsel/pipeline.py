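"""End-to-end orchestration: simulate a cohort, then run tracks -> iSSA ->
relative selection strength -> home ranges -> home-range-size drivers.

The synthetic cohort mirrors the study design the analysis assumes: animals on
a 4-h fix schedule in two population nuclei whose landscapes differ in
altitude and NDVI seasonality (the western nucleus higher with a strong
seasonal productivity cycle, the eastern lower and more stable), and
sex-specific habitat selection (females favouring steeper slopes, males lower
heat load). Every stage draws its randomness from deterministic children of
one master seed, so a fixed seed reproduces every output table bit for bit.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import drivers as drv
from . import rss as rss_mod
from .homerange import HomeRangeEstimate, estimate_home_range, home_range_table
from .issa import IssaFit, child_seed, fit_issa
from .landscape import Landscape, SeasonalityParams, generate_landscape
from .simulate import SimulationScenario, simulate_track
from .tracks import (
    build_steps,
    clean_track,
    daily_net_displacement,
    regularize,
    season_of_month,
)

__all__ = ["CohortConfig", "simulate_cohort", "run_pipeline", "PipelineResult"]

#: selection coefficients on raw covariate scale, by sex
_SEX_SELECTION = {
    "female": {"slope": 0.10, "heat": -1.0, "heat2": -1.5, "ndvi": 4.0, "ndvi2": -3.0},
    "male": {"slope": 0.06, "heat": -2.5, "ndvi": 3.0, "ndvi2": -2.0},
}

_WEST = SeasonalityParams(altitude_min=2200, altitude_max=3000, ndvi_amp_gradient=0.25)
_EAST = SeasonalityParams(
    altitude_min=1700, altitude_max=2300, ndvi_amp_gradient=0.08, ndvi_mean_low=0.45
)


@dataclass
class CohortConfig:
    n_animals: int = 8
    n_fixes: int = 1100  # ~183 days at 4-h fixes
    candidate_set_size: int = 50
    landscape_dims: tuple[int, int] = (80, 80)
    cell_size: float = 100.0
    gamma_shape: float = 2.0
    # per-animal movement scales span this range: individuals differ in
    # displacement rate, a driver of home-range size
    gamma_scale_range: tuple[float, float] = (90.0, 220.0)
    kappa_range: tuple[float, float] = (0.2, 0.9)
    start_time: _dt.datetime = _dt.datetime(2005, 1, 10)
    master_seed: int = 0


def simulate_cohort(
    config: CohortConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, Landscape]]:
    """Simulate fixes for a two-nucleus cohort.

    Returns (fixes, metadata, landscapes-by-nucleus); animals alternate sex and
    split evenly between nuclei, starting near their landscape's centre with
    staggered start days.
    """
    cfg = config or CohortConfig()
    landscapes = {
        "west": generate_landscape(
            cfg.landscape_dims, cfg.cell_size, _WEST,
            seed=child_seed(cfg.master_seed, "landscape", "west"),
        ),
        "east": generate_landscape(
            cfg.landscape_dims, cfg.cell_size, _EAST,
            seed=child_seed(cfg.master_seed, "landscape", "east"),
        ),
    }
    fixes_parts = []
    meta_rows = []
    traits_rng = np.random.default_rng(child_seed(cfg.master_seed, "traits"))
    scales = traits_rng.uniform(*cfg.gamma_scale_range, size=cfg.n_animals)
    kappas = traits_rng.uniform(*cfg.kappa_range, size=cfg.n_animals)
    for a in range(cfg.n_animals):
        sex = "male" if a % 2 else "female"
        nucleus = "east" if a < cfg.n_animals // 2 else "west"
        land = landscapes[nucleus]
        xmin, ymin, xmax, ymax = land.extent
        scen = SimulationScenario(
            selection=_SEX_SELECTION[sex],
            shape=cfg.gamma_shape,
            scale=float(scales[a]),
            kappa=float(kappas[a]),
            n_fixes=cfg.n_fixes,
            start_xy=(0.5 * (xmin + xmax), 0.5 * (ymin + ymax)),
            start_time=cfg.start_time + _dt.timedelta(days=3 * a),
            candidate_set_size=cfg.candidate_set_size,
            seed=child_seed(cfg.master_seed, "track", a),
            animal_id=f"ibex{a:02d}",
            sex=sex,
            nucleus=nucleus,
        )
        fixes_parts.append(simulate_track(land, scen))
        meta_rows.append({"animal_id": scen.animal_id, "sex": sex, "nucleus": nucleus})
    return (
        pd.concat(fixes_parts, ignore_index=True),
        pd.DataFrame(meta_rows),
        landscapes,
    )


@dataclass
class PipelineResult:
    issa_fits: list[IssaFit]
    issa_table: pd.DataFrame
    hr_estimates: list[HomeRangeEstimate]
    hr_table: pd.DataFrame
    driver_table: pd.DataFrame
    model_ranking: pd.DataFrame | None = None
    best_model: object | None = None
    importance: pd.DataFrame | None = None
    rss_curves: pd.DataFrame | None = None
    displacement_r: float | None = None
    extras: dict = field(default_factory=dict)


def run_pipeline(
    fixes: pd.DataFrame,
    metadata: pd.DataFrame,
    landscapes: dict[str, Landscape],
    master_seed: int = 0,
    n_available: int = 10,
    min_strata: int = 100,
    select_model: bool = True,
    rss_variable: str = "ndvi",
) -> PipelineResult:
    """Run the full analysis on a fix table.

    Per animal: clean (drop first 5 fixes, speed filter), regularize to 4 h,
    build steps and split by season. Per animal-season with at least
    ``min_strata`` usable steps: iSSA (N = ``n_available``) and a kernel home
    range over that season's fixes. The per animal-season results feed the
    driver table, AICc model selection and group importance, plus pooled
    relative-selection-strength curves and the displacement / home-range-size
    correlation.
    """
    meta = metadata.set_index("animal_id")
    fits: list[IssaFit] = []
    hr: list[HomeRangeEstimate] = []
    disp_rows = []
    altitudes: dict[tuple[str, str], float] = {}
    for animal, g in fixes.groupby("animal_id", sort=True):
        land = landscapes[meta.loc[animal, "nucleus"]]
        track = regularize(clean_track(g), interval_h=4.0)
        steps = build_steps(track)
        fix_season = track["timestamp"].dt.month.map(lambda m: season_of_month(int(m)))
        for season, ss in steps.groupby("season", sort=True):
            if ss["cos_ta"].notna().sum() < min_strata:
                continue
            fits.append(
                fit_issa(
                    ss, land, n_available=n_available,
                    seed=child_seed(master_seed, "issa", animal, season),
                    animal_id=animal, season=season,
                )
            )
            sf = track.loc[fix_season == season]
            hr.append(estimate_home_range(sf, animal_id=animal, season=season))
            if "altitude" in sf.columns:
                altitudes[(animal, season)] = float(sf["altitude"].mean())
            else:
                altitudes[(animal, season)] = float(
                    land.value_at("altitude", sf["x"].to_numpy(), sf["y"].to_numpy()).mean()
                )
            nd = daily_net_displacement(sf)
            disp_rows.append(
                {
                    "animal_id": animal,
                    "season": season,
                    "displacement": float(nd["displacement"].median()),
                }
            )

    hr_tab = home_range_table(hr)
    issa_tab = pd.DataFrame([f.summary_row() for f in fits])
    driver_tab = drv.build_driver_table(fits, hr, metadata, altitudes=altitudes)
    result = PipelineResult(
        issa_fits=fits,
        issa_table=issa_tab,
        hr_estimates=hr,
        hr_table=hr_tab,
        driver_table=driver_tab,
    )
    if len(disp_rows) >= 3:
        try:
            r, p = drv.displacement_hr_correlation(pd.DataFrame(disp_rows), hr_tab)
            result.displacement_r = r
            result.extras["displacement_p"] = p
        except ValueError:
            pass
    if fits:
        curves = rss_mod.individual_rss_curves(fits, rss_variable)
        boot = rss_mod.bootstrap_population_rss(
            curves, n_boot=2000, seed=child_seed(master_seed, "rss", rss_variable)
        )
        result.rss_curves = boot.assign(variable=rss_variable)
    if select_model and driver_tab["animal"].nunique() >= 2 and len(driver_tab) >= 12:
        ranking, best, _ = drv.all_subsets_aicc(driver_tab)
        result.model_ranking = ranking
        result.best_model = best
        result.importance = drv.group_importance(driver_tab, best)
        result.extras["marginal_r2"] = drv.marginal_variance_explained(best)
    return result
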