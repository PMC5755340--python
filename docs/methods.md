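# Methods

## The estimation problem

An animal's space use couples two processes: where it *can* go in a fix
interval (the movement kernel) and where it *prefers* to go (habitat
selection). Integrated step-selection analysis (iSSA) estimates both at once
by conditional logistic regression: each observed step is one matched set
(stratum) together with N available steps sharing its start point, and the
likelihood contribution of a stratum is the probability that the used step's
exponential score beats the alternatives'. Because availability is part of
the design, the fitted movement coefficients measure how the *observed* step
lengths and turns deviate from the availability distribution, and algebra on
the gamma family turns that deviation into a selection-free movement kernel.
Downstream, seasonal kernel home ranges are regressed on the per
animal-season iSSA outputs to ask what drives home-range size.

## Step construction (tracks)

- **Cleaning.** The first five fixes are dropped (collar settling), then fixes
  whose straight-line speed to *both* temporal neighbours exceeds a threshold
  (default 10 km/h, configurable) are removed iteratively. The both-neighbour
  rule removes isolated spikes but keeps genuine fast transits; 10 km/h is
  conservative for a large ungulate at multi-hour fixes. Track endpoints,
  having one neighbour, are never flagged.
- **Regularization.** Greedy-forward subsampling to the target interval
  (default 4 h ± 30 min): from each kept fix, the next fix whose gap falls in
  the window is kept; an unbridgeable gap starts a new burst. No
  interpolation. Turn angles are never computed across burst boundaries, so
  the first step of each burst carries no turn angle and is excluded from
  strata.
- **Steps.** Length and heading from the fix pair; turn angle is the wrapped
  heading difference in (−π, π]. Zero-length steps are kept (dropping them
  would bias the gamma fit long) and inherit the previous heading so the next
  turn angle stays defined. Each step's season comes from its end fix's
  month, because covariates are evaluated at end points. Daily net
  displacement is the distance between a day's first and last fix (UTC day
  boundaries by default).

## iSSA details

- **Availability.** Step lengths: gamma fitted by ML (`scipy` with location
  fixed at zero) to the animal-season's observed lengths; zeros are replaced
  by half the smallest positive length first (log and gamma support). Turn
  angles: uniform on (−π, π]. N = 10 available steps per stratum by default.
- **Covariates.** Slope and heat load by nearest-cell lookup; NDVI from the
  stack layer nearest the step's end time, ties resolved to the earlier
  layer (match first, standardize second). Available end points falling off
  the raster are dropped individually; a stratum survives while at least one
  available alternative remains, and is dropped with a warning if its used
  end point leaves the raster. Off-raster alternatives could instead be
  redrawn; truncation was chosen as it mirrors the hard availability boundary
  of a real landscape.
- **Standardization.** Habitat covariates are centred/scaled by the mean and
  SD over *all* alternatives (used + available) within the animal-season —
  availability is the natural baseline — and quadratic terms are squares of
  the standardized value. Movement covariates (l, ln l, cos turn angle) stay
  on their natural scale: the selection-free kernel formula consumes β_l and
  β_ln l in 1/m and dimensionless units and is only coherent on the raw scale.
- **Fitting.** Newton–Raphson on the matched conditional likelihood, starting
  at β = 0 (uniform choice), step-halving, convergence at gradient max-norm
  < 1e−8, at most 100 iterations; the likelihood is concave so this is
  reliable. Standard errors from the inverse observed information. The
  within-stratum-centred design is rank-checked first (errors name the
  collinear terms); estimates passing |β| = 50 are flagged non-identifiable
  (separation). The null log-likelihood is −S ln(N+1) exactly. Pairwise
  Pearson correlations among habitat covariates are reported with an
  |r| ≥ 0.70 flag; flagged pairs do not stop the fit.
- **Kernel update.** Updated gamma shape k + β_ln l and rate θ⁻¹ − β_l;
  l_mean is their ratio when both are positive and flagged undefined
  otherwise (never silently negative). Directional persistence is β_cos
  itself, a von Mises concentration relative to the uniform proposal.
- **Habitat importance.** ΔAIC = AIC(movement-only) − AIC(full) on identical
  strata; habitat is called important when ΔAIC > 2. Under six null habitat
  terms the flag fires at roughly the χ²₆ tail rate (~3%).
- Fits are per animal-season only; no pooled or mixed conditional model.
  One master seed yields deterministic per-(animal, season) child seeds.

## Relative selection strength

log RSS(x₁; x₂) = β₁(z₁ − z₂) + β₂(z₁² − z₂²) on the fit's standardized
scale; movement terms cancel in the matched design and other habitat
variables are held equal. The reference x₂ is the group's 50th percentile of
raw covariate values over all alternatives, and grids span the 1st–99th
percentiles. Population curves: resample individuals with replacement within
the group (2,000 draws by default), report the bootstrap mean and percentile
2.5/97.5 bounds; a single-individual group gets a point estimate with the CI
flagged unavailable. Percentile rather than BCa intervals — the simplest
interval consistent with an individual-level resampling design.

## Home ranges

h_ref = σ·n^(−1/6) with σ² the mean of the two coordinate sample variances
(an alternative dialect, the mean of the two SDs used by some home-range
software, is available via `href_dialect`). The UD evaluates the isotropic
bivariate normal kernel (SD h, truncated at 6h where the neglected mass is
~1e−8) exactly at cell centres on a grid with cell size h/4 and the data
bounding box padded by 4h — this resolves the kernel and keeps mass leakage
below 0.1%; a grid losing more than 1% of kernel mass raises an error.
Isopleths take cells by decreasing density until the target mass is enclosed;
area is cell count × cell area (reported in km² to 2 decimals) and polygons
are unions of the selected cells. All fixes of an animal-season enter the
KDE, including altitudinal-transit fixes — the home-range notion deliberately
includes space covered during gradual seasonal movements. The module's oracle:
a KDE of draws from N(0, σ²I) must match the analytic convolution
N(0, (σ² + h²)I), whose 90% isopleth area is 2πσ_eff² ln 10.

## Home-range-size drivers

Response: log area (90% or 50% isopleth) per animal-season; random intercept
per animal. The LMM is fitted by profiling the likelihood over
λ = σ_b²/σ_e²: given λ the fixed effects are closed-form GLS, and the scalar
profile is maximized numerically with the λ = 0 boundary checked explicitly
(boundary fits are flagged; fixed effects then equal OLS). ML is used for all
AICc comparisons because candidate fixed-effect sets differ; REML is
available for reporting a final model and is used when quoting variance
components. AICc counts all fixed effects plus two variance parameters;
candidates with a non-positive correction denominator are skipped.

Model selection enumerates predictor subsets at the *group* level (season,
sex, nucleus, altitude, movement, selection, availability → 2⁷ = 128
candidates). Term-level enumeration over ~16 predictors (≈65k mixed-model
fits) is possible via a custom `group_defs` but the group level preserves the
inferential structure at a fraction of the cost, and quadratic selection
coefficients belong to their variable's group either way. Ties in AICc break
to fewer parameters, then lexicographically. A group's importance is the
AICc increase when it is removed from the best model and the model refitted
(refit-from-best, the stricter of the two possible accountings). Marginal
variance explained = var(Xβ̂)/(var(Xβ̂) + σ_b² + σ_e²). The availability CVs
are SD/mean over the available alternatives' raw values; NDVI is shifted to
[0, 2] before its CV so near-zero means cannot inflate it. Daily net
displacement is summarized per animal-season by its median before the
log-log Pearson correlation with area.

## The simulator and what it does (not) show

`simulate_track` inverts the estimator: per step it draws C candidates
(gamma lengths, von Mises turns centred forward; uniform heading for the
first step), scores candidate end points with raw-scale selection
coefficients, and picks one ∝ exp(score). Finite C is an approximation that
converges to the continuous kernel as C grows; C = 50 by default. At C = 50
a small discretization bias (up to ~0.05 on strongly selected standardized
terms) is measurable, which is why the recovery studies use moderate
coefficient magnitudes; at C = 200 the bias is below Monte-Carlo noise.
Candidates leaving the landscape are discarded and redrawn (truncation, the
same convention the estimator applies to off-raster availability); if every
candidate is off-landscape for over 100 consecutive redraws the simulator
raises naming the step index. Optional fix drop-out and coordinate jitter
exist for robustness experiments and default off.

Landscapes are synthetic: altitude = linear ramp + correlated Gaussian
relief; slope = gradient magnitude of that surface; heat load = an
independent smooth field rescaled to [0, 1] (generated directly — deriving a
heat-load index from a DEM is out of scope); NDVI(cell, t) = mean(z) +
amp(z)·cos(2π(doy − peak)/365.25) with mean decreasing and amplitude
increasing in altitude, so altitude and NDVI correlate positively in
midsummer and negatively in midwinter, the characteristic high-mountain
pattern. The default two-nucleus cohort gives the western nucleus higher
altitude and stronger NDVI seasonality, the eastern a higher, flatter NDVI
mean; females favour steeper slopes and males lower heat load; animals differ
individually in movement scale and persistence, which makes selection-free
movement a genuine driver of home-range size.

What passing recovery tests show: the estimators invert the generative model
they assume. What they cannot show: robustness to real-data violations —
autocorrelated fix errors, behavioural states, non-gamma step lengths,
covariate misregistration — none of which the simulator emulates.

## Problem sizes and numerical choices

Recovery studies use 30 animal-seasons × 1,500 steps (iSSA), 200 replicates
of 1,000 strata (AIC importance rates), 200 cohorts of 40 animals × 4
seasons (LMM), and 10,000-point KDEs — sizes at which Monte-Carlo error is
well below the effects being checked while a full validation run stays in the
minutes range on one core. Seeds: every study derives integer child seeds
from one master seed via `SeedSequence`; identical seeds reproduce every
table byte for byte. Degenerate inputs are errors, not warnings: identical
step lengths (gamma ML diverges), zero-spread point sets (h_ref), zero
variance in a habitat covariate (standardization), fewer than two animals
(LMM).

## Known limitations

- No mixed-effects (population-level) conditional logit; inference pools
  individual fits via the bootstrap only.
- The LMM has a single variance component; no random slopes, spatial or
  temporal autocorrelation.
- Kernel home ranges only (no autocorrelated-kernel or bridge estimators);
  h_ref over-smooths strongly clustered use.
- CRS handling is the caller's job: coordinates must arrive in projected
  metres, and tables that look geographic are rejected rather than
  reprojected.
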