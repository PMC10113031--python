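# Methods note

This note records what each stage of the `ecolag` pipeline computes, the
default parameter values and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical choices that affect
results.

## 1. Population trends (`ecolag.trends`)

**Input.** An abundance time series: observation years (integers, strictly
increasing) and non-negative abundance values, plus population metadata
(species binomial, taxon class, coordinates, realm, protection/management/use
flags, location identifier).

**Eligibility.** A series enters the analysis only if its monitoring span
(last year − first year) is at least 5 years *and* it has at least 3
observations. Shorter or sparser series cannot support even the linear trend
model.

**Preprocessing.** Zeros are replaced by 1 % of the mean of the non-zero
observations (a log-scale placeholder well below the observed range). If any
*observed* non-zero value is below 1, the whole series — including replaced
zeros — is shifted by +1 so that log10 values stay non-negative for sub-unit
counts. The trigger is the observed values, not the zero replacements:
replacing a zero in an otherwise large-count series must not rescale the
series.

**Interpolation and trend.** Trends are computed on the log10 scale on the
full annual grid between the first and last observation year:

- fewer than 6 observations: ordinary least squares of log10 abundance on
  year (a straight line);
- 6 or more observations: an unpenalized B-spline regression
  (`patsy.bs` basis) with degrees of freedom ⌈n/2⌉, clipped to
  [4, n − 1], and spline degree min(3, df − 1). Half the number of data
  points is a standard default for smoother flexibility: enough to track
  decadal fluctuations without interpolating through every observation.

The population trend is the mean annual log10 change of the interpolated
series, which telescopes to

λ̄ = (log10 N_T − log10 N_1) / (T − 1),

where N_1 and N_T are the interpolated endpoint values. λ̄ is invariant to
multiplying the series by a constant (units of abundance do not matter).

**Quality filter.** Populations whose trend model has adjusted R² ≤ 0 are
removed: the fitted trend explains less than a constant would, so λ̄ is not a
meaningful summary of the trajectory. `compute_trends` reports the count
removed at each stage (`input`, `eligibility_removed`, `r2_filter_removed`,
`retained`).

**Influence screen.** After a mixed model is fitted, `influence_screen`
recomputes the fixed effects with each population deleted in turn and scores
the coefficient shift as (Δβ)ᵀ V⁻¹ (Δβ)/p, with V the coefficient covariance
and p the number of coefficients (a Cook's-distance-style statistic).
Populations with score > 0.5 are flagged so the model can be refitted without
them; 0.5 is the conventional "worth investigating" threshold for this
statistic.

## 2. Driver rates and lags (`ecolag.environment`)

Each population's location has annual environmental trajectories: mean annual
temperature (°C) and the anthropogenic land fraction (cropland + pasture +
rangeland, in [0, 1]).

- **CC** (climate-change rate) over a window is the OLS slope of temperature
  on year, in °C/yr — robust to interannual noise, unlike an endpoint
  difference.
- **LUC** (land-use-change rate) is the mean of the annual differences of the
  anthropogenic fraction, in fraction/yr. For land use, which is close to
  piecewise-monotone, the mean annual difference equals the endpoint rate and
  is the natural discrete analogue of a derivative.

A candidate lag ℓ shifts the monitoring window [s, e] to [s − ℓ, e − ℓ];
rates are evaluated over the shifted window, which has the same length as the
monitoring span. A lag is admissible only if the shifted window stays inside
environmental coverage. With abundance monitoring from 1950 and environmental
data from 1901, the largest admissible year lag is 49, hence the default year
grid 0–49 (2500 lag pairs).

Lags may instead be expressed in generation lengths: multipliers 0.3–3.1 in
steps of 0.1 for birds (29 values) and 0.3–2.3 for mammals (21 values), an
ecologically motivated range from sub-generational to multi-generational
response times, with the narrower mammal range keeping long-generation
species inside data coverage. Generations convert to integer year lags by
round-half-up: ⌊m·g + 0.5⌋ for multiplier m and generation length g. The
full default grid therefore has 2500 + 29² = 3341 combinations for birds and
2500 + 21² = 2941 for mammals per fixed-effect structure.

## 3. Lag models (`ecolag.lag_models`)

**Design.** For a given lag pair, the design joins trends, lagged driver
rates, and traits. CC, LUC and log10 body mass are z-scored (the scaling is
stored so predictions can be made on natural units). Rows with missing body
mass are dropped.

**Model.** A linear mixed-effects model fitted by maximum likelihood
(`statsmodels` `MixedLM` in its variance-components formulation, which
handles crossed grouping factors):

- fixed effects, by structure:
  - `Base`: λ̄ ~ cc * luc + bm + pa
  - `MU`: Base + man + use
  - `R`: Base + realm
  - `MUR`: Base + man + use + realm
  - `Null`: λ̄ ~ 1
- random effects: crossed random intercepts for species and for location,
  encoded as two variance components over indicator matrices. The
  single-group random intercept that would otherwise be added is dropped
  (`re_formula="0"`) because it is unidentifiable alongside the fixed
  intercept.

ML rather than REML is used because models with different fixed effects are
compared by information criterion, and REML likelihoods are not comparable
across fixed-effect structures.

**Optimizer.** Each fit runs L-BFGS and then a Powell polish warm-started
from the L-BFGS solution (profiled `MixedLMParams`); on crossed designs of a
few hundred rows L-BFGS alone can stall slightly short of the optimum, and
the polish closes the gap (verified against an independent mixed-model
implementation to < 0.01 log-likelihood units). During a lag scan each fit is
warm-started from the previous lag's optimum, which is both faster (~5×) and
never worse in log-likelihood than a cold start.

**Model comparison.** The parameter count is k = (number of fixed effects) +
2 variance components + 1 residual variance, and

AICc = −2ℓ + 2k + 2k(k + 1)/(n − k − 1).

Models within ΔAICc < 6 of the best are retained (a conventional
"substantial support" band). Akaike weights w_i ∝ exp(−Δ_i/2) are computed
over the scanned set and renormalized over the retained set for averaging.
Model-averaged coefficients use the renormalized weights; a coefficient
absent from a retained model contributes zero with its weight (shrinkage
averaging). The **lag support profile** sums retained weights per candidate
lag separately for each driver.

**Subsets.** `make_subsets` builds trait-based data subsets: body-mass
tertiles (species-level log10 mass, tertile boundaries at the 1/3 and 2/3
quantiles, ties to the lower tertile), trophic groups, and tropical
(|latitude| ≤ 23.5°) versus temperate populations.

## 4. Projection (`ecolag.projection`)

Decades 2010–2020, 2020–2030, 2030–2040, 2040–2050 (11-year inclusive
windows). For each scenario, decade, and retained model, driver rates are
evaluated over the decade window shifted back by that model's lags, the
population-level trend is predicted from the fixed effects (plus any
available random-effect BLUPs), and populations are averaged hierarchically:
populations within species, species within realms, realms within the class.
Model-averaged decadal trends λ̄_d give an abundance index anchored at 1 in
2010:

I_d = I_{d−1} · 10^(10 · λ̄_d).

Each decade × driver is classified by lock-in: **fully** dependent on
historical change if the lagged window ends at or before 2010, **not**
dependent if it starts at or after 2010, **partially** otherwise. Fully
locked-in decades are provably scenario-invariant when scenarios share their
pre-divergence history, and the test suite checks this.

## 5. Synthetic data (`ecolag.synthetic`)

The generator emulates the *structure* of a multi-population monitoring
compilation with environmental covariates:

- per-location temperature: a linear trend (mean 0.02 °C/yr, SD 0.015 across
  locations) plus interannual noise (SD 0.3 °C), spanning 1901–2100;
- per-location anthropogenic fraction: a logistic ramp clipped to [0, 1] with
  small noise; scenarios share history and diverge in 2015 by multiplying
  post-divergence increments by 0.5 / 1.5 / 2.0 (three stylized futures);
- traits: species generation length, body mass, trophic group; population
  flags for protection, management and use;
- true trends: λ̄ built from the generating linear formula with z-scored
  covariates evaluated at the *true* lags (defaults: CC lag 6 yr, LUC lag
  2 yr) plus species, location and residual noise (SDs 0.005/0.005/0.008 —
  random effects comparable to the fixed-effect signal, residual slightly
  larger);
- abundance: exponentiated log10 trajectories with observation noise
  (default 0.02 log10 units), random missingness (10 %) that preserves the
  endpoints, and optional injected zeros. Declining populations start
  proportionally higher so the deterministic trajectory does not cross
  abundance 1 — a population observed declining for decades started large,
  and without this the sub-unit +1 shift would distort λ̄ for extreme
  decliners.

Default effect sizes (cc −0.04, luc −0.03, cc:luc −0.02, bm +0.01,
pa +0.015, man +0.02, use −0.03, intercept −0.005, in λ̄ units per SD of the
z-scored covariate) are chosen so that driver effects are clearly detectable
at a few hundred populations without being trivially large.

The generator does **not** emulate: observation-effort or detectability
models, spatial autocorrelation between locations, density dependence or
population dynamics (trajectories are trend + noise), taxonomic imbalance,
or reporting biases. It is a recovery benchmark, not a data simulator for
ecological inference.

**Recovery benchmark** (`ecolag.experiments.run_lag_recovery`). Ten
replicates, each: simulate (~300 populations, 60 species), scan a reduced
0–10 × 0–10 year-lag grid (121 fits) with the Base structure, and check
(a) that the summed-weight modal lags equal the generating pair and (b) how
many model-averaged coefficients fall within 2 SE of their generating values.
The benchmark configuration uses the Base-matching generator (management/use
effects zero), no injected zeros, observation noise 0.01 and large initial
abundances, so that what is measured is lag-scan and coefficient recovery
rather than the preprocessing rules (which have their own unit tests). The
reduced grid keeps the ten-replicate benchmark around ten minutes on one CPU;
the full 2500-point grid would measure the same thing at ~20× the cost.
Replicate seeds are derived from the top-level seed via
`numpy.random.SeedSequence` and masked below 2³¹.

## 6. Numerical choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; reruns are bit-reproducible (tested on the
  pipeline outputs).
- Generation→year conversion is round-half-up, not banker's rounding, so
  half-year boundaries resolve deterministically upward.
- AICc uses the k convention above (fixed + 2 + 1) for every structure,
  including Null, so structures are compared on a consistent penalty.
- Akaike weights are computed by subtracting the minimum AICc before
  exponentiation (no overflow); non-finite AICc values get weight 0.
- The ΔAICc retention threshold is 6 and the influence threshold 0.5; both
  are conventional values and are parameters of the corresponding functions.
- Interpolated trends evaluate the fitted curve on the annual grid; λ̄ then
  depends only on the fitted endpoint values (telescoping), which the test
  suite verifies to 1e-12.

## 7. Limitations

- The B-spline trend smoother is unpenalized; its flexibility is set by the
  ⌈n/2⌉ basis-dimension rule rather than chosen by cross-validation, so very
  noisy long series can yield wiggly interpolations.
- Crossed random effects are fitted via variance components in a single
  group, which is exact but slower than specialized sparse solvers; scans
  over the full lag grid for several structures are CPU-intensive (minutes
  to hours, mitigated by warm starts).
- Lag selection by AICc over a grid treats lags as model indices; no
  continuous-lag uncertainty interval is produced beyond the summed-weight
  profile.
- Projections extrapolate a linear trend model outside the fitted covariate
  range; scenario index paths decades ahead should be read as model
  propagation, not forecasts.
- The coefficient-recovery criterion is pooled 2-SE coverage across
  replicates (nominally ~95 %), not per-replicate joint coverage, which for
  six coefficients would be far below its nominal level by construction.
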