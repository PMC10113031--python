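"""Synthetic Living-Planet-style data with known lag structure.

Generates abundance time-series, gridded-style environmental series and
species traits whose statistical structure mirrors the real inputs of the
lagged-driver analysis: noisy exponential-trend abundance with missing years
and occasional zeros; trended mean annual temperature with interannual noise;
smooth, roughly monotone anthropogenic land-cover fractions in [0, 1]; and
three diverging post-2015 scenario trajectories. The generating model for
each population's trend is the same fixed-effect structure the analysis fits
(CC*LUC + BM + PA + Man + Use with species and location random intercepts),
so recovery of the generating lags and coefficients is a meaningful
end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import EnvSeries, climate_rate, landuse_rate, lag_window
from .trends import AbundanceSeries

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticEnvironment",
    "generate_environment",
    "generate_populations",
    "simulate",
    "SCENARIOS",
]

# Post-divergence trend multipliers; monotone ordering makes projection
# tests directional (SSP1 mildest, SSP5 most intense).
SCENARIOS: dict[str, float] = {"SSP1": 0.5, "SSP3": 1.5, "SSP5": 2.0}


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults define the study conditions.

    ``beta`` is the generating coefficient set on the lambda-bar scale (per
    year), applied to z-scored CC/LUC/BM covariates and 0/1 flags. True lags
    are in whole years. ``sigma_resid`` is population-level trend noise;
    ``obs_noise`` is multiplicative log-normal observation noise on abundance
    (log10-scale standard deviation).
    """

    n_species: int = 60
    pops_per_species: tuple[int, int] = (3, 7)
    year_span: tuple[int, int] = (1950, 2014)
    env_span: tuple[int, int] = (1901, 2100)
    true_lag_cc: int = 6
    true_lag_luc: int = 2
    beta: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": -0.005,
            "cc": -0.04,
            "luc": -0.03,
            "cc_luc": -0.02,
            "bm": 0.01,
            "pa": 0.015,
            "man": 0.02,
            "use": -0.03,
        }
    )
    sigma_species: float = 0.005
    sigma_location: float = 0.005
    sigma_resid: float = 0.008
    obs_noise: float = 0.02
    missingness: float = 0.1
    zero_rate: float = 0.02
    n1_log10_range: tuple[float, float] = (1.5, 3.0)  # initial abundance 10^lo..10^hi
    taxon_class: str = "bird"
    divergence_year: int = 2015
    temp_trend_mean: float = 0.02  # degC / yr
    temp_trend_sd: float = 0.015
    temp_noise_sd: float = 0.3
    luc_noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        known = {"intercept", "cc", "luc", "cc_luc", "bm", "pa", "man", "use"}
        extra = set(self.beta) - known
        if extra:
            raise ValueError(f"beta references unknown covariates: {sorted(extra)}")
        for name in ("sigma_species", "sigma_location", "sigma_resid", "obs_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("missingness", "zero_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.year_span[1] < self.year_span[0] or self.env_span[1] < self.env_span[0]:
            raise ValueError("non-positive span")
        max_lag = max(self.true_lag_cc, self.true_lag_luc)
        if self.year_span[0] - max_lag < self.env_span[0]:
            raise ValueError("env_span does not cover the lagged windows")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated dataset.

    ``table`` has one row per population: the z-scored generating covariates,
    flags, random intercepts, expected trend (the model formula applied to
    those covariates) and the realized trend (expected plus residual noise)
    that built the abundance series.
    """

    table: pd.DataFrame
    beta: dict[str, float]
    true_lag_cc: int
    true_lag_luc: int
    scaling: dict[str, tuple[float, float]]

    def expected_from_formula(self) -> pd.Series:
        """Recompute expected lambda-bar from stored covariates and betas."""
        t, b = self.table, self.beta
        return (
            b["intercept"]
            + b["cc"] * t["cc_z"]
            + b["luc"] * t["luc_z"]
            + b["cc_luc"] * t["cc_z"] * t["luc_z"]
            + b["bm"] * t["bm_z"]
            + b["pa"] * t["pa"]
            + b["man"] * t["man"]
            + b["use"] * t["use"]
            + t["u_species"]
            + t["u_location"]
        )


@dataclass
class SyntheticEnvironment:
    """Historical series per location plus named scenario variants."""

    historical: dict[str, EnvSeries]
    scenarios: dict[str, dict[str, EnvSeries]]
    divergence_year: int


def generate_environment(config: SyntheticConfig, n_locations: int) -> SyntheticEnvironment:
    """Per-location temperature and land-use series over the environment span.

    Temperature is a per-location linear trend plus independent interannual
    noise; the anthropogenic fraction is a logistic-style ramp with small
    noise, clipped to [0, 1]. After the divergence year the three scenario
    variants rescale the post-divergence increments by their trend
    multipliers, sharing history exactly.
    """
    if n_locations < 1:
        raise ValueError("n_locations must be at least 1")
    y0, y1 = config.env_span
    if y1 < y0:
        raise ValueError("non-positive environment span")
    years = np.arange(y0, y1 + 1)
    div_idx = np.searchsorted(years, config.divergence_year)
    rng = np.random.default_rng([config.seed, 1])
    historical: dict[str, EnvSeries] = {}
    scenarios: dict[str, dict[str, EnvSeries]] = {s: {} for s in SCENARIOS}
    for i in range(n_locations):
        loc = f"loc{i:04d}"
        base_t = rng.uniform(-5.0, 25.0)
        trend = rng.normal(config.temp_trend_mean, config.temp_trend_sd)
        t_noise = rng.normal(0.0, config.temp_noise_sd, size=years.size)
        temp = base_t + trend * (years - y0) + t_noise

        f0 = rng.uniform(0.0, 0.2)
        f1 = rng.uniform(0.3, 0.9)
        mid = rng.uniform(1950, 2010)
        rate = rng.uniform(10.0, 40.0)
        ramp = f0 + (f1 - f0) / (1.0 + np.exp(-(years - mid) / rate))
        a_noise = rng.normal(0.0, config.luc_noise_sd, size=years.size)
        anthro = np.clip(ramp + a_noise, 0.0, 1.0)

        historical[loc] = EnvSeries(loc, years, temp, anthro)
        for name, mult in SCENARIOS.items():
            t_s = temp.copy()
            a_s = anthro.copy()
            if div_idx < years.size:
                t_s[div_idx:] = temp[div_idx] + mult * (temp[div_idx:] - temp[div_idx])
                a_s[div_idx:] = np.clip(
                    anthro[div_idx] + mult * (anthro[div_idx:] - anthro[div_idx]), 0.0, 1.0
                )
            scenarios[name][loc] = EnvSeries(loc, years, t_s, a_s)
    return SyntheticEnvironment(historical, scenarios, config.divergence_year)


def _zscore(x: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    mu, sd = float(np.mean(x)), float(np.std(x))
    if sd == 0.0:
        return x - mu, (mu, 1.0)
    return (x - mu) / sd, (mu, sd)


def generate_populations(
    config: SyntheticConfig,
    environment: SyntheticEnvironment,
) -> tuple[list[AbundanceSeries], pd.DataFrame, SyntheticTruth]:
    """Abundance series, traits table and ground truth for one dataset.

    Each population's expected trend follows the generating fixed-effect
    formula with species and location random intercepts; abundance is
    N_1 * 10^(lambda * (t - t_1)) with multiplicative log-normal observation
    noise, thinned by missingness and (for large-valued series) injected with
    occasional zeros. Traits (body mass, a generation length positively
    correlated with body mass, diet fractions) are attached per species.
    Returns (series, traits, truth).
    """
    rng = np.random.default_rng([config.seed, 2])
    locations = sorted(environment.historical)
    n_loc = len(locations)
    y0, y1 = config.year_span

    species = [f"sp{i:03d}" for i in range(config.n_species)]
    log_bm = rng.normal(1.8, 1.0, size=config.n_species)  # log10 grams
    # Generation length log-normal, positively correlated with body mass.
    gen_len = np.exp(0.3 + 0.45 * (log_bm - log_bm.mean()) + rng.normal(0, 0.25, config.n_species))
    diet_animal = rng.beta(0.6, 0.6, size=config.n_species)
    u_species = rng.normal(0.0, config.sigma_species, size=config.n_species)
    u_location = rng.normal(0.0, config.sigma_location, size=n_loc)
    realms = np.array(["Palearctic", "Nearctic", "Afrotropical", "Neotropical", "Indomalayan"])

    traits = pd.DataFrame(
        {
            "binomial": species,
            "body_mass": 10.0 ** log_bm,
            "generation_length": gen_len,
            "diet_animal_frac": diet_animal,
            "diet_plant_frac": 1.0 - diet_animal,
        }
    ).set_index("binomial")

    lo, hi = config.pops_per_species
    rows = []
    for si, sp in enumerate(species):
        n_pops = int(rng.integers(lo, hi + 1))
        for _ in range(n_pops):
            li = int(rng.integers(0, n_loc))
            start = int(rng.integers(y0 + 10, y0 + 41))
            length = int(rng.integers(15, 36))
            end = min(start + length - 1, y1)
            rows.append(
                {
                    "species_idx": si,
                    "binomial": sp,
                    "location_idx": li,
                    "location": locations[li],
                    "start": start,
                    "end": end,
                    "pa": int(rng.random() < 0.3),
                    "man": int(rng.random() < 0.2),
                    "use": int(rng.random() < 0.3),
                    "realm": realms[int(rng.integers(0, realms.size))],
                }
            )
    meta = pd.DataFrame(rows)
    meta["population_id"] = [f"pop{i:04d}" for i in range(len(meta))]

    # Generating covariates: lag-offset CC / LUC rates over each pop's window.
    cc_raw, luc_raw = [], []
    env_start = config.env_span[0]
    for r in meta.itertuples():
        env = environment.historical[r.location]
        cw = lag_window((r.start, r.end), config.true_lag_cc, env_start)
        lw = lag_window((r.start, r.end), config.true_lag_luc, env_start)
        cc_raw.append(climate_rate(env.window(*cw).temperature))
        luc_raw.append(landuse_rate(env.window(*lw).anthro))
    cc_z, cc_sc = _zscore(np.array(cc_raw))
    luc_z, luc_sc = _zscore(np.array(luc_raw))
    bm_z, bm_sc = _zscore(log_bm[meta["species_idx"].to_numpy()])

    b = config.beta
    expected = (
        b["intercept"]
        + b["cc"] * cc_z
        + b["luc"] * luc_z
        + b["cc_luc"] * cc_z * luc_z
        + b["bm"] * bm_z
        + b["pa"] * meta["pa"].to_numpy()
        + b["man"] * meta["man"].to_numpy()
        + b["use"] * meta["use"].to_numpy()
        + u_species[meta["species_idx"].to_numpy()]
        + u_location[meta["location_idx"].to_numpy()]
    )
    resid = rng.normal(0.0, config.sigma_resid, size=len(meta))
    realized = expected + resid

    series: list[AbundanceSeries] = []
    for i, r in enumerate(meta.itertuples()):
        yrs = np.arange(r.start, r.end + 1)
        # Declining populations start proportionally higher so the trend stays
        # on the observable scale (a 30-year monitored decline implies a large
        # starting population); avoids floor artifacts from the sub-unit shift.
        n1_exp = rng.uniform(*config.n1_log10_range)
        n1_exp += max(0.0, -realized[i] * (yrs.size - 1))
        log_n = n1_exp + realized[i] * (yrs - r.start)
        if config.obs_noise > 0:
            log_n = log_n + rng.normal(0.0, config.obs_noise, size=yrs.size)
        vals = 10.0 ** log_n
        # Thin interior years; endpoints kept so the monitoring span is stable.
        keep = rng.random(yrs.size) >= config.missingness
        keep[0] = keep[-1] = True
        yrs_o, vals_o = yrs[keep], vals[keep]
        if config.zero_rate > 0 and vals_o.mean() >= 1.0:
            zeros = rng.random(yrs_o.size) < config.zero_rate
            # Never zero out everything.
            if zeros.all():
                zeros[0] = False
            vals_o = np.where(zeros, 0.0, vals_o)
        series.append(
            AbundanceSeries(
                population_id=r.population_id,
                binomial=r.binomial,
                taxon_class=config.taxon_class,
                latitude=float(rng.uniform(-60, 70)),
                longitude=float(rng.uniform(-180, 180)),
                realm=r.realm,
                pa=r.pa,
                man=r.man,
                use=r.use,
                years=yrs_o,
                values=vals_o,
                location=r.location,
            )
        )

    truth_table = pd.DataFrame(
        {
            "population_id": meta["population_id"],
            "binomial": meta["binomial"],
            "location": meta["location"],
            "cc_raw": cc_raw,
            "luc_raw": luc_raw,
            "cc_z": cc_z,
            "luc_z": luc_z,
            "bm_z": bm_z,
            "pa": meta["pa"],
            "man": meta["man"],
            "use": meta["use"],
            "u_species": u_species[meta["species_idx"].to_numpy()],
            "u_location": u_location[meta["location_idx"].to_numpy()],
            "expected_lambda": expected,
            "lambda_true": realized,
        }
    ).set_index("population_id")
    truth = SyntheticTruth(
        table=truth_table,
        beta=dict(b),
        true_lag_cc=config.true_lag_cc,
        true_lag_luc=config.true_lag_luc,
        scaling={"cc": cc_sc, "luc": luc_sc, "bm": bm_sc},
    )
    return series, traits, truth


def simulate(
    config: SyntheticConfig,
    n_locations: int | None = None,
) -> tuple[list[AbundanceSeries], pd.DataFrame, SyntheticEnvironment, SyntheticTruth]:
    """Generate environment, populations, traits and truth in one call."""
    if n_locations is None:
        expected_pops = config.n_species * (sum(config.pops_per_species) / 2)
        n_locations = max(2, int(expected_pops // 2))
    env = generate_environment(config, n_locations)
    series, traits, truth = generate_populations(config, env)
    return series, traits, env, truth
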