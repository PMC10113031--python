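"""Decadal abundance-index projection under socio-economic scenarios.

Retained lag models are pushed forward from 2010: for each population,
scenario, decade and model, lag-offset CC and LUC rates are computed on the
scenario trajectory, the fixed-effect predictor gives a per-population trend,
trends are hierarchically averaged (populations -> species -> realm -> class),
model-averaged with renormalized Akaike weights, and chained into a relative
abundance index anchored at 1 in 2010 via I_d = I_{d-1} * 10^(10 * lambda_d).
Because lags reach backwards, early decades can depend wholly or partly on
pre-2010 environmental change ('locked-in' trends), which the dependence
classifier tags per driver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import DriverRates, EnvSeries, LagSpec, climate_rate, landuse_rate, lag_window
from .lag_models import FittedModel, FittedModelSet

__all__ = [
    "DECADES",
    "decade_rates",
    "predict_population_trend",
    "hierarchical_average",
    "model_average_trend",
    "index_path",
    "dependence_classification",
    "project_index",
]

# Decade windows share boundary years: [start, start + 10] inclusive gives 11
# annual values for rate fitting, matching the monitoring-window convention.
DECADES: list[tuple[int, int]] = [(2010, 2020), (2020, 2030), (2030, 2040), (2040, 2050)]
BASELINE_YEAR = 2010


def decade_rates(
    population_id: str,
    trajectory: EnvSeries,
    lag: LagSpec,
    decade: tuple[int, int],
    generation_length: float | None = None,
) -> DriverRates:
    """Lag-offset CC and LUC rates for one decade of a scenario trajectory."""
    from .environment import generations_to_years

    if lag.currency == "generations":
        if generation_length is None:
            raise ValueError("generation currency needs a generation length")
        cc_lag = generations_to_years(lag.cc_lag, generation_length)
        luc_lag = generations_to_years(lag.luc_lag, generation_length)
    else:
        cc_lag, luc_lag = int(lag.cc_lag), int(lag.luc_lag)
    env_start = trajectory.span[0]
    cc_win = lag_window(decade, cc_lag, env_start)
    luc_win = lag_window(decade, luc_lag, env_start)
    cc = climate_rate(trajectory.window(*cc_win).temperature)
    luc = landuse_rate(trajectory.window(*luc_win).anthro)
    return DriverRates(population_id, cc, luc, cc_lag, luc_lag)


def predict_population_trend(
    model: FittedModel,
    cc: float,
    luc: float,
    bm_log10: float,
    pa: int,
    man: int,
    use: int,
    realm: str | None = None,
    species: str | None = None,
    location: str | None = None,
) -> float:
    """Fixed-effect linear predictor on the lambda-bar scale.

    Raw CC/LUC/BM inputs are standardized with the scaling constants stored
    at fit time (coefficients are on the scaled scale). Random intercepts
    default to zero; for populations in the fitting data the stored species
    and location intercepts are added when keys are supplied.
    """
    if model.scaling is None:
        raise ValueError("model carries no scaling constants")
    z = {}
    for name, raw in (("cc", cc), ("luc", luc), ("bm", bm_log10)):
        mu, sd = model.scaling[name]
        z[name] = (raw - mu) / sd
    p = model.params
    pred = float(p.get("Intercept", 0.0))
    pred += float(p.get("cc", 0.0)) * z["cc"]
    pred += float(p.get("luc", 0.0)) * z["luc"]
    pred += float(p.get("cc:luc", 0.0)) * z["cc"] * z["luc"]
    pred += float(p.get("bm", 0.0)) * z["bm"]
    pred += float(p.get("pa", 0.0)) * pa
    pred += float(p.get("man", 0.0)) * man
    pred += float(p.get("use", 0.0)) * use
    if realm is not None:
        key = f"C(realm)[T.{realm}]"
        pred += float(p.get(key, 0.0))
    if model.random_effects:
        if species is not None:
            pred += model.random_effects.get("species", {}).get(species, 0.0)
        if location is not None:
            pred += model.random_effects.get("location", {}).get(location, 0.0)
    return pred


def hierarchical_average(per_population: pd.DataFrame) -> float:
    """Population -> species -> realm -> class unweighted mean of trends.

    ``per_population`` needs columns ``lambda_hat``, ``binomial`` and
    ``realm``; every population belongs to the one class being averaged.
    """
    if per_population.empty:
        raise ValueError("no populations to average")
    by_species = per_population.groupby(["realm", "binomial"])["lambda_hat"].mean()
    by_realm = by_species.groupby(level="realm").mean()
    return float(by_realm.mean())


def model_average_trend(trends: np.ndarray, weights: np.ndarray) -> float:
    """Akaike-weighted mean of per-model class trends."""
    trends = np.asarray(trends, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if trends.shape != weights.shape:
        raise ValueError("trend/weight length mismatch")
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1 (renormalize over the retained set)")
    return float(np.dot(trends, weights))


def index_path(decadal_lambdas: list[float], start_year: int = BASELINE_YEAR) -> pd.Series:
    """Relative abundance index anchored at 1 in the baseline year.

    Each decade multiplies the index by 10^(10 * lambda-bar of that decade).
    """
    lams = np.asarray(decadal_lambdas, dtype=float)
    if not np.all(np.isfinite(lams)):
        raise ValueError("non-finite decadal trend")
    years = [start_year + 10 * i for i in range(lams.size + 1)]
    idx = np.concatenate([[1.0], np.cumprod(10.0 ** (10.0 * lams))])
    return pd.Series(idx, index=years, name="index")


def dependence_classification(
    lag: LagSpec,
    decade: tuple[int, int],
    baseline_year: int = BASELINE_YEAR,
    generation_length: float | None = None,
) -> dict[str, str]:
    """Per-driver dependence of a projected decade on pre-baseline environment.

    'fully' if the lag-offset window ends at or before the baseline year,
    'partially' if it straddles it, 'not' if it starts at or after it.
    """
    from .environment import generations_to_years

    out = {}
    for driver, lag_val in (("cc", lag.cc_lag), ("luc", lag.luc_lag)):
        if lag.currency == "generations":
            if generation_length is None:
                raise ValueError("generation currency needs a generation length")
            lag_years = generations_to_years(lag_val, generation_length)
        else:
            lag_years = int(lag_val)
        w0, w1 = lag_window(decade, lag_years)
        if w1 <= baseline_year:
            out[driver] = "fully"
        elif w0 >= baseline_year:
            out[driver] = "not"
        else:
            out[driver] = "partially"
    return out


def project_index(
    model_set: FittedModelSet,
    pop_meta: pd.DataFrame,
    traits: pd.DataFrame,
    scenario_env: dict[str, dict[str, EnvSeries]],
    taxon_class: str,
    decades: list[tuple[int, int]] | None = None,
    generation_lengths: dict[str, float] | None = None,
    use_random_effects: bool = True,
) -> pd.DataFrame:
    """Class-level projected trends and index paths for every scenario.

    ``pop_meta`` (indexed by population_id) supplies binomial, location,
    realm, pa, man, use for the modelled populations; ``scenario_env`` maps
    scenario -> location -> trajectory. Returns a long table with one row per
    scenario x decade: lambda-bar, index value, and per-driver dependence
    tags taken from the best (lowest-AICc) retained model's lags.
    """
    decades = decades or DECADES
    retained = model_set.retained
    if not retained:
        raise ValueError("no retained models to project")
    weights = model_set.retained_weights
    traits_bm = np.log10(traits["body_mass"])

    rows = []
    for scenario, env in scenario_env.items():
        lambda_by_decade = []
        for decade in decades:
            per_model = []
            for fm in retained:
                preds = []
                for pid, r in pop_meta.iterrows():
                    gl = (
                        generation_lengths.get(r["binomial"]) if generation_lengths else None
                    )
                    rates = decade_rates(pid, env[r["location"]], fm.lag, decade, gl)
                    preds.append(
                        {
                            "lambda_hat": predict_population_trend(
                                fm,
                                rates.cc,
                                rates.luc,
                                float(traits_bm.loc[r["binomial"]]),
                                int(r["pa"]),
                                int(r["man"]),
                                int(r["use"]),
                                realm=r["realm"],
                                species=r["binomial"] if use_random_effects else None,
                                location=r["location"] if use_random_effects else None,
                            ),
                            "binomial": r["binomial"],
                            "realm": r["realm"],
                        }
                    )
                per_model.append(hierarchical_average(pd.DataFrame(preds)))
            lambda_by_decade.append(model_average_trend(np.array(per_model), weights))
        path = index_path(lambda_by_decade, decades[0][0])
        best = model_set.best
        for i, decade in enumerate(decades):
            dep = dependence_classification(best.lag, decade)
            rows.append(
                {
                    "class": taxon_class,
                    "scenario": scenario,
                    "decade_start": decade[0],
                    "decade_end": decade[1],
                    "lambda_bar": lambda_by_decade[i],
                    "index": float(path.iloc[i + 1]),
                    "cc_dependence": dep["cc"],
                    "luc_dependence": dep["luc"],
                }
            )
    return pd.DataFrame(rows)
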