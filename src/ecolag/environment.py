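"""Lag-adjusted rates of climate and land-use change.

A lag is the delay between an environmental change and the population-trend
response it drives. Rates of climate change (CC, the OLS slope of mean annual
temperature on year, in degrees C per year) and land-use change (LUC, the mean
annual change in the anthropogenic land-cover fraction — cropland plus pasture
plus rangeland) are computed over windows equal in length to each population's
monitoring span but offset backwards in time by the lag. Lags come in two
currencies: whole years (0-49) and species generation lengths (multipliers on
a 0.1-step grid, converted to whole years per species).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EnvSeries",
    "LagSpec",
    "DriverRates",
    "climate_rate",
    "landuse_rate",
    "lag_window",
    "generations_to_years",
    "bird_generation_grid",
    "mammal_generation_grid",
    "enumerate_lag_grid",
    "rates_for_lag",
]

YEAR_LAG_MIN = 0
YEAR_LAG_MAX = 49  # abundance data start 1950, environmental data start 1901


@dataclass
class EnvSeries:
    """Annual environmental series for one location.

    ``temperature`` is mean annual temperature (degrees C) and ``anthro`` the
    anthropogenic land-cover fraction, both indexed by contiguous ``years``.
    """

    location: str
    years: np.ndarray
    temperature: np.ndarray
    anthro: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.anthro = np.asarray(self.anthro, dtype=float)
        if self.years.size == 0:
            raise ValueError("empty environmental series")
        if np.any(np.diff(self.years) != 1):
            raise ValueError(f"{self.location}: years must be contiguous")
        if self.temperature.size != self.years.size or self.anthro.size != self.years.size:
            raise ValueError(f"{self.location}: length mismatch")
        if np.any((self.anthro < 0) | (self.anthro > 1)):
            raise ValueError(f"{self.location}: anthropogenic fraction outside [0, 1]")

    @property
    def span(self) -> tuple[int, int]:
        return int(self.years[0]), int(self.years[-1])

    def window(self, start: int, end: int) -> "EnvSeries":
        """Inclusive sub-window; rejects years outside coverage."""
        s0, s1 = self.span
        if start < s0 or end > s1:
            raise ValueError(
                f"{self.location}: window {start}-{end} outside coverage {s0}-{s1}"
            )
        i0, i1 = start - s0, end - s0 + 1
        return EnvSeries(
            self.location, self.years[i0:i1], self.temperature[i0:i1], self.anthro[i0:i1]
        )


@dataclass(frozen=True)
class LagSpec:
    """A climate-lag / land-use-lag pair in a given currency.

    Year currency: integer lags in [0, 49]. Generation currency: multipliers of
    species generation length on the grid 0.3-3.1 (birds) or 0.3-2.3 (mammals),
    step 0.1, converted per species to whole years before windowing.
    """

    currency: str  # "years" | "generations"
    cc_lag: float
    luc_lag: float

    def __post_init__(self) -> None:
        if self.currency not in ("years", "generations"):
            raise ValueError(f"unknown lag currency {self.currency!r}")
        if self.cc_lag < 0 or self.luc_lag < 0:
            raise ValueError("lags must be non-negative")
        if self.currency == "years" and (
            self.cc_lag != int(self.cc_lag) or self.luc_lag != int(self.luc_lag)
        ):
            raise ValueError("year-currency lags must be integers")


@dataclass
class DriverRates:
    """Lag-adjusted CC and LUC rates for one population."""

    population_id: str
    cc: float  # degC / yr
    luc: float  # proportion / yr
    cc_lag_years: int
    luc_lag_years: int


def climate_rate(temperature: np.ndarray, years: np.ndarray | None = None) -> float:
    """OLS slope of mean annual temperature on year (degC per year)."""
    t = np.asarray(temperature, dtype=float)
    if t.size < 2:
        raise ValueError("climate rate needs a window of at least 2 years")
    x = np.arange(t.size, dtype=float) if years is None else np.asarray(years, dtype=float)
    if years is not None and np.any(np.diff(x) != 1):
        raise ValueError("missing years within window")
    xc = x - x.mean()
    return float(np.dot(xc, t - t.mean()) / np.dot(xc, xc))


def landuse_rate(anthro: np.ndarray) -> float:
    """Mean of consecutive annual differences in anthropogenic fraction.

    Telescopes to (last - first) / (window length - 1).
    """
    a = np.asarray(anthro, dtype=float)
    if a.size < 2:
        raise ValueError("land-use rate needs a window of at least 2 years")
    if np.any((a < 0) | (a > 1)):
        raise ValueError("anthropogenic fraction outside [0, 1]")
    return float(np.mean(np.diff(a)))


def lag_window(pop_span: tuple[int, int], lag_years: int, env_start: int | None = None) -> tuple[int, int]:
    """Offset a monitoring span backwards by a lag, keeping its length.

    Returns (start - lag, end - lag). If ``env_start`` is given, a window
    reaching before environmental coverage is rejected with the limiting year.
    """
    if lag_years < 0:
        raise ValueError("lag must be non-negative")
    start, end = int(pop_span[0]), int(pop_span[1])
    w = (start - int(lag_years), end - int(lag_years))
    if env_start is not None and w[0] < env_start:
        raise ValueError(
            f"lagged window starts {w[0]}, before environmental coverage ({env_start})"
        )
    return w


def generations_to_years(multiplier: float, generation_length: float) -> int:
    """Convert a generation-length multiplier to a whole number of years.

    Round-half-up, minimum 0: two generations of a 25-year species is 50
    years; two generations of a 1-year species is 2 years.
    """
    if multiplier <= 0 or generation_length <= 0:
        raise ValueError("multiplier and generation length must be positive")
    return int(np.floor(multiplier * generation_length + 0.5))


def _generation_grid(lo: float, hi: float) -> np.ndarray:
    # Build on an integer grid to avoid float accumulation (0.3, 0.4, ..., hi).
    return np.round(np.arange(round(lo * 10), round(hi * 10) + 1)) / 10.0


def bird_generation_grid() -> np.ndarray:
    """Generation multipliers 0.3-3.1 step 0.1 (29 values)."""
    return _generation_grid(0.3, 3.1)


def mammal_generation_grid() -> np.ndarray:
    """Generation multipliers 0.3-2.3 step 0.1 (21 values)."""
    return _generation_grid(0.3, 2.3)


def enumerate_lag_grid(
    taxon_class: str,
    currencies: tuple[str, ...] = ("years", "generations"),
    max_year_lag: int = YEAR_LAG_MAX,
) -> list[LagSpec]:
    """All CC x LUC lag combinations for a vertebrate class.

    Full grid: 50x50 year lags plus 29x29 (birds) or 21x21 (mammals)
    generation multipliers — 3341 and 2941 combinations respectively.
    """
    if taxon_class not in ("bird", "mammal"):
        raise ValueError(f"unknown taxon class {taxon_class!r}")
    specs: list[LagSpec] = []
    if "years" in currencies:
        year_lags = range(YEAR_LAG_MIN, max_year_lag + 1)
        specs.extend(
            LagSpec("years", cc, luc) for cc in year_lags for luc in year_lags
        )
    if "generations" in currencies:
        grid = bird_generation_grid() if taxon_class == "bird" else mammal_generation_grid()
        specs.extend(
            LagSpec("generations", float(cc), float(luc)) for cc in grid for luc in grid
        )
    return specs


def rates_for_lag(
    populations: list,
    environment: dict[str, EnvSeries],
    spec: LagSpec,
    generation_lengths: dict[str, float] | None = None,
) -> list[DriverRates]:
    """Lag-adjusted CC and LUC rates for every population under one LagSpec.

    ``populations`` are AbundanceSeries-like objects with ``population_id``,
    ``binomial``, a location key attribute ``location`` (or latitude/longitude
    string key), and ``span``. Generation currency requires a generation
    length per species binomial; conversion to whole years happens per species
    before windowing. Any window not covered by the environment aborts the run
    (coverage is a precondition of the scan design).
    """
    out: list[DriverRates] = []
    for pop in populations:
        if spec.currency == "generations":
            if generation_lengths is None or pop.binomial not in generation_lengths:
                raise ValueError(f"{pop.population_id}: no generation length for {pop.binomial}")
            gl = generation_lengths[pop.binomial]
            cc_lag = generations_to_years(spec.cc_lag, gl)
            luc_lag = generations_to_years(spec.luc_lag, gl)
        else:
            cc_lag, luc_lag = int(spec.cc_lag), int(spec.luc_lag)
        env = environment[_location_key(pop)]
        env_start = env.span[0]
        cc_win = lag_window(pop.span, cc_lag, env_start)
        luc_win = lag_window(pop.span, luc_lag, env_start)
        cc = climate_rate(env.window(*cc_win).temperature)
        luc = landuse_rate(env.window(*luc_win).anthro)
        out.append(DriverRates(pop.population_id, cc, luc, cc_lag, luc_lag))
    return out


def _location_key(pop) -> str:
    key = getattr(pop, "location", None)
    if key is None:
        key = f"{pop.latitude:.4f}_{pop.longitude:.4f}"
    return key


def rates_frame(rates: list[DriverRates]) -> pd.DataFrame:
    """DriverRates collection as a frame indexed by population_id."""
    return pd.DataFrame(
        {
            "population_id": [r.population_id for r in rates],
            "cc": [r.cc for r in rates],
            "luc": [r.luc for r in rates],
            "cc_lag_years": [r.cc_lag_years for r in rates],
            "luc_lag_years": [r.luc_lag_years for r in rates],
        }
    ).set_index("population_id")
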