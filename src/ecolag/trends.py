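"""Population-trend extraction from abundance time-series.

Raw abundance records (counts, densities, or any proxy of abundance) are
converted into an interpolated annual log10 series over the monitoring span,
from which the mean annual log10 rate of change — lambda-bar, the standard
Living-Planet-style population trend statistic — is computed. Inclusion rules
(minimum span and number of monitoring points), zero handling, the +1 shift for
sub-unit series, and an adjusted-R^2 quality filter are applied exactly as in
the lagged-driver analysis this package implements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

__all__ = [
    "AbundanceSeries",
    "PopulationTrend",
    "filter_eligible",
    "preprocess_values",
    "interpolate_log10",
    "lambda_bar",
    "compute_trend",
    "compute_trends",
    "quality_filter",
    "iucn_threshold_lambda",
]


@dataclass
class AbundanceSeries:
    """One population's raw annual observations plus metadata.

    ``years`` are the observed monitoring years (strictly increasing), and
    ``values`` the non-negative abundance observations in those years. The
    binary flags record protected-area status (``pa``), targeted management
    (``man``) and biological resource use such as hunting or collecting
    (``use``).
    """

    population_id: str
    binomial: str
    taxon_class: str  # "bird" | "mammal"
    latitude: float
    longitude: float
    realm: str
    pa: int
    man: int
    use: int
    years: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    values: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))
    location: str | None = None  # environmental grid-cell key; lat/lon used if absent

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.size == 0:
            raise ValueError(f"{self.population_id}: no observations")
        if self.years.size != self.values.size:
            raise ValueError(f"{self.population_id}: years/values length mismatch")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError(f"{self.population_id}: years must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError(f"{self.population_id}: negative abundance")

    @property
    def span(self) -> tuple[int, int]:
        return int(self.years[0]), int(self.years[-1])

    @property
    def n_points(self) -> int:
        return int(self.years.size)


@dataclass
class PopulationTrend:
    """Interpolated annual log10 abundance and the lambda-bar trend statistic.

    ``log10_values`` holds one value per calendar year of the monitoring span
    (``start_year`` .. ``start_year + T - 1``). ``lambda_bar`` is the mean of
    consecutive annual log10 ratios, per year. ``adjusted_r2`` is the adjusted
    R^2 of the trend model used for interpolation and feeds the quality filter.
    """

    population_id: str
    start_year: int
    log10_values: np.ndarray
    lambda_bar: float
    adjusted_r2: float
    method: str  # "linear" | "gam"

    @property
    def n_years(self) -> int:
        return int(self.log10_values.size)


def filter_eligible(series: AbundanceSeries) -> bool:
    """Inclusion rule: span of at least 5 years and at least 3 time-points."""
    start, end = series.span
    return (end - start + 1) >= 5 and series.n_points >= 3


def preprocess_values(values: np.ndarray) -> np.ndarray:
    """Replace zeros and shift sub-unit series to make log10 well defined.

    Zeros become 1% of the mean of the series' non-zero entries. Series whose
    observed (non-zero) values include any value below one get one added to
    every value; values below one that arise only from the zero replacement do
    not trigger the shift. The output is strictly positive.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("abundance values must be non-negative")
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero series: zero replacement undefined")
    out = values.copy()
    out[out == 0] = 0.01 * nonzero.mean()
    if np.any(nonzero < 1):
        out = out + 1.0
    return out


def _adjusted_r2(y: np.ndarray, fitted: np.ndarray, n_params: int) -> float:
    n = y.size
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        # Flat series: the trend model explains everything there is to explain.
        return 1.0 if ss_res < 1e-20 else 0.0
    df_resid = n - n_params
    if df_resid <= 0:
        return float("nan")
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / df_resid


def interpolate_log10(series: AbundanceSeries) -> PopulationTrend:
    """Annual log10 abundance across the monitoring span.

    Fewer than six observed points: linear interpolation on the log10 scale
    between observations, with adjusted R^2 taken from an OLS fit of log10
    abundance on year. Six or more points: a smooth trend model — a B-spline
    regression whose basis dimension is half the number of data points
    (rounded up) — evaluated at every year of the span.
    """
    start, end = series.span
    if end == start:
        raise ValueError(f"{series.population_id}: span of a single year")
    vals = preprocess_values(series.values)
    logv = np.log10(vals)
    yrs = series.years.astype(float)
    grid = np.arange(start, end + 1, dtype=float)
    n = series.n_points

    if n < 6:
        annual = np.interp(grid, yrs, logv)
        X = sm.add_constant(yrs)
        ols = sm.OLS(logv, X).fit()
        adj = _adjusted_r2(logv, np.asarray(ols.fittedvalues), 2)
        method = "linear"
    else:
        df_basis = max(4, math.ceil(n / 2))
        df_basis = min(df_basis, n - 1)
        degree = min(3, df_basis - 1)
        design = patsy.dmatrix(
            "bs(year, df=df_basis, degree=degree, include_intercept=True) - 1",
            {"year": yrs, "df_basis": df_basis, "degree": degree},
        )
        ols = sm.OLS(logv, np.asarray(design)).fit()
        (pred_design,) = patsy.build_design_matrices([design.design_info], {"year": grid})
        annual = np.asarray(pred_design) @ ols.params
        adj = _adjusted_r2(logv, np.asarray(ols.fittedvalues), df_basis)
        method = "gam"

    if not np.all(np.isfinite(annual)):
        raise ValueError(f"{series.population_id}: non-finite interpolated values")
    lam = lambda_bar(annual)
    return PopulationTrend(
        population_id=series.population_id,
        start_year=start,
        log10_values=annual,
        lambda_bar=lam,
        adjusted_r2=float(adj),
        method=method,
    )


def lambda_bar(log10_values: np.ndarray) -> float:
    """Mean annual log10 ratio over an interpolated series.

    Equals sum_{t=2..T} log10(N_t / N_{t-1}) / (T - 1), which telescopes to
    (log10 N_T - log10 N_1) / (T - 1).
    """
    logv = np.asarray(log10_values, dtype=float)
    if logv.size < 2:
        raise ValueError("lambda-bar needs at least two annual values")
    if not np.all(np.isfinite(logv)):
        raise ValueError("non-finite interpolated values")
    return float(np.mean(np.diff(logv)))


def compute_trend(series: AbundanceSeries) -> PopulationTrend:
    """Eligibility check, preprocessing and interpolation for one population."""
    if not filter_eligible(series):
        raise ValueError(f"{series.population_id}: fails span/points eligibility")
    return interpolate_log10(series)


def compute_trends(
    series_list: list[AbundanceSeries],
    apply_quality_filter: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Trend table for a collection of populations, with filter-stage counts.

    Returns a frame indexed by population_id with columns ``lambda_bar``,
    ``n_years``, ``adjusted_r2``, ``method``, and a dict of counts recording
    how many populations each stage removed.
    """
    counts = {"input": len(series_list)}
    eligible = [s for s in series_list if filter_eligible(s)]
    counts["eligibility_removed"] = counts["input"] - len(eligible)
    trends = [interpolate_log10(s) for s in eligible]
    if apply_quality_filter:
        kept = quality_filter(trends)
    else:
        kept = trends
    counts["r2_filter_removed"] = len(trends) - len(kept)
    counts["retained"] = len(kept)
    df = pd.DataFrame(
        {
            "population_id": [t.population_id for t in kept],
            "lambda_bar": [t.lambda_bar for t in kept],
            "n_years": [t.n_years for t in kept],
            "adjusted_r2": [t.adjusted_r2 for t in kept],
            "method": [t.method for t in kept],
        }
    ).set_index("population_id")
    return df, counts


def quality_filter(trends: list[PopulationTrend]) -> list[PopulationTrend]:
    """Retain trends whose trend model had adjusted R^2 > 0."""
    return [t for t in trends if t.adjusted_r2 > 0]


def iucn_threshold_lambda(decline_fraction: float, horizon: float = 10.0) -> float:
    """Lambda-bar equivalent of a fractional decline over a time horizon.

    A 50% decline over 10 years (IUCN A2 Endangered) corresponds to
    log10(0.5)/10 ≈ -0.0301 per year.
    """
    if not 0.0 <= decline_fraction < 1.0:
        raise ValueError("decline_fraction must be in [0, 1)")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    return math.log10(1.0 - decline_fraction) / horizon
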