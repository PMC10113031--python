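"""Mixed-model lag scanning, AICc ranking and Akaike-weight model averaging.

Population trends (lambda-bar) are modelled as linear mixed-effects functions
of lagged rates of climate change (CC) and land-use change (LUC), log10 body
mass (BM), and binary protected-area (PA), management (Man) and resource-use
(Use) statuses, with crossed random intercepts for species identity and
population location. Every lag combination in a grid is fitted, models are
ranked by small-sample-corrected AIC (AICc), the plausible set (delta AICc
below 6) is retained, and coefficients are averaged with renormalized Akaike
weights. Ecological subsetting (body-mass tertiles, trophic level, latitude)
and a case-deletion influence screen complete the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .environment import EnvSeries, LagSpec, rates_for_lag, rates_frame

__all__ = [
    "ModelSpec",
    "FittedModel",
    "FittedModelSet",
    "STRUCTURES",
    "build_design",
    "fit_mixed",
    "scan_lags",
    "akaike_weights",
    "retain_and_average",
    "lag_support_profile",
    "make_subsets",
    "influence_screen",
]

# Fixed-effect structures; all non-null structures carry the CC:LUC interaction
# and every model adds crossed random intercepts for species and location.
STRUCTURES: dict[str, str] = {
    "Base": "lambda_bar ~ cc * luc + bm + pa",
    "MU": "lambda_bar ~ cc * luc + bm + pa + man + use",
    "R": "lambda_bar ~ cc * luc + bm + pa + C(realm)",
    "MUR": "lambda_bar ~ cc * luc + bm + pa + man + use + C(realm)",
    "Null": "lambda_bar ~ 1",
}

DELTA_AICC_RETAIN = 6.0


@dataclass(frozen=True)
class ModelSpec:
    """A named fixed-effect structure (Base, MU, R, MUR or Null)."""

    structure: str

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown model structure {self.structure!r}")

    @property
    def formula(self) -> str:
        return STRUCTURES[self.structure]


@dataclass
class FittedModel:
    """One mixed-model fit at one lag pair."""

    structure: str
    lag: LagSpec
    params: pd.Series
    bse: pd.Series
    llf: float
    k: int
    n: int
    aicc: float
    converged: bool = True
    cov_params: pd.DataFrame | None = None
    scaling: dict | None = None
    random_effects: dict | None = None
    full_params: object | None = None  # MixedLMParams state, reused to warm-start neighbouring lags


@dataclass
class FittedModelSet:
    """A scan's member fits with delta AICc, Akaike weights and retention flags."""

    models: list[FittedModel]
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_models(cls, models: list[FittedModel]) -> "FittedModelSet":
        if not models:
            raise ValueError("empty model set")
        aicc = np.array([m.aicc for m in models], dtype=float)
        w = akaike_weights(aicc)
        delta = aicc - np.nanmin(aicc)
        table = pd.DataFrame(
            {
                "structure": [m.structure for m in models],
                "currency": [m.lag.currency for m in models],
                "cc_lag": [m.lag.cc_lag for m in models],
                "luc_lag": [m.lag.luc_lag for m in models],
                "logLik": [m.llf for m in models],
                "k": [m.k for m in models],
                "n": [m.n for m in models],
                "AICc": aicc,
                "delta_AICc": delta,
                "weight": w,
                "retained": delta < DELTA_AICC_RETAIN,
            }
        )
        return cls(models=models, table=table)

    @property
    def retained(self) -> list[FittedModel]:
        mask = self.table["retained"].to_numpy()
        return [m for m, keep in zip(self.models, mask) if keep]

    @property
    def retained_weights(self) -> np.ndarray:
        """Akaike weights of the retained set, renormalized to sum to 1."""
        w = self.table.loc[self.table["retained"], "weight"].to_numpy()
        return w / w.sum()

    @property
    def best(self) -> FittedModel:
        return self.models[int(self.table["delta_AICc"].idxmin())]


def build_design(
    pop_meta: pd.DataFrame,
    trends: pd.DataFrame,
    rates: pd.DataFrame,
    traits: pd.DataFrame,
    structure: str = "Base",
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Model-ready table with centred and scaled continuous covariates.

    ``pop_meta`` is indexed by population_id with columns binomial, location,
    realm, pa, man, use; ``trends`` carries lambda_bar per population;
    ``rates`` the lagged CC/LUC rates; ``traits`` is indexed by binomial with
    a positive ``body_mass`` column. CC, LUC and log10 body mass are z-scored
    within the fitted dataset; the scaling constants are returned so that
    projection covariates can reuse them. Populations with a missing trait
    are dropped.
    """
    ModelSpec(structure)
    df = pop_meta.join(trends[["lambda_bar"]], how="inner")
    df = df.join(rates[["cc", "luc"]], how="inner")
    df = df.join(traits[["body_mass"]], on="binomial", how="left")
    dropped = df.index[df["body_mass"].isna() | (df["body_mass"] <= 0)]
    if len(dropped):
        df = df.drop(index=dropped)
    if len(df) < 2:
        raise ValueError("fewer than two populations: scaling undefined")
    df = df.copy()
    df["bm"] = np.log10(df["body_mass"].astype(float))
    scaling: dict[str, tuple[float, float]] = {}
    for col in ("cc", "luc", "bm"):
        mu, sd = float(df[col].mean()), float(df[col].std(ddof=0))
        if sd == 0.0:
            raise ValueError(f"covariate {col!r} has zero variance: scaling undefined")
        df[col] = (df[col] - mu) / sd
        scaling[col] = (mu, sd)
    for col in ("pa", "man", "use"):
        df[col] = df[col].astype(int)
    cols = ["lambda_bar", "cc", "luc", "bm", "pa", "man", "use", "realm", "binomial", "location"]
    return df[cols], scaling


def _restart(res) -> MixedLMParams:
    """Optimizer state of a fitted model, reusable as a starting point."""
    return MixedLMParams.from_components(
        fe_params=np.asarray(res.fe_params),
        cov_re=np.atleast_2d(np.asarray(res.cov_re)) / res.scale,
        vcomp=np.asarray(res.vcomp) / res.scale,
    )


def _aicc(llf: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return float("inf")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_mixed(
    design: pd.DataFrame,
    structure: str = "Base",
    lag: LagSpec | None = None,
    scaling: dict | None = None,
    start_params: MixedLMParams | None = None,
) -> FittedModel:
    """Maximum-likelihood mixed model with crossed species/location intercepts.

    Estimation is by ML (not REML) so that AICc is comparable across fixed-
    effect structures. The parameter count k covers the fixed effects plus the
    two random-intercept variances and the residual variance. Rank-deficient
    fixed-effect designs are rejected (over-parameterized for the subset).
    """
    spec = ModelSpec(structure)
    if design["binomial"].nunique() < 2 or design["location"].nunique() < 2:
        raise ValueError("need at least two species and two locations")
    data = design.copy()
    data["_one"] = 1
    vc = {"species": "0 + C(binomial)", "location": "0 + C(location)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        # One all-encompassing group with two variance components gives the
        # crossed species/location random-intercept structure; re_formula="0"
        # drops the (unidentifiable) single-group intercept.
        model = smf.mixedlm(spec.formula, data, groups="_one", vc_formula=vc, re_formula="0")
        if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
            raise ValueError(f"{structure}: fixed-effect design is rank deficient")
        # L-BFGS gets close fast; a derivative-free polish from that point
        # reliably reaches the optimum (checked against lme4), which matters
        # when AICc differences of ~1 decide lag support.
        try:
            res = model.fit(reml=False, method="lbfgs", start_params=start_params)
            res = model.fit(reml=False, method="powell", start_params=_restart(res))
            converged = bool(res.converged)
        except Exception:
            res = model.fit(reml=False, method="powell")
            converged = bool(res.converged)
    fe_names = list(model.exog_names)
    params = res.params[fe_names].rename(index=str)
    bse = res.bse[fe_names].rename(index=str)
    k = len(fe_names) + 2 + 1
    n = len(data)
    fm = FittedModel(
        structure=structure,
        lag=lag if lag is not None else LagSpec("years", 0, 0),
        params=params,
        bse=bse,
        llf=float(res.llf),
        k=k,
        n=n,
        aicc=_aicc(float(res.llf), k, n),
        converged=converged,
        cov_params=res.cov_params().loc[fe_names, fe_names],
        scaling=scaling,
        full_params=_restart(res),
    )
    fm.random_effects = _extract_random_intercepts(model, res, data)
    return fm


def _extract_random_intercepts(model, res, data: pd.DataFrame) -> dict:
    """BLUPs of the species and location intercepts, keyed by level label."""
    re = res.random_effects
    blups = next(iter(re.values())) if len(re) == 1 else None
    out: dict[str, dict[str, float]] = {"species": {}, "location": {}}
    if blups is None:
        return out
    names = model.data.exog_vc.names if hasattr(model.data, "exog_vc") else []
    # vc design columns are labelled like 'species[C(binomial)[sp1]]'
    for name, val in blups.items():
        if name.startswith("species["):
            level = name.split("[", 2)[-1].rstrip("]")
            out["species"][level] = float(val)
        elif name.startswith("location["):
            level = name.split("[", 2)[-1].rstrip("]")
            out["location"][level] = float(val)
    return out


def akaike_weights(aicc: np.ndarray) -> np.ndarray:
    """Akaike weights exp(-delta/2), normalized to sum to 1.

    Computed on delta AICc for numerical stability; non-finite members get
    weight 0.
    """
    aicc = np.asarray(aicc, dtype=float)
    finite = np.isfinite(aicc)
    if not finite.any():
        raise ValueError("no finite AICc values")
    delta = aicc - aicc[finite].min()
    w = np.where(finite, np.exp(-0.5 * np.where(finite, delta, 0.0)), 0.0)
    return w / w.sum()


def scan_lags(
    populations: list,
    environment: dict[str, EnvSeries],
    pop_meta: pd.DataFrame,
    trends: pd.DataFrame,
    traits: pd.DataFrame,
    structure: str,
    grid: list[LagSpec],
    generation_lengths: dict[str, float] | None = None,
) -> FittedModelSet:
    """Fit one mixed model per lag pair and rank the set by AICc.

    Fit failures are recorded (the member is excluded from the weights) with a
    warning rather than aborting the scan.
    """
    models: list[FittedModel] = []
    start = None
    for spec in grid:
        rates = rates_frame(rates_for_lag(populations, environment, spec, generation_lengths))
        design, scaling = build_design(pop_meta, trends, rates, traits, structure)
        try:
            fm = fit_mixed(design, structure, lag=spec, scaling=scaling, start_params=start)
        except Exception as err:  # pragma: no cover - defensive
            warnings.warn(f"lag {spec}: fit failed ({err}); excluded from weights")
            start = None
            continue
        # Neighbouring lags have near-identical likelihood surfaces, so the
        # previous optimum is an excellent starting point.
        start = fm.full_params
        models.append(fm)
    return FittedModelSet.from_models(models)


def retain_and_average(model_set: FittedModelSet) -> tuple[pd.Series, pd.Series]:
    """Akaike-weight average of coefficients over the retained set.

    Weights are renormalized over the delta AICc < 6 subset. All retained
    members must share one fixed-effect structure so coefficients align
    term-by-term. Returns (averaged coefficients, averaged standard errors).
    """
    retained = model_set.retained
    if not retained:
        raise ValueError("retained subset is empty")
    structures = {m.structure for m in retained}
    if len(structures) > 1:
        raise ValueError(f"mixed structures in retained set: {sorted(structures)}")
    w = model_set.retained_weights
    coefs = pd.concat([m.params for m in retained], axis=1)
    ses = pd.concat([m.bse for m in retained], axis=1)
    if coefs.isna().any().any():
        raise ValueError("coefficient names do not align across retained models")
    avg = coefs.mul(w, axis=1).sum(axis=1)
    avg_se = ses.mul(w, axis=1).sum(axis=1)
    return avg, avg_se


def lag_support_profile(model_set: FittedModelSet, driver: str) -> pd.Series:
    """Summed Akaike weight per lag value of one driver over the retained set.

    Weights are the full-scan weights, so the profile sums to at most 1;
    values near 1 indicate strong relative support for that lag.
    """
    if driver not in ("cc", "luc"):
        raise ValueError("driver must be 'cc' or 'luc'")
    tab = model_set.table
    col = "cc_lag" if driver == "cc" else "luc_lag"
    ret = tab[tab["retained"]]
    return ret.groupby(col)["weight"].sum().sort_index()


def make_subsets(
    pop_meta: pd.DataFrame,
    traits: pd.DataFrame,
    dimension: str,
) -> dict[str, pd.Index]:
    """Partition populations for ecological subsetting.

    body_mass: small/medium/large by tertiles of species-level log10 body
    mass (ties to the lower bin). trophic: carnivore if the animal diet
    fraction is at least 2/3, herbivore if the plant fraction is; mixed diets
    are excluded. latitude: temperate if |latitude| > 23.5 degrees, else
    tropical. 'all' returns every population in one subset.
    """
    if dimension == "all":
        return {"all": pop_meta.index}
    if dimension == "body_mass":
        joined = pop_meta.join(traits[["body_mass"]], on="binomial", how="inner")
        sp_mass = np.log10(joined.groupby("binomial")["body_mass"].first())
        q1, q2 = sp_mass.quantile([1 / 3, 2 / 3])
        def bin_of(m: float) -> str:
            if m <= q1:
                return "small"
            if m <= q2:
                return "medium"
            return "large"
        labels = {sp: bin_of(m) for sp, m in sp_mass.items()}
        out: dict[str, list] = {"small": [], "medium": [], "large": []}
        for pid, sp in joined["binomial"].items():
            out[labels[sp]].append(pid)
        return {k: pd.Index(v) for k, v in out.items()}
    if dimension == "trophic":
        joined = pop_meta.join(
            traits[["diet_animal_frac", "diet_plant_frac"]], on="binomial", how="inner"
        )
        carn = joined.index[joined["diet_animal_frac"] >= 2 / 3]
        herb = joined.index[joined["diet_plant_frac"] >= 2 / 3]
        return {"carnivore": carn, "herbivore": herb}
    if dimension == "latitude":
        lat = pop_meta["latitude"].astype(float)
        return {
            "temperate": pop_meta.index[lat.abs() > 23.5],
            "tropical": pop_meta.index[lat.abs() <= 23.5],
        }
    raise ValueError(f"unknown subset dimension {dimension!r}")


def influence_screen(
    design: pd.DataFrame,
    structure: str = "Base",
    threshold: float = 0.5,
) -> tuple[pd.Series, list[str]]:
    """Case-deletion influence scores (Cook's-D style) per population.

    Each population is deleted in turn and the model refitted; the score is
    the squared coefficient displacement scaled by the baseline coefficient
    covariance, (b - b_i)' V^-1 (b - b_i) / p. Populations scoring above the
    threshold are flagged for exclusion.
    """
    base = fit_mixed(design, structure)
    beta = base.params.to_numpy()
    vinv = np.linalg.pinv(base.cov_params.to_numpy())
    p = beta.size
    scores = {}
    for pid in design.index:
        sub = design.drop(index=pid)
        if sub["binomial"].nunique() < 2 or sub["location"].nunique() < 2:
            warnings.warn(f"{pid}: deletion leaves <2 groups; screening skipped")
            scores[pid] = np.nan
            continue
        try:
            fm = fit_mixed(sub, structure)
        except Exception:
            scores[pid] = np.nan
            continue
        d = beta - fm.params.reindex(base.params.index).to_numpy()
        scores[pid] = float(d @ vinv @ d) / p
    s = pd.Series(scores, name="cooks_d")
    flagged = [pid for pid, v in s.items() if np.isfinite(v) and v > threshold]
    return s, flagged
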