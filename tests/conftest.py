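import numpy as np
import pandas as pd
import pytest

from ecolag.io import pop_meta_frame
from ecolag.synthetic import SyntheticConfig, simulate
from ecolag.trends import AbundanceSeries, compute_trends


def make_series(pid="p1", years=(2000, 2001, 2002, 2003, 2004), values=(10, 12, 15, 18, 22), **kw):
    meta = dict(
        population_id=pid,
        binomial=kw.pop("binomial", "Falco tinnunculus"),
        taxon_class=kw.pop("taxon_class", "bird"),
        latitude=kw.pop("latitude", 51.5),
        longitude=kw.pop("longitude", -0.1),
        realm=kw.pop("realm", "Palearctic"),
        pa=kw.pop("pa", 0),
        man=kw.pop("man", 0),
        use=kw.pop("use", 0),
    )
    return AbundanceSeries(years=np.array(years), values=np.array(values, dtype=float), **meta, **kw)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small but fully structured synthetic dataset (~60 populations)."""
    cfg = SyntheticConfig(
        n_species=15,
        pops_per_species=(3, 5),
        seed=7,
        zero_rate=0.0,
        obs_noise=0.01,
        missingness=0.05,
        n1_log10_range=(3.0, 5.0),
    )
    series, traits, env, truth = simulate(cfg)
    trends, counts = compute_trends(series)
    series = [s for s in series if s.population_id in set(trends.index)]
    return {
        "config": cfg,
        "series": series,
        "traits": traits,
        "env": env,
        "truth": truth,
        "trends": trends,
        "pop_meta": pop_meta_frame(series),
    }


@pytest.fixture(scope="session")
def tiny_design(tiny_dataset):
    """Model-ready design at the generating lag pair."""
    from ecolag.environment import LagSpec, rates_for_lag, rates_frame
    from ecolag.lag_models import build_design

    d = tiny_dataset
    spec = LagSpec("years", d["config"].true_lag_cc, d["config"].true_lag_luc)
    rates = rates_frame(rates_for_lag(d["series"], d["env"].historical, spec))
    design, scaling = build_design(d["pop_meta"], d["trends"], rates, d["traits"], "Base")
    return design, scaling
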