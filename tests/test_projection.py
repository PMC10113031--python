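import numpy as np
import pandas as pd
import pytest

from ecolag.environment import EnvSeries, LagSpec
from ecolag.lag_models import FittedModelSet, fit_mixed
from ecolag.projection import (
    decade_rates,
    dependence_classification,
    hierarchical_average,
    index_path,
    model_average_trend,
    predict_population_trend,
    project_index,
)


def linear_trajectory(loc="L0", slope=0.02, frac_rate=0.002):
    years = np.arange(1901, 2101)
    temp = 8.0 + slope * (years - 1901)
    anthro = np.clip(0.05 + frac_rate * (years - 1901), 0, 1)
    return EnvSeries(loc, years, temp, anthro)


class TestDecadeRates:
    def test_zero_lag_uses_decade_window(self):
        traj = linear_trajectory()
        r = decade_rates("p", traj, LagSpec("years", 0, 0), (2010, 2020))
        assert (r.cc_lag_years, r.luc_lag_years) == (0, 0)
        assert r.cc == pytest.approx(0.02)
        assert r.luc == pytest.approx(0.002)

    def test_thirty_year_lag_reads_history(self):
        traj = linear_trajectory()
        r30 = decade_rates("p", traj, LagSpec("years", 30, 30), (2010, 2020))
        win = traj.window(1980, 1990)
        assert r30.cc == pytest.approx((win.temperature[-1] - win.temperature[0]) / 10)
        assert r30.luc == pytest.approx((win.anthro[-1] - win.anthro[0]) / 10)

    def test_linear_trajectory_rates_scenario_invariant(self):
        a = decade_rates("p", linear_trajectory(), LagSpec("years", 10, 10), (2010, 2020))
        b = decade_rates("p", linear_trajectory(), LagSpec("years", 10, 10), (2030, 2040))
        assert a.cc == pytest.approx(b.cc) and a.luc == pytest.approx(b.luc)


class TestPredict:
    def test_reference_inputs_return_intercept(self, tiny_design):
        design, scaling = tiny_design
        fm = fit_mixed(design, "Base", scaling=scaling)
        pred = predict_population_trend(
            fm,
            cc=scaling["cc"][0],
            luc=scaling["luc"][0],
            bm_log10=scaling["bm"][0],
            pa=0, man=0, use=0,
        )
        assert pred == pytest.approx(fm.params["Intercept"])

    def test_hand_computed_linear_predictor(self, tiny_design):
        design, scaling = tiny_design
        fm = fit_mixed(design, "Base", scaling=scaling)
        cc = scaling["cc"][0] + 2 * scaling["cc"][1]
        luc = scaling["luc"][0] - 1 * scaling["luc"][1]
        bm = scaling["bm"][0] + 0.5 * scaling["bm"][1]
        p = fm.params
        expected = (
            p["Intercept"] + 2 * p["cc"] - 1 * p["luc"] + (2 * -1) * p["cc:luc"]
            + 0.5 * p["bm"] + p["pa"]
        )
        got = predict_population_trend(fm, cc, luc, bm, pa=1, man=0, use=0)
        assert got == pytest.approx(expected, abs=1e-12)


class TestHierarchicalAverage:
    def test_single_population_passthrough(self):
        df = pd.DataFrame({"lambda_hat": [0.07], "binomial": ["a"], "realm": ["R1"]})
        assert hierarchical_average(df) == pytest.approx(0.07)

    def test_species_then_realm_weighting(self):
        # species A: 3 populations at 0.1 -> 0.1; species B: one at 0.3
        df = pd.DataFrame(
            {
                "lambda_hat": [0.1, 0.1, 0.1, 0.3],
                "binomial": ["A", "A", "A", "B"],
                "realm": ["R1"] * 4,
            }
        )
        assert hierarchical_average(df) == pytest.approx(0.2)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "lambda_hat": rng.normal(size=20),
                "binomial": rng.choice(list("abcde"), 20),
                "realm": rng.choice(["R1", "R2"], 20),
            }
        )
        shuffled = df.sample(frac=1, random_state=1)
        assert hierarchical_average(df) == pytest.approx(hierarchical_average(shuffled))

    def test_bounded_by_member_trends(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "lambda_hat": rng.normal(size=30),
                "binomial": rng.choice(list("abcdefg"), 30),
                "realm": rng.choice(["R1", "R2", "R3"], 30),
            }
        )
        avg = hierarchical_average(df)
        assert df["lambda_hat"].min() <= avg <= df["lambda_hat"].max()


class TestModelAverage:
    def test_single_model_identity(self):
        assert model_average_trend([0.03], [1.0]) == pytest.approx(0.03)

    def test_hand_computation(self):
        assert model_average_trend([0.0, 0.04], [0.75, 0.25]) == pytest.approx(0.01)

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            model_average_trend([0.0, 0.04], [0.5, 0.25])


class TestIndexPath:
    def test_flat_trend_constant_index(self):
        path = index_path([0.0, 0.0, 0.0])
        np.testing.assert_allclose(path.to_numpy(), 1.0)

    def test_single_decade_closed_form(self):
        path = index_path([0.01])
        assert path.iloc[-1] == pytest.approx(10 ** 0.1)

    def test_multiplicative_symmetry(self):
        path = index_path([0.01, -0.01])
        assert path.iloc[-1] == pytest.approx(1.0)

    def test_split_decade_multiplicativity(self):
        # one decade at lambda vs two pseudo-decades at half the exponent
        whole = index_path([0.02]).iloc[-1]
        split = index_path([0.01, 0.01]).iloc[-1]
        assert whole == pytest.approx(split)

    def test_index_years(self):
        path = index_path([0.0, 0.0], start_year=2010)
        assert list(path.index) == [2010, 2020, 2030]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            index_path([np.nan])


class TestDependence:
    @pytest.mark.parametrize(
        "lag, decade, expected",
        [
            (30, (2010, 2020), "fully"),  # window 1980-1990
            (5, (2010, 2020), "partially"),  # window 2005-2015
            (0, (2020, 2030), "not"),
            (10, (2010, 2020), "fully"),  # window 2000-2010 ends at baseline
            (20, (2030, 2040), "not"),  # window 2010-2020 starts at the baseline year
        ],
    )
    def test_window_arithmetic(self, lag, decade, expected):
        spec = LagSpec("years", lag, lag)
        dep = dependence_classification(spec, decade)
        assert dep["cc"] == expected and dep["luc"] == expected

    def test_per_driver_classification(self):
        # cc window 1980-1990 is history; luc window starts at the baseline
        dep = dependence_classification(LagSpec("years", 30, 0), (2010, 2020))
        assert dep == {"cc": "fully", "luc": "not"}
        dep = dependence_classification(LagSpec("years", 30, 5), (2010, 2020))
        assert dep == {"cc": "fully", "luc": "partially"}


class TestProjectIndex:
    def test_locked_in_decades_scenario_invariant(self, tiny_dataset, tiny_design):
        d = tiny_dataset
        design, scaling = tiny_design
        lag = LagSpec("years", 35, 35)
        fm = fit_mixed(design, "Base", lag=lag, scaling=scaling)
        ms = FittedModelSet.from_models([fm])
        proj = project_index(
            ms, d["pop_meta"], d["traits"], d["env"].scenarios, d["config"].taxon_class
        )
        # first two decades (windows 1975-1985, 1985-1995) predate 2015 divergence
        for start in (2010, 2020):
            vals = proj[proj.decade_start == start].groupby("scenario")["index"].first()
            assert vals.max() - vals.min() == pytest.approx(0.0, abs=1e-12)
        assert (proj[proj.decade_start == 2010]["cc_dependence"] == "fully").all()

    def test_index_anchored_and_positive(self, tiny_dataset, tiny_design):
        d = tiny_dataset
        design, scaling = tiny_design
        fm = fit_mixed(design, "Base", lag=LagSpec("years", 5, 5), scaling=scaling)
        ms = FittedModelSet.from_models([fm])
        proj = project_index(
            ms, d["pop_meta"], d["traits"], d["env"].scenarios, "bird"
        )
        assert (proj["index"] > 0).all()
        assert set(proj["scenario"]) == {"SSP1", "SSP3", "SSP5"}
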