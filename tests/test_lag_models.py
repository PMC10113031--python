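import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from ecolag.environment import LagSpec
from ecolag.lag_models import (
    FittedModel,
    FittedModelSet,
    ModelSpec,
    akaike_weights,
    build_design,
    fit_mixed,
    influence_screen,
    lag_support_profile,
    make_subsets,
    retain_and_average,
)


def fake_model(aicc, cc_lag=0, luc_lag=0, params=None, structure="Base"):
    p = pd.Series(params or {"Intercept": 0.0})
    return FittedModel(
        structure=structure,
        lag=LagSpec("years", cc_lag, luc_lag),
        params=p,
        bse=p * 0 + 1.0,
        llf=0.0,
        k=4,
        n=100,
        aicc=aicc,
    )


def synthetic_design(n_per_cell=2, noise=0.0, seed=0):
    """Small balanced design with y built from known coefficients."""
    rng = np.random.default_rng(seed)
    rows = []
    species = [f"s{i}" for i in range(6)]
    locations = [f"l{i}" for i in range(8)]
    i = 0
    for sp in species:
        for _ in range(4):
            rows.append(
                {
                    "binomial": sp,
                    "location": locations[i % 8],
                    "cc": rng.normal(),
                    "luc": rng.normal(),
                    "bm": rng.normal(),
                    "pa": i % 2,
                    "man": (i // 2) % 2,
                    "use": (i // 3) % 2,
                    "realm": "Palearctic",
                }
            )
            i += 1
    df = pd.DataFrame(rows, index=[f"p{j}" for j in range(len(rows))])
    beta = {"Intercept": -0.01, "cc": -0.04, "luc": -0.03, "cc:luc": -0.02, "bm": 0.01, "pa": 0.02}
    df["lambda_bar"] = (
        beta["Intercept"]
        + beta["cc"] * df.cc
        + beta["luc"] * df.luc
        + beta["cc:luc"] * df.cc * df.luc
        + beta["bm"] * df.bm
        + beta["pa"] * df.pa
        + noise * rng.normal(size=len(df))
    )
    return df, beta


class TestBuildDesign:
    def test_scaled_columns_are_standardized(self, tiny_design):
        design, scaling = tiny_design
        for col in ("cc", "luc", "bm"):
            assert design[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert design[col].std(ddof=0) == pytest.approx(1.0, abs=1e-10)
            assert col in scaling

    def test_single_population_rejected(self, tiny_dataset, tiny_design):
        from ecolag.environment import rates_for_lag, rates_frame

        d = tiny_dataset
        one = [d["series"][0]]
        rates = rates_frame(rates_for_lag(one, d["env"].historical, LagSpec("years", 0, 0)))
        with pytest.raises(ValueError, match="fewer than two"):
            build_design(
                d["pop_meta"].iloc[:1], d["trends"], rates, d["traits"], "Base"
            )

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValueError, match="unknown model structure"):
            ModelSpec("Realm")

    def test_structure_formulas(self):
        assert "man" in ModelSpec("MU").formula and "realm" not in ModelSpec("MU").formula
        assert "realm" in ModelSpec("R").formula
        assert ModelSpec("Null").formula.endswith("~ 1")


class TestFitMixed:
    def test_noiseless_identifiability(self):
        design, beta = synthetic_design(noise=0.0)
        fm = fit_mixed(design, "Base")
        for term, val in beta.items():
            assert fm.params[term] == pytest.approx(val, abs=1e-6)

    def test_aicc_formula(self):
        design, _ = synthetic_design(noise=0.01)
        fm = fit_mixed(design, "Base")
        k, n = fm.k, fm.n
        assert k == 6 + 2 + 1
        assert fm.aicc == pytest.approx(-2 * fm.llf + 2 * k + 2 * k * (k + 1) / (n - k - 1))

    def test_null_intercept_near_sample_mean(self, tiny_design):
        design, _ = tiny_design
        fm = fit_mixed(design, "Null")
        assert fm.params["Intercept"] == pytest.approx(design["lambda_bar"].mean(), abs=0.01)

    def test_nested_loglik_inequality(self, tiny_design):
        design, _ = tiny_design
        assert fit_mixed(design, "Base").llf >= fit_mixed(design, "Null").llf - 1e-6

    def test_matches_lme4_oracle(self, tmp_path, tiny_design):
        design, _ = tiny_design
        csv = tmp_path / "design.csv"
        design.to_csv(csv, index=False)
        rscript = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(lambda_bar ~ cc*luc + bm + pa + (1|binomial) + (1|location),
                  data=d, REML=FALSE)
        cat(jsonlite::toJSON(list(fixef=as.list(fixef(m)), logLik=as.numeric(logLik(m))),
            auto_unbox=TRUE, digits=12))
        """
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        ref = json.loads(out.stdout)
        fm = fit_mixed(design, "Base")
        assert fm.llf == pytest.approx(ref["logLik"], abs=1e-2)
        mapping = {
            "Intercept": "(Intercept)", "cc": "cc", "luc": "luc",
            "cc:luc": "cc:luc", "bm": "bm", "pa": "pa",
        }
        for ours, theirs in mapping.items():
            assert fm.params[ours] == pytest.approx(ref["fixef"][theirs], abs=3e-4)


class TestAkaikeWeights:
    def test_equal_aicc_uniform(self):
        w = akaike_weights(np.array([10.0, 10.0, 10.0, 10.0]))
        np.testing.assert_allclose(w, 0.25)

    def test_delta_two_closed_form(self):
        w = akaike_weights(np.array([100.0, 102.0]))
        e = np.exp(-1.0)
        np.testing.assert_allclose(w, [1 / (1 + e), e / (1 + e)], atol=1e-12)

    def test_huge_delta_no_overflow(self):
        w = akaike_weights(np.array([0.0, 1000.0]))
        assert w[0] == pytest.approx(1.0) and w[1] == pytest.approx(0.0, abs=1e-200)
        assert np.isfinite(w).all()

    def test_all_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights(np.array([np.inf, np.nan]))


class TestModelSetArithmetic:
    def test_single_model_has_weight_one(self):
        ms = FittedModelSet.from_models([fake_model(5.0)])
        assert ms.table["weight"].iloc[0] == pytest.approx(1.0)
        prof = lag_support_profile(ms, "cc")
        assert prof.to_dict() == {0.0: pytest.approx(1.0)}

    def test_equal_aicc_split(self):
        ms = FittedModelSet.from_models([fake_model(3.0), fake_model(3.0)])
        np.testing.assert_allclose(ms.table["weight"], 0.5)

    def test_retain_and_average_single(self):
        m = fake_model(0.0, params={"Intercept": 1.5, "cc": -0.2})
        avg, _ = retain_and_average(FittedModelSet.from_models([m]))
        assert avg["cc"] == pytest.approx(-0.2)

    def test_equal_weight_midpoint(self):
        ms = FittedModelSet.from_models(
            [fake_model(0.0, params={"cc": 1.0}), fake_model(0.0, params={"cc": 3.0})]
        )
        avg, _ = retain_and_average(ms)
        assert avg["cc"] == pytest.approx(2.0)

    def test_average_matches_brute_force_weighted_sum(self):
        rng = np.random.default_rng(4)
        models = [
            fake_model(float(rng.uniform(0, 4)), params={"cc": float(rng.normal())})
            for _ in range(6)
        ]
        ms = FittedModelSet.from_models(models)
        avg, _ = retain_and_average(ms)
        w = ms.table["weight"].to_numpy()
        expected = sum(
            wi * m.params["cc"] for wi, m in zip(w / w.sum(), models)
        )  # all retained (delta < 6 by construction)
        assert ms.table["retained"].all()
        assert avg["cc"] == pytest.approx(expected, abs=1e-12)

    def test_mixed_structures_rejected(self):
        ms = FittedModelSet.from_models(
            [fake_model(0.0), fake_model(1.0, structure="MU")]
        )
        with pytest.raises(ValueError, match="mixed structures"):
            retain_and_average(ms)

    def test_delta_floor_and_weight_sum(self):
        ms = FittedModelSet.from_models([fake_model(a) for a in (12.0, 3.0, 7.0, 30.0)])
        assert ms.table["delta_AICc"].min() == 0.0
        assert ms.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert ms.table["retained"].tolist() == [False, True, True, False]

    def test_support_profile_hand_case(self):
        # 4 equal-AICc specs sharing two cc lags -> 0.5 / 0.5
        models = [fake_model(0.0, cc_lag=cc, luc_lag=l) for cc, l in [(2, 0), (2, 1), (5, 0), (5, 1)]]
        prof = lag_support_profile(FittedModelSet.from_models(models), "cc")
        assert prof[2.0] == pytest.approx(0.5) and prof[5.0] == pytest.approx(0.5)


class TestSubsets:
    def _meta(self):
        return pd.DataFrame(
            {
                "binomial": [f"s{i}" for i in range(9)],
                "latitude": [0.0, 30.0, -40.0, 10.0, -10.0, 60.0, 23.4, -23.6, 5.0],
            },
            index=[f"p{i}" for i in range(9)],
        )

    def _traits(self):
        return pd.DataFrame(
            {
                "body_mass": 10.0 ** np.arange(1, 10),
                "diet_animal_frac": [0.7, 0.5, 0.1, 1.0, 2 / 3, 0.0, 0.4, 0.9, 0.2],
                "diet_plant_frac": [0.3, 0.5, 0.9, 0.0, 1 / 3, 1.0, 0.6, 0.1, 0.8],
            },
            index=[f"s{i}" for i in range(9)],
        ).rename_axis("binomial")

    def test_latitude_rule(self):
        subs = make_subsets(self._meta(), self._traits(), "latitude")
        assert set(subs["temperate"]) == {"p1", "p2", "p5", "p7"}
        assert set(subs["tropical"]) == {"p0", "p3", "p4", "p6", "p8"}

    def test_trophic_two_thirds_rule(self):
        subs = make_subsets(self._meta(), self._traits(), "trophic")
        assert set(subs["carnivore"]) == {"p0", "p3", "p4", "p7"}  # 0.7 and 2/3 inclusive
        assert set(subs["herbivore"]) == {"p2", "p5", "p8"}
        # mixed diets (p1, p6) excluded entirely
        assert "p1" not in set(subs["carnivore"]) | set(subs["herbivore"])

    def test_body_mass_tertiles_even_split(self):
        subs = make_subsets(self._meta(), self._traits(), "body_mass")
        assert [len(subs[k]) for k in ("small", "medium", "large")] == [3, 3, 3]
        assert set(subs["small"]) == {"p0", "p1", "p2"}

    def test_exhaustive_and_disjoint(self):
        subs = make_subsets(self._meta(), self._traits(), "body_mass")
        ids = [p for v in subs.values() for p in v]
        assert sorted(ids) == sorted(self._meta().index)

    def test_all_dimension(self):
        subs = make_subsets(self._meta(), self._traits(), "all")
        assert len(subs["all"]) == 9


class TestInfluenceScreen:
    def test_planted_outlier_is_argmax(self):
        design, _ = synthetic_design(noise=0.005, seed=2)
        design.loc["p0", "cc"] = 6.0  # extreme leverage
        design.loc["p0", "lambda_bar"] = 0.5  # and deviant response
        scores, flagged = influence_screen(design, "Base")
        assert scores.idxmax() == "p0"
        assert "p0" in flagged

    def test_duplicated_balanced_data_has_no_influential_case(self):
        design, _ = synthetic_design(noise=0.005, seed=3)
        dup = design.copy()
        dup.index = [f"{i}_dup" for i in design.index]
        both = pd.concat([design, dup])
        scores, flagged = influence_screen(both, "Base")
        assert flagged == []
        assert scores.max() < 0.5
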