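"""Poisson GLM fitting, AICc scoring, selection and model averaging."""

import numpy as np
import pandas as pd
import pytest

from firesync import FireRegimeSelection, aicc, fit_poisson, select_models
from firesync.spatial_glm import build_design, default_candidate_sets


def plots_frame(rng, n=30, beta0=1.5, beta_dist=-0.002):
    d = rng.uniform(0, 2000, size=n)
    lam = np.exp(beta0 + beta_dist * d)
    veg = rng.choice(["zonal", "bog_forest", "bog_woodland", "blanket_bog"], n)
    return pd.DataFrame(
        {
            "plot_id": [f"P{i}" for i in range(n)],
            "vegetation_type": veg,
            "elevation_m": rng.uniform(0, 150, n),
            "slope_deg": rng.uniform(0, 30, n),
            "aspect_deg": rng.uniform(0, 360, n),
            "dist_habitation_m": d,
            "dist_shoreline_m": rng.uniform(0, 800, n),
            "n_fire_events": rng.poisson(lam),
        }
    )


class TestFitPoisson:
    def test_intercept_only_closed_form(self, rng):
        y = rng.poisson(5.0, size=40)
        X = pd.DataFrame({"const": np.ones(40)})
        fr = fit_poisson(y, X)
        assert fr.params["const"] == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_two_group_closed_form(self):
        y = np.array([2, 4, 3, 3, 8, 10, 9, 9])  # means 3 and 9
        X = pd.DataFrame({"const": np.ones(8),
                          "g": np.r_[np.zeros(4), np.ones(4)]})
        fr = fit_poisson(y, X)
        assert fr.params["const"] == pytest.approx(np.log(3), abs=1e-8)
        assert fr.params["g"] == pytest.approx(np.log(9 / 3), abs=1e-8)

    def test_residual_deviance_below_null(self, rng):
        df = plots_frame(rng)
        X = build_design(df, ("dist_habitation",))
        fr = fit_poisson(df["n_fire_events"], X)
        assert fr.deviance <= fr.null_deviance
        assert 0.0 <= fr.pseudo_r2 <= 1.0

    def test_counts_validation(self):
        X = pd.DataFrame({"const": np.ones(3)})
        with pytest.raises(ValueError, match="non-negative integers"):
            fit_poisson([-1, 2, 3], X)
        with pytest.raises(ValueError, match="non-negative integers"):
            fit_poisson([1.5, 2, 3], X)

    def test_rank_deficient_design_names_aliased_columns(self, rng):
        df = plots_frame(rng)
        df["vegetation_type"] = "zonal"  # dummy block collinear w/ intercept
        with pytest.raises(ValueError, match="aliased.*veg_bog_forest"):
            build_design(df, ("vegetation",))


class TestAicc:
    def test_hand_value(self):
        assert aicc(-50.0, 2, 30) == pytest.approx(104 + 12 / 27)

    def test_k_zero_equals_aic(self):
        assert aicc(-50.0, 0, 30) == pytest.approx(100.0)

    def test_large_n_approaches_aic(self):
        aic = -2 * (-50.0) + 2 * 3
        assert aicc(-50.0, 3, 10**7) == pytest.approx(aic, abs=1e-4)

    def test_small_n_errors(self):
        with pytest.raises(ValueError, match="n > K"):
            aicc(-50.0, 29, 30)


class TestSelection:
    def test_weights_sum_to_one_top_er_one(self, rng):
        res = select_models(plots_frame(rng), "event_frequency")
        assert res.table["w"].sum() == pytest.approx(1.0)
        assert res.table["dAICc"].iloc[0] == 0.0
        assert res.table["ER"].iloc[0] == pytest.approx(1.0)
        assert (res.table["ER"] >= 1.0 - 1e-12).all()

    def test_delta_two_weight_ratio_is_e(self, rng):
        # two models dAICc (0, 2): w = (0.731, 0.269), ER = e
        df = plots_frame(rng)
        res = select_models(df, "event_frequency")
        # verify the closed form on the table itself
        w = np.exp(-res.table["dAICc"] / 2)
        w /= w.sum()
        assert np.allclose(res.table["w"], w)
        two = np.exp(np.array([0.0, -1.0]))
        two /= two.sum()
        assert two[0] == pytest.approx(0.7311, abs=1e-4)
        assert two[0] / two[1] == pytest.approx(np.e)

    def test_distance_recovered_in_top_model(self, rng):
        hits = 0
        for i in range(20):
            df = plots_frame(np.random.default_rng(1000 + i))
            res = select_models(df, "event_frequency")
            top = res.table["predictors"].iloc[0]
            hits += "dist_habitation" in top
        assert hits >= 18

    def test_candidate_set_is_all_subsets(self):
        assert len(default_candidate_sets()) == 64

    def test_identical_candidates_split_weight(self, rng):
        df = plots_frame(rng)
        res = select_models(
            df, "event_frequency",
            candidate_sets=[("dist_habitation",), ("dist_habitation",)],
        )
        assert np.allclose(res.table["w"], [0.5, 0.5])
        assert np.allclose(res.table["ER"], [1.0, 1.0])

    def test_vegetation_block_uses_reference_level(self, rng):
        df = plots_frame(rng)
        df["vegetation_type"] = (
            ["zonal", "bog_forest", "bog_woodland", "blanket_bog"] * 8
        )[: len(df)]
        X = build_design(df, ("vegetation",))
        assert set(X.columns) == {"const", "veg_zonal", "veg_bog_forest",
                                  "veg_bog_woodland"}


class TestAveraging:
    def test_singleton_confidence_set_returns_that_model(self, rng):
        df = plots_frame(rng)
        res = select_models(
            df, "event_frequency",
            candidate_sets=[("dist_habitation",), ()],
        )
        avg = res.average(confidence=1e-9)
        assert len(avg.confidence_set) == 1
        top = res.top_model
        for name, b in top.params.items():
            assert avg.coefficients[name] == pytest.approx(b)

    def test_shrinkage_halves_absent_coefficient(self):
        # two equal-weight models; predictor present in one with b=-0.002
        from firesync.spatial_glm import FitResult, SelectionResults

        f1 = FitResult(("dist_habitation",),
                       pd.Series({"const": 1.0, "dist_habitation": -0.002}),
                       pd.Series({"const": 0.1, "dist_habitation": 0.0005}),
                       -10, 5, 10, 30, True)
        f2 = FitResult((), pd.Series({"const": 0.9}),
                       pd.Series({"const": 0.1}), -10, 5, 10, 30, True)
        table = pd.DataFrame(
            {"model": ["m1", "m2"], "K": [2, 1], "pseudo_R2": [0.5, 0.0],
             "AICc": [100.0, 100.0], "predictors": [("dist_habitation",), ()],
             "dAICc": [0.0, 0.0], "w": [0.5, 0.5], "ER": [1.0, 1.0]}
        )
        res = SelectionResults(table, {"m1": f1, "m2": f2}, 30, "x")
        avg = res.average(confidence=0.95)
        assert avg.coefficients["dist_habitation"] == pytest.approx(-0.001)
        assert avg.relative_importance["dist_habitation"] == pytest.approx(0.5)

    def test_importance_of_true_predictor_dominates(self, rng):
        df = plots_frame(np.random.default_rng(7))
        res = select_models(df, "event_frequency")
        avg = res.average()
        imp = avg.relative_importance
        dist_imp = imp.get("dist_habitation", 0.0)
        noise = [v for k, v in imp.items() if not k.startswith("dist_hab")]
        assert all(dist_imp >= v for v in noise)

    def test_summary_mentions_response_and_models(self, rng):
        res = select_models(plots_frame(rng), "event_frequency")
        text = res.summary()
        assert "event_frequency" in text and "AICc" in text


def test_selection_requires_two_candidates(rng):
    with pytest.raises(ValueError, match="two candidate"):
        FireRegimeSelection(plots_frame(rng), "event_frequency",
                            candidate_sets=[()])
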