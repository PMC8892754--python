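"""Predictor conditioning, IC machinery, model averaging, mixed-model contracts."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ternflight import inference as inf
from ternflight import synthetic as syn


class TestStandardize:
    def test_three_values(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, rec = inf.standardize(df)
        assert list(out["x"]) == [-1.0, 0.0, 1.0]
        assert rec["x"] == (2.0, 1.0)

    def test_already_standardized_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        x = (x - x.mean()) / x.std(ddof=1)
        out, _ = inf.standardize(pd.DataFrame({"x": x}))
        assert np.allclose(out["x"], x, atol=1e-12)

    def test_constant_column_raises_with_name(self):
        with pytest.raises(ValueError, match="xconst"):
            inf.standardize(pd.DataFrame({"xconst": [1.0, 1.0, 1.0]}))

    def test_round_trip_unscaling(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(5, 3, 300)})
        df["y"] = 2.0 + 4.0 * df["x"] + rng.normal(0, 0.1, 300)
        std, rec = inf.standardize(df, columns=["x"])
        import statsmodels.api as sm
        raw = sm.OLS(df["y"], sm.add_constant(df["x"])).fit().params["x"]
        scaled = sm.OLS(df["y"], sm.add_constant(std["x"])).fit().params["x"]
        assert inf.unstandardize_coef(scaled, predictor_record=rec["x"]) \
            == pytest.approx(raw, abs=1e-8)


class TestVifScreen:
    def test_orthogonal_predictors_all_kept(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(300, 3)), columns=["a", "b", "c"])
        kept, rep = inf.vif_screen(df, ["a", "b", "c"])
        assert kept == ["a", "b", "c"]
        assert (rep.iloc[0] < 1.1).all()

    def test_duplicated_predictor_dropped(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(size=200)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=200)
        kept, _ = inf.vif_screen(df, ["a", "b", "c"])
        assert len(kept) == 2
        assert "c" in kept

    def test_correlation_09_exceeds_vif_5(self):
        # r = 0.9 -> R^2 = 0.81 -> VIF = 1/(1-0.81) = 5.26 > 5: one is dropped
        rng = np.random.default_rng(5)
        n = 20_000
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        df = pd.DataFrame({"a": a, "b": b})
        kept, rep = inf.vif_screen(df, ["a", "b"])
        assert len(kept) == 1
        assert rep.iloc[0].max() == pytest.approx(5.26, abs=0.35)

    def test_keep_override_protects_named_column(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"air_temperature": rng.normal(size=300)})
        df["surface_temperature"] = df["air_temperature"] \
            + 0.1 * rng.normal(size=300)
        kept, _ = inf.vif_screen(df, ["air_temperature", "surface_temperature"],
                                 keep=("air_temperature",))
        assert "air_temperature" in kept
        assert "surface_temperature" not in kept


class TestPowerTransform:
    def test_lognormal_lambda_near_zero(self):
        y = np.exp(np.random.default_rng(7).normal(1.0, 0.5, 500))
        _, lam, shift = inf.power_transform(y)
        assert abs(lam) < 0.15
        assert shift == 0.0

    def test_normal_lambda_near_one(self):
        y = np.random.default_rng(8).normal(20.0, 2.0, 2000)
        _, lam, _ = inf.power_transform(y)
        assert 0.5 < lam < 1.5

    def test_zero_containing_response_shifted(self):
        y = np.concatenate([[0.0], np.random.default_rng(9).gamma(2, 2, 100)])
        out, lam, shift = inf.power_transform(y)
        assert shift > 0
        assert np.isfinite(out).all()

    def test_constant_response_identity_with_warning(self):
        with pytest.warns(UserWarning):
            out, lam, shift = inf.power_transform(np.full(10, 3.0))
        assert lam == 1.0
        assert np.allclose(out, 3.0)


class TestCandidateSet:
    @pytest.mark.parametrize("p,expected", [(0, 1), (3, 8), (11, 2048)])
    def test_subset_counts(self, p, expected):
        preds = [f"x{i}" for i in range(p)]
        assert len(inf.candidate_set(preds)) == expected

    def test_combinatorial_guard(self):
        with pytest.raises(ValueError):
            inf.candidate_set([f"x{i}" for i in range(21)])


class TestICWeights:
    def _fits(self, bics):
        fits = []
        for i, b in enumerate(bics):
            n, k = 100, 3
            llf = -(b - k * np.log(n)) / 2.0
            fits.append(inf.FittedLMM(predictors=(f"m{i}",),
                                      params=pd.Series({"Intercept": 0.0}),
                                      bse=pd.Series({"Intercept": 1.0}),
                                      llf=llf, k=k, nobs=n, vcomp={},
                                      sigma2=1.0, singular=False, converged=True))
        return fits

    def test_delta_two_gives_0731(self):
        tab = inf.ic_weights(self._fits([100.0, 102.0]), "BIC")
        assert tab["weight"].iloc[0] == pytest.approx(0.7311, abs=1e-4)
        assert tab["weight"].iloc[1] == pytest.approx(0.2689, abs=1e-4)

    def test_equal_criteria_equal_weights(self):
        tab = inf.ic_weights(self._fits([100.0, 100.0]), "BIC")
        assert np.allclose(tab["weight"], 0.5)

    def test_weights_sum_to_one(self):
        tab = inf.ic_weights(self._fits([100.0, 104.0, 90.0, 95.5]), "BIC")
        assert tab["weight"].sum() == pytest.approx(1.0)
        assert tab["cum_weight"].is_monotonic_increasing

    def test_aicc_small_sample_penalty(self):
        f = self._fits([100.0])[0]
        assert f.aicc == pytest.approx(f.aic + 2 * 3 * 4 / (100 - 3 - 1))


def _mock_fit(preds_with_beta, weight_llf, n=200):
    params = {"Intercept": 1.0}
    bse = {"Intercept": 0.1}
    for p, b in preds_with_beta.items():
        params[p] = b
        bse[p] = 0.1
    return inf.FittedLMM(predictors=tuple(preds_with_beta), params=pd.Series(params),
                         bse=pd.Series(bse), llf=weight_llf, k=len(params) + 2,
                         nobs=n, vcomp={}, sigma2=1.0, singular=False,
                         converged=True)


class TestModelAverage:
    def test_predictor_in_all_models_unchanged(self):
        fits = [_mock_fit({"water": -2.0}, -100.0),
                _mock_fit({"water": -2.0, "x": 0.1}, -100.5)]
        tab = inf.ic_weights(fits, "BIC")
        avg = inf.model_average(tab)
        assert avg.table.loc["water", "estimate"] == pytest.approx(-2.0)

    def test_zero_method_dilutes_absent_predictor(self):
        # two equal-weight models; x present in one with beta = 1 -> average 0.5
        fits = [_mock_fit({"x": 1.0}, -100.0), _mock_fit({}, -100.0)]
        fits[1].k = fits[0].k  # equalize criterion
        tab = inf.ic_weights(fits, "BIC")
        avg = inf.model_average(tab)
        assert avg.table.loc["x", "estimate"] == pytest.approx(0.5)

    def test_single_dominant_model_returned_as_is(self):
        fits = [_mock_fit({"x": 1.5}, -100.0), _mock_fit({}, -300.0)]
        tab = inf.ic_weights(fits, "BIC")
        avg = inf.model_average(tab)
        assert avg.n_models == 1
        assert avg.table.loc["x", "estimate"] == pytest.approx(1.5)

    def test_confidence_set_weights_renormalized(self):
        fits = [_mock_fit({"x": 1.0}, -100.0), _mock_fit({}, -101.0),
                _mock_fit({"y": 0.3}, -102.0), _mock_fit({"x": 0.9, "y": 0.2}, -108.0)]
        tab = inf.ic_weights(fits, "BIC")
        ncut = int(np.searchsorted(tab["cum_weight"].to_numpy(), 0.95) + 1)
        top = tab.iloc[:ncut]
        assert (top["weight"] / top["weight"].sum()).sum() == pytest.approx(1.0)

    def test_shrinkage_vs_conditional_average(self):
        fits = [_mock_fit({"x": 1.0}, -100.0), _mock_fit({}, -100.4),
                _mock_fit({"x": 1.2, "y": -0.5}, -101.0)]
        tab = inf.ic_weights(fits, "BIC")
        avg = inf.model_average(tab)
        cond = inf.conditional_average(tab)
        for p in avg.table.index:
            assert abs(avg.table.loc[p, "estimate"]) <= abs(cond[p]) + 1e-12


class TestFitLMM:
    def test_intercept_only_recovers_mean(self):
        df = syn.simulate_behavior_table(seed=3, beta_water=0.0)
        fit = inf.fit_lmm(df, "travel_speed", ())
        assert fit.params["Intercept"] == pytest.approx(
            df["travel_speed"].mean(), abs=2.0)

    def test_strong_effect_recovered(self):
        df = syn.simulate_behavior_table(seed=4)
        fit = inf.fit_lmm(df, "travel_speed", ("water", "noise1"))
        assert fit.params["water"] == pytest.approx(-200.0, abs=40.0)
        assert not fit.singular

    def test_random_intercept_variance_detected(self):
        df = syn.simulate_behavior_table(seed=5, sd_individual=80.0, sd_noise=20.0)
        fit = inf.fit_lmm(df, "travel_speed", ("water",))
        assert fit.vcomp["individual"] > 1000.0   # true 6400

    def test_nested_segment_structure_fits(self):
        df = syn.simulate_behavior_table(seed=6, n_individuals=8, n_segments=6)
        fit = inf.fit_lmm(df, "travel_speed", ("water",),
                          random=("individual", "segment"))
        assert set(fit.vcomp) == {"individual", "segment"}
        assert np.isfinite(fit.llf)


class TestSelectRandomEffects:
    def _with_colony(self, colony_sd, seed):
        rng = np.random.default_rng(seed)
        df = syn.simulate_behavior_table(seed=seed, n_individuals=30, n_segments=8)
        colonies = [f"c{i % 5}" for i in range(30)]
        eff = {c: rng.normal(0, colony_sd) for c in set(colonies)}
        df["colony"] = np.repeat(colonies, 8)
        df["travel_speed"] += df["colony"].map(eff)
        return df

    def test_null_colony_effect_selects_individual_only(self):
        df = self._with_colony(0.0, 7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chosen, _ = inf.select_random_effects(
                df, "travel_speed", ("water",),
                candidates=[("individual",), ("individual", "colony")])
        assert chosen == ("individual",)

    def test_large_colony_effect_keeps_colony(self):
        df = self._with_colony(100.0, 8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chosen, _ = inf.select_random_effects(
                df, "travel_speed", ("water",),
                candidates=[("individual",), ("individual", "colony")])
        assert chosen == ("individual", "colony")

    def test_single_candidate_returned(self):
        df = syn.simulate_behavior_table(seed=9)
        chosen, tab = inf.select_random_effects(df, "travel_speed", ("water",),
                                                candidates=[("individual",)])
        assert chosen == ("individual",)
        assert len(tab) == 1


class TestLikelihoodRatio:
    def test_identical_models_chi2_zero(self):
        df = syn.simulate_behavior_table(seed=10)
        f = inf.fit_lmm(df, "travel_speed", ("water",))
        f2 = inf.FittedLMM(**{**f.__dict__, "k": f.k + 1})
        chi2, dof, p = inf.likelihood_ratio_test(f, f2)
        assert chi2 == 0.0
        assert p == 1.0

    def test_chi2_384_df1_p_005(self):
        from scipy import stats
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=1e-3)

    def test_strong_effect_detected(self):
        df = syn.simulate_behavior_table(seed=11)
        f0 = inf.fit_lmm(df, "travel_speed", ())
        f1 = inf.fit_lmm(df, "travel_speed", ("water",))
        chi2, dof, p = inf.likelihood_ratio_test(f0, f1)
        assert dof == 1
        assert p < 1e-6

    def test_non_nested_rejected(self):
        df = syn.simulate_behavior_table(seed=12)
        f1 = inf.fit_lmm(df, "travel_speed", ("water",))
        f2 = inf.fit_lmm(df, "travel_speed", ("noise1",))
        with pytest.raises(ValueError):
            inf.likelihood_ratio_test(f1, f2)


class TestBICConsistency:
    def test_true_model_selected_more_often_at_larger_n(self):
        hits = {60: 0, 600: 0}
        for n in hits:
            for rep in range(8):
                df = syn.simulate_behavior_table(
                    seed=1000 + rep, n_individuals=max(n // 10, 6),
                    n_segments=10 if n >= 100 else n // 6,
                    sd_individual=20.0, sd_noise=60.0)
                fits = inf.fit_candidates(df, "travel_speed",
                                          ("water", "noise1"))
                tab = inf.ic_weights(fits, "BIC")
                hits[n] += tab.iloc[0]["predictors"] == ("water",)
        assert hits[600] >= hits[60]
        assert hits[600] >= 7


class TestDriver:
    def test_average_models_end_to_end(self):
        df = syn.simulate_behavior_table(seed=13)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = inf.average_models(df, "travel_speed",
                                     ["water", "noise1", "noise2"],
                                     transform_response=False)
        avg = res["averaged"].table
        assert avg.loc["water", "distinguishable"]
        assert not avg.loc["noise1", "distinguishable"] \
            or abs(avg.loc["noise1", "estimate"]) < 0.2
        assert res["random"] == ("individual",)

    def test_spring_exclusions_applied(self):
        df = syn.simulate_behavior_table(seed=14)
        df["days_at_previous_stopover"] = np.random.default_rng(0).uniform(
            1, 10, len(df))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = inf.average_models(df, "travel_speed",
                                     ["water", "days_at_previous_stopover"],
                                     season="spring", transform_response=False)
        assert "days_at_previous_stopover" not in res["retained_predictors"]
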