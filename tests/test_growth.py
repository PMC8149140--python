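"""Growth curves, model selection, length-weight analysis."""

import numpy as np
import pandas as pd
import pytest

from fishtroph.growth import (LWRFit, VBModelSpec, VBParams, aic_ls,
                              all_model_specs, ancova_lwr, as_fish_frame,
                              body_condition, fit_lwr, fit_vb,
                              mean_length_at_age, predict_vb,
                              vb_model_selection)
from fishtroph.growth import test_isometry as isometry_test
from fishtroph.records import FishRecord

TABLE_PARAMS = {
    "PVp": VBParams(34.4, 0.24, -0.60), "PVi": VBParams(45.7, 0.24, 0.03),
    "TLp": VBParams(35.9, 0.24, -0.50), "TLi": VBParams(41.1, 0.24, -0.55),
}


def laa_from(params: dict, noise_sd: float, rng, ages=range(5)):
    rows = []
    for p, vb in params.items():
        for age in ages:
            rows.append({"population_id": p, "age": age,
                         "mean_tl": predict_vb(vb, age)
                         + (rng.normal(0, noise_sd) if noise_sd else 0.0),
                         "n": 1})
    return pd.DataFrame(rows)


class TestPredictVB:
    def test_zero_at_t0(self):
        assert predict_vb(VBParams(40, 0.3, 0.5), 0.5) == pytest.approx(0.0)

    def test_approaches_linf(self):
        assert predict_vb(VBParams(40, 0.3, 0.0), 200.0) == pytest.approx(
            40.0, rel=1e-9)

    def test_published_pvi_curve_value(self):
        # Linf 45.7, K 0.24, t0 0.03 at age 3
        assert predict_vb(VBParams(45.7, 0.24, 0.03), 3.0) == pytest.approx(
            45.7 * (1 - np.exp(-0.24 * 2.97)), rel=1e-12)
        assert predict_vb(VBParams(45.7, 0.24, 0.03), 3.0) == pytest.approx(
            23.3, abs=0.05)


class TestMeanLengthAtAge:
    def test_mean_and_sd(self):
        fish = [FishRecord(f"f{i}", "P", "purebred", tl, age=2)
                for i, tl in enumerate([10.0, 20.0])]
        out = mean_length_at_age(fish, max_age=4)
        assert out.loc[0, "mean_tl"] == 15.0
        assert out.loc[0, "sd"] == pytest.approx(7.0711, abs=1e-3)

    def test_old_fish_excluded(self):
        fish = [FishRecord("a", "P", "purebred", 10.0, age=2),
                FishRecord("b", "P", "purebred", 30.0, age=5)]
        out = mean_length_at_age(fish, max_age=4)
        assert set(out["age"]) == {2}

    def test_row_count_is_distinct_retained_ages(self, study):
        out = mean_length_at_age(study["fish"], max_age=4)
        df = as_fish_frame(study["fish"]).dropna(subset=["age"])
        df = df[df.age <= 4]
        expected = df.groupby("population_id")["age"].nunique().sum()
        assert len(out) == expected


class TestAicLs:
    def test_halving_sse_lowers_by_n_ln2(self):
        n, k = 30, 4
        assert aic_ls(5.0, n, k) - aic_ls(10.0, n, k) == pytest.approx(
            -n * np.log(2))

    def test_extra_parameter_costs_two(self):
        assert aic_ls(5.0, 30, 5) - aic_ls(5.0, 30, 4) == pytest.approx(2.0)

    def test_agrees_with_gaussian_likelihood(self, rng):
        y = rng.normal(size=25)
        resid = y - y.mean()
        sse = float(resid @ resid)
        n, k = 25, 1
        sigma2 = sse / n
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
        aic_ll = -2 * loglik + 2 * (k + 1)
        # the two forms differ by the constant n(log 2 pi + 1)
        assert aic_ls(sse, n, k) == pytest.approx(
            aic_ll - n * (np.log(2 * np.pi) + 1), rel=1e-12)

    def test_zero_sse_sentinel(self):
        with pytest.warns(RuntimeWarning):
            assert aic_ls(0.0, 10, 2) == -np.inf


class TestFitVB:
    def test_noiseless_recovery_fully_free(self, rng):
        laa = laa_from(TABLE_PARAMS, 0.0, rng)
        fit = fit_vb(laa, VBModelSpec(False, False, False), seed=0)
        assert fit.sse < 1e-10
        for p, true in TABLE_PARAMS.items():
            assert fit.params[p].Linf == pytest.approx(true.Linf, abs=1e-3)
            assert fit.params[p].K == pytest.approx(true.K, abs=1e-4)

    def test_grid_search_finds_no_better_sse(self, rng):
        params = {"A": VBParams(40.0, 0.25, -0.4)}
        laa = laa_from(params, 0.3, rng, ages=range(6))
        fit = fit_vb(laa, VBModelSpec(False, False, False), seed=1)
        t = laa["age"].to_numpy()
        y = laa["mean_tl"].to_numpy()
        best_grid = np.inf
        for linf in np.linspace(30, 60, 40):
            for k in np.linspace(0.05, 0.8, 40):
                for t0 in np.linspace(-2, 1, 30):
                    pred = linf * (1 - np.exp(-k * (t - t0)))
                    best_grid = min(best_grid, ((y - pred) ** 2).sum())
        assert fit.sse <= best_grid + 1e-9

    def test_shared_parameters_identical_across_pops(self, rng):
        laa = laa_from(TABLE_PARAMS, 0.5, rng)
        fit = fit_vb(laa, VBModelSpec(False, True, True), seed=2)
        ks = {p.K for p in fit.params.values()}
        t0s = {p.t0 for p in fit.params.values()}
        assert len(ks) == 1 and len(t0s) == 1
        assert fit.k_params == 4 + 1 + 1


class TestModelSelection:
    def test_eight_specs_enumerated(self):
        specs = all_model_specs()
        assert len(specs) == len(set(specs)) == 8

    def test_identical_populations_pick_fully_shared(self, rng):
        # noiseless identical populations: every structure fits exactly,
        # so parsimony must break the tie for the fully shared model
        params = {p: VBParams(40.0, 0.24, -0.5) for p in "ABC"}
        laa = laa_from(params, 0.0, rng)
        ranked = vb_model_selection(laa, seed=3)
        assert ranked[0].spec == VBModelSpec(True, True, True)

    def test_nesting_monotonicity(self, rng):
        laa = laa_from(TABLE_PARAMS, 1.0, rng)
        fits = {f.spec: f for f in vb_model_selection(laa, seed=4)}
        for a, fa in fits.items():
            for b, fb in fits.items():
                if a.is_restriction_of(b):
                    assert fa.sse >= fb.sse - 1e-8 * max(fa.sse, 1.0)

    def test_selection_consistency_in_noiseless_limit(self, rng):
        # zero noise: both structures containing the truth fit exactly;
        # the generating shared-K model wins on parsimony
        laa = laa_from(TABLE_PARAMS, 0.0, rng)
        ranked = vb_model_selection(laa, seed=5)
        assert ranked[0].spec == VBModelSpec(False, True, False)
        containing = {VBModelSpec(False, True, False),
                      VBModelSpec(False, False, False)}
        for f in ranked:
            if f.spec in containing:
                assert f.sse < 1e-8


class TestLWR:
    def test_exact_power_law_recovered(self):
        tl = np.linspace(5, 30, 20)
        w = 0.011 * tl ** 2.99
        fish = [FishRecord(f"f{i}", "P", "purebred", float(tl[i]),
                           weight=float(w[i])) for i in range(20)]
        fit = fit_lwr(fish)
        assert fit.b == pytest.approx(2.99, abs=1e-9)
        assert fit.a == pytest.approx(0.011, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_doubling_weights_changes_a_not_b(self, rng):
        tl = rng.uniform(5, 30, 40)
        w = 0.014 * tl ** 2.8 * 10 ** rng.normal(0, 0.03, 40)
        mk = lambda wv: [FishRecord(f"f{i}", "P", "purebred", float(tl[i]),
                                    weight=float(wv[i])) for i in range(40)]
        f1, f2 = fit_lwr(mk(w)), fit_lwr(mk(2 * w))
        assert f2.b == pytest.approx(f1.b, rel=1e-9)
        assert f2.a == pytest.approx(2 * f1.a, rel=1e-9)

    def test_slope_recovery_at_study_sample_size(self, rng):
        hits = 0
        for _ in range(100):
            tl = rng.uniform(7, 28, 141)
            w = 0.014 * tl ** 2.8 * 10 ** rng.normal(0, 0.02, 141)
            fish = pd.DataFrame({"population_id": "TLi",
                                 "total_length": tl, "weight": w})
            hits += abs(fit_lwr(fish).b - 2.8) < 0.05
        assert hits >= 90


class TestIsometry:
    def test_b_equal_three_is_isometric(self):
        fit = LWRFit(a=0.01, b=3.0, se_b=0.05, r_squared=0.99,
                     residuals=np.zeros(3), n=50)
        res = isometry_test(fit)
        assert res["t"] == 0.0 and res["verdict"] == "isometric"

    def test_negative_allometry_detected(self, rng):
        tl = rng.uniform(7, 28, 141)
        w = 0.014 * tl ** 2.8 * 10 ** rng.normal(0, 0.02, 141)
        fish = pd.DataFrame({"population_id": "X", "total_length": tl,
                             "weight": w})
        res = isometry_test(fit_lwr(fish))
        assert res["verdict"] == "allometric_negative"


class TestAncova:
    def test_common_power_law_not_significant(self, rng):
        rows = []
        for p in ("A", "B", "C"):
            tl = rng.uniform(5, 30, 60)
            w = 0.012 * tl ** 2.9 * 10 ** rng.normal(0, 0.04, 60)
            rows.append(pd.DataFrame({"population_id": p,
                                      "total_length": tl, "weight": w}))
        res = ancova_lwr(pd.concat(rows))
        assert res["p"] > 0.01

    def test_different_slopes_detected(self, rng):
        rows = []
        for p, b in (("A", 2.8), ("B", 3.0)):
            tl = rng.uniform(5, 30, 80)
            w = 0.012 * tl ** b * 10 ** rng.normal(0, 0.01, 80)
            rows.append(pd.DataFrame({"population_id": p,
                                      "total_length": tl, "weight": w}))
        assert ancova_lwr(pd.concat(rows))["p"] < 1e-3

    def test_two_population_f_equals_interaction_t_squared(self, rng):
        import statsmodels.api as sm
        rows = []
        for p, b in (("A", 2.85), ("B", 2.95)):
            tl = rng.uniform(5, 30, 50)
            w = 0.012 * tl ** b * 10 ** rng.normal(0, 0.03, 50)
            rows.append(pd.DataFrame({"population_id": p,
                                      "total_length": tl, "weight": w}))
        df = pd.concat(rows)
        res = ancova_lwr(df)
        x = np.log10(df["total_length"])
        y = np.log10(df["weight"])
        g = (df["population_id"] == "B").astype(float)
        X = sm.add_constant(np.column_stack([x, g, g * x]))
        ols = sm.OLS(y, X).fit()
        assert res["F"] == pytest.approx(ols.tvalues.iloc[-1] ** 2, rel=1e-8)


class TestBodyCondition:
    def test_per_population_residual_means_vanish(self, study):
        res = body_condition(study["fish"], mode="per_population")
        for mean in res["population_means"].values():
            assert abs(mean) < 1e-10

    def test_inflated_weights_detected_under_pooled_lwr(self, rng):
        rows = []
        for p, boost in (("A", 1.0), ("B", 1.1)):
            tl = rng.uniform(5, 30, 80)
            w = boost * 0.012 * tl ** 2.9 * 10 ** rng.normal(0, 0.03, 80)
            rows.append(pd.DataFrame({"fish_id": [f"{p}{i}" for i in
                                                  range(80)],
                                      "population_id": p,
                                      "total_length": tl, "weight": w}))
        res = body_condition(pd.concat(rows), mode="pooled")
        assert res["population_means"]["B"] > res["population_means"]["A"]
        assert res["anova"].p < 0.01
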