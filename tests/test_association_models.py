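"""Linear/logistic determinant models: transforms, VIF, semipartials, ORs."""

import numpy as np
import pandas as pd
import pytest

from anemiascope.association_models import (
    SeparationWarning,
    bivariate_screen,
    fit_anemia_model,
    fit_hb_model,
    percent_odds_reduction,
    transform_predictors,
    vif_screen,
)


class TestTransformPredictors:
    def test_log10(self):
        df = pd.DataFrame({"ferritin": [100.0, 10.0], "hb": [130.0, 120.0]})
        out = transform_predictors(df, skewed=["ferritin"])
        np.testing.assert_allclose(out["ferritin"], [2.0, 1.0])
        np.testing.assert_allclose(out["hb"], df["hb"])  # untouched

    def test_nonpositive_value_rejected_with_row(self):
        df = pd.DataFrame({"crp": [1.0, 0.0, 2.0]})
        with pytest.raises(ValueError, match="rows \\[1\\]"):
            transform_predictors(df, skewed=["crp"])


class TestVifScreen:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame(
            {"a": np.cos(2 * np.pi * t / n), "b": np.sin(2 * np.pi * t / n),
             "c": np.cos(4 * np.pi * t / n)}
        )
        kept, table = vif_screen(X)
        assert list(kept.columns) == ["a", "b", "c"]
        final = table[table["round"] == table["round"].max()]
        np.testing.assert_allclose(final["vif"], 1.0, atol=1e-10)

    def test_pairwise_correlation_closed_form(self, rng):
        # two predictors with exact sample correlation 0.6:
        # VIF = 1 / (1 - 0.36) = 1.5625 for both
        n = 1000
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal to a
        b /= b.std()
        x2 = 0.6 * a + np.sqrt(1 - 0.36) * b
        kept, table = vif_screen(pd.DataFrame({"a": a, "x2": x2}))
        np.testing.assert_allclose(table["vif"], 1.5625, atol=1e-9)
        assert list(kept.columns) == ["a", "x2"]

    def test_duplicated_predictor_dropped_with_infinite_vif(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        X = pd.DataFrame({"a": x, "a_copy": x, "b": y})
        kept, table = vif_screen(X)
        assert kept.shape[1] == 2
        assert np.isinf(table.loc[table["round"] == 0, "vif"]).sum() == 2
        assert table["dropped"].sum() == 1


class TestFitHbModel:
    def test_single_predictor_semipartial_equals_r2(self, rng):
        # the nested comparison against the intercept-only model is exact
        x = rng.normal(size=300)
        y = 2.0 + 1.5 * x + rng.normal(size=300)
        res = fit_hb_model(pd.DataFrame({"x": x}), y)
        assert res.semipartial_r2["x"] == pytest.approx(res.r2, abs=1e-12)

    def test_orthogonal_design_semipartials_sum_to_r2(self):
        n = 64
        t = np.arange(n)
        a = np.cos(2 * np.pi * t / n)
        b = np.sin(2 * np.pi * t / n)
        rng = np.random.default_rng(7)
        y = 1.0 + 2.0 * a - 1.0 * b + rng.normal(size=n)
        res = fit_hb_model(pd.DataFrame({"a": a, "b": b}), y)
        assert (res.semipartial_r2["a"] + res.semipartial_r2["b"]
                == pytest.approx(res.r2, abs=1e-10))

    def test_semipartial_refit_matches_t_statistic_identity(self, cohort):
        """sr2_j by nested refit equals t_j^2 (1-R2)/(n-p-1) to 1e-10."""
        from anemiascope.biomarker_adjustment import adjust_cohort
        from anemiascope.pipeline import HB_MODEL_PREDICTORS
        import statsmodels.api as sm

        adjusted, _ = adjust_cohort(cohort)
        design = transform_predictors(
            adjusted[HB_MODEL_PREDICTORS], skewed=HB_MODEL_PREDICTORS
        )
        res = fit_hb_model(design, adjusted["hb_adj"])
        X = sm.add_constant(design, has_constant="add")
        full = sm.OLS(np.asarray(adjusted["hb_adj"], float), X).fit()
        n, p = len(design), design.shape[1]
        for col in design.columns:
            algebraic = (full.tvalues[col] ** 2) * (1 - full.rsquared) / (n - p - 1)
            assert abs(res.semipartial_r2[col] - algebraic) < 1e-10

    def test_coefficient_recovery(self, rng):
        n = 5000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 130.0 + 3.0 * x1 - 2.0 * x2 + rng.normal(0, 5, size=n)
        res = fit_hb_model(pd.DataFrame({"x1": x1, "x2": x2}), y)
        se = 5.0 / np.sqrt(n)
        assert abs(res.params["x1"] - 3.0) < 2 * se
        assert abs(res.params["x2"] + 2.0) < 2 * se
        assert res.adjusted_r2_percent > 0

    def test_singular_design_rejected(self, rng):
        x = rng.normal(size=100)
        with pytest.raises(ValueError, match="singular|VIF|screen"):
            fit_hb_model(pd.DataFrame({"a": x, "b": x}), rng.normal(size=100))


class TestLogistic:
    def test_saturated_2x2_equals_cross_product(self):
        # a=10, b=20, c=30, d=40 -> OR = 10*40 / (20*30) = 2/3
        x = np.repeat([1, 1, 0, 0], [10, 20, 30, 40])
        y = np.repeat([1, 0, 1, 0], [10, 20, 30, 40])
        res = fit_anemia_model(pd.DataFrame({"f": x}), y)
        assert res.odds_ratios["f"] == pytest.approx(2.0 / 3.0, abs=1e-8)
        lo, hi = res.conf_int.loc["f", 0], res.conf_int.loc["f", 1]
        assert lo < res.odds_ratios["f"] < hi

    def test_factor_identical_to_outcome_flags_separation(self):
        y = np.repeat([0, 1], 50)
        with pytest.warns(SeparationWarning):
            res = fit_anemia_model(pd.DataFrame({"f": y}), y)
        assert res.separation_flagged

    def test_no_outcome_variation_rejected(self):
        with pytest.raises(ValueError, match="variation"):
            fit_anemia_model(pd.DataFrame({"f": [0, 1, 0]}), [1, 1, 1])

    def test_few_events_warns(self, rng):
        y = np.zeros(200, dtype=int)
        y[:5] = 1
        x = rng.integers(0, 2, size=200)
        with pytest.warns(UserWarning, match="events"):
            fit_anemia_model(pd.DataFrame({"f": x}), y)


class TestBivariateScreen:
    def test_null_factor_type_I_error_near_alpha(self, rng):
        hits = 0
        reps = 150
        for _ in range(reps):
            y = rng.integers(0, 2, size=400)
            x = rng.integers(0, 2, size=400)
            retained, _ = bivariate_screen(pd.DataFrame({"f": x}), y)
            hits += len(retained)
        assert 0.01 < hits / reps < 0.10

    def test_strong_factor_power(self, rng):
        hits = 0
        reps = 60
        for _ in range(reps):
            x = rng.integers(0, 2, size=500)
            logit = -2.0 + np.log(5.0) * x
            y = rng.random(500) < 1 / (1 + np.exp(-logit))
            retained, _ = bivariate_screen(
                pd.DataFrame({"f": x}), y.astype(int)
            )
            hits += len(retained)
        assert hits / reps > 0.9

    def test_zero_cell_gets_continuity_correction(self):
        x = np.repeat([1, 1, 0, 0], [0, 30, 20, 50])
        y = np.repeat([1, 0, 1, 0], [0, 30, 20, 50])
        with pytest.warns(SeparationWarning, match="zero cell"):
            _, table = bivariate_screen(pd.DataFrame({"f": x}), y)
        assert table.loc[0, "continuity_corrected"]
        assert np.isfinite(table.loc[0, "odds_ratio"])

    def test_effects_cohort_multivariate_ors_on_correct_side(self, calibrated_spec):
        """With the generator's effects hook on, the fitted odds ratios land
        on the risk side for low MUAC and illiteracy and on the protective
        side for adequate TfR and AGP."""
        import dataclasses

        from anemiascope.biomarker_adjustment import adjust_cohort
        from anemiascope.socioeconomic_scores import score_cohort
        from anemiascope.status_classification import classify_cohort
        from anemiascope.synthetic_cohort import EffectsHook, generate_cohort
        from anemiascope.pipeline import ANEMIA_FACTORS

        spec = dataclasses.replace(
            calibrated_spec, n=2000, effects=EffectsHook()
        )
        df = generate_cohort(spec)
        df, _ = adjust_cohort(df)
        df = classify_cohort(df)
        df, _ = score_cohort(df)
        retained, _ = bivariate_screen(df[ANEMIA_FACTORS], df["anemic"])
        res = fit_anemia_model(df[retained], df["anemic"])
        assert res.odds_ratios["low_muac"] > 1
        assert res.odds_ratios["illiterate"] > 1
        assert res.odds_ratios["low_tfr"] < 1
        assert res.odds_ratios["low_agp"] < 1


class TestPercentOddsReduction:
    def test_protective_or(self):
        assert percent_odds_reduction(0.5) == pytest.approx(50.0)

    def test_harmful_or_negative_reduction(self):
        assert percent_odds_reduction(2.0) == pytest.approx(-100.0)
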