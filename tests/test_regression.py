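"""Logistic fits, screening, VIF exclusion and the stratified aOR chain."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from settlescan.errors import DomainError, SeparationError
from settlescan.regression import (
    ModelSpec,
    bivariate_screen,
    compute_vif,
    fit_logit,
    fit_mlr,
    prevalence,
    run_model,
    vif_exclude,
)


def table_2x2(a, b, c, d):
    """Expanded rows for exposed-case/exposed-noncase/unexposed-case/unexposed-noncase."""
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    return y, np.column_stack([np.ones_like(x), x])


class TestFitLogit:
    def test_null_effect_recovered_at_large_n(self):
        rng = np.random.default_rng(0)
        n = 100_000
        x = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < 0.2).astype(float)  # independent of x
        fit = fit_logit(y, np.column_stack([np.ones(n), x]))
        assert fit.converged
        assert np.exp(fit.beta[1]) == pytest.approx(1.0, abs=0.05)

    def test_2x2_mle_equals_cross_product_ratio(self):
        y, X = table_2x2(10, 90, 5, 95)
        fit = fit_logit(y, X)
        assert np.exp(fit.beta[1]) == pytest.approx((10 * 95) / (90 * 5), abs=1e-6)

    def test_constant_outcome_is_separation_error(self):
        with pytest.raises(SeparationError):
            fit_logit(np.ones(20), np.column_stack([np.ones(20), np.arange(20.0)]))

    def test_perfect_separation_is_flagged_not_silent(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        X = np.column_stack([np.ones(20), y.copy()])  # x == y: perfect separation
        with pytest.raises(SeparationError):
            fit_logit(y, X)

    def test_rank_deficiency_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.random(50)
        y = (rng.random(50) < 0.5).astype(float)
        X = np.column_stack([np.ones(50), x, x])  # duplicated column
        fit = fit_logit(y, X)
        assert not fit.converged and "rank" in fit.note

    def test_wald_ci_coverage_is_calibrated(self):
        # 200 simulated datasets; the 95% CI for a true nonzero beta must
        # cover it 93–97% of the time
        rng = np.random.default_rng(42)
        beta_true = np.log(1.8)
        n, covered = 1500, 0
        for _ in range(200):
            x = (rng.random(n) < 0.4).astype(float)
            y = (rng.random(n) < expit(-1.5 + beta_true * x)).astype(float)
            fit = fit_logit(y, np.column_stack([np.ones(n), x]))
            lo, hi = fit.beta[1] - 1.96 * fit.se[1], fit.beta[1] + 1.96 * fit.se[1]
            covered += lo <= beta_true <= hi
        assert 0.93 <= covered / 200 <= 0.97


class TestScreening:
    def _data(self, n=2000, seed=0, or_strong=2.0):
        rng = np.random.default_rng(seed)
        strong = (rng.random(n) < 0.4)
        noise = (rng.random(n) < 0.5)
        y = rng.random(n) < expit(-1.6 + np.log(or_strong) * strong)
        df = pd.DataFrame({
            "diarrhea_2wk": y, "strong": strong, "noise": noise,
            "flat": np.zeros(n, dtype=bool),
        })
        return df.astype({c: "boolean" for c in df.columns})

    def test_strong_effect_kept_null_screened_out(self):
        res = bivariate_screen(self._data(), ["strong", "noise"], screen_p=0.1)
        status = res.set_index("variable")["status"]
        assert status["strong"] == "kept"

    def test_constant_candidate_dropped_with_degenerate_note(self):
        res = bivariate_screen(self._data(), ["strong", "flat"])
        row = res.set_index("variable").loc["flat"]
        assert row["status"] == "dropped_screen" and "degenerate" in row["note"]

    def test_near_universal_exposure_dropped_by_rarity_guard(self):
        df = self._data()
        rng = np.random.default_rng(5)
        df["near_universal"] = pd.array(rng.random(len(df)) > 0.01, dtype="boolean")
        res = bivariate_screen(df, ["strong", "near_universal"])
        row = res.set_index("variable").loc["near_universal"]
        assert row["status"] == "dropped_screen" and "minority" in row["note"]

    def test_threshold_one_keeps_all_nondegenerate(self):
        res = bivariate_screen(self._data(), ["strong", "noise"], screen_p=1.0)
        assert (res.set_index("variable")["status"][["strong", "noise"]] == "kept").all()

    def test_screening_is_order_independent(self):
        df = self._data()
        a = bivariate_screen(df, ["strong", "noise", "flat"])
        b = bivariate_screen(df, ["flat", "noise", "strong"])
        merged = a.set_index("variable")["status"].sort_index()
        assert merged.equals(b.set_index("variable")["status"].sort_index())


class TestVIF:
    def test_orthogonal_columns_have_unit_vif(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0],
                          "c": [1, -1, -1, 1.0]})
        vifs = compute_vif(X)
        np.testing.assert_allclose(vifs, 1.0, atol=1e-6)

    def test_duplicated_column_reports_infinity(self):
        rng = np.random.default_rng(0)
        x = rng.random(100)
        vifs = compute_vif(pd.DataFrame({"a": x, "b": x, "c": rng.random(100)}))
        assert np.isinf(vifs["a"]) and np.isinf(vifs["b"])

    def test_known_population_r2_gives_vif_five(self):
        rng = np.random.default_rng(1)
        n = 100_000
        x1 = rng.normal(size=n)
        x2 = x1 + rng.normal(scale=0.5, size=n)  # R² = 1/1.25 = 0.8
        vifs = compute_vif(pd.DataFrame({"x1": x1, "x2": x2}))
        assert vifs["x2"] == pytest.approx(5.0, rel=0.05)

    def test_exclusion_drops_exactly_one_of_near_duplicates(self):
        rng = np.random.default_rng(2)
        n = 2000
        z = rng.random(n) < 0.5
        flip = rng.random(n) < 0.02
        data = pd.DataFrame({
            "diarrhea_2wk": rng.random(n) < expit(-1.5 + 0.8 * z),
            "v1": z, "v2": np.where(flip, ~z, z).astype(bool),
            "other": rng.random(n) < 0.5,
        }).astype({"diarrhea_2wk": "boolean", "v1": "boolean",
                   "v2": "boolean", "other": "boolean"})
        screening = bivariate_screen(data, ["v1", "v2", "other"], screen_p=1.0)
        updated = vif_exclude(screening, data, vif_max=5.0)
        status = updated.set_index("variable")["status"]
        assert (status[["v1", "v2"]] == "dropped_vif").sum() == 1
        assert status["other"] == "kept"

    def test_nothing_dropped_when_all_below_threshold(self):
        rng = np.random.default_rng(3)
        n = 1000
        data = pd.DataFrame({
            "diarrhea_2wk": rng.random(n) < 0.2,
            "a": rng.random(n) < 0.5, "b": rng.random(n) < 0.5,
        }).astype({"diarrhea_2wk": "boolean", "a": "boolean", "b": "boolean"})
        screening = bivariate_screen(data, ["a", "b"], screen_p=1.0)
        updated = vif_exclude(screening, data, vif_max=5.0)
        assert (updated["status"] != "dropped_vif").all()


class TestJointModel:
    def test_parameter_recovery_on_synthetic_survey(self, analysis_rows):
        from settlescan.schema import filter_complete_cases
        complete, _ = filter_complete_cases(analysis_rows)
        fit = run_model(complete, ModelSpec())
        est = fit.estimates.set_index("variable")
        # default generator uses aOR 1.79 for inadequate materials
        row = est.loc["inadequate_materials"]
        assert row["ci_low"] < 1.79 < row["ci_high"]
        assert fit.llr_stat >= 0
        assert (est["ci_low"] <= est["aOR"]).all() and (est["aOR"] <= est["ci_high"]).all()

    def test_conjunctive_significance_criterion(self):
        # a weak model (llr_p >= 0.05) must mark every variable non-significant
        rng = np.random.default_rng(8)
        n = 300
        data = pd.DataFrame({
            "diarrhea_2wk": rng.random(n) < 0.2,
            "a": rng.random(n) < 0.5, "b": rng.random(n) < 0.5,
        }).astype({"diarrhea_2wk": "boolean", "a": "boolean", "b": "boolean"})
        fit = fit_mlr(data, ["a", "b"])
        if fit.llr_p >= 0.05:
            assert not fit.estimates["significant"].any()

    def test_under5_stratum_uses_only_young_children(self, analysis_rows):
        from settlescan.schema import filter_complete_cases
        complete, _ = filter_complete_cases(analysis_rows)
        fit = run_model(complete, ModelSpec(stratum="under5"))
        assert fit.n_rows == int(complete["under5"].astype(bool).sum())

    def test_no_surviving_variables_is_an_error(self):
        df = pd.DataFrame({"diarrhea_2wk": pd.array([0, 1, 0, 1], dtype="boolean")})
        with pytest.raises(DomainError):
            fit_mlr(df, [])


class TestPrevalence:
    def test_simple_arithmetic(self):
        df = pd.DataFrame({
            "site_id": ["s"] * 20,
            "under5": pd.array([True] * 5 + [False] * 15, dtype="boolean"),
            "diarrhea_2wk": pd.array([True] * 3 + [False] * 17, dtype="boolean"),
        })
        assert prevalence(df) == pytest.approx(15.0)
        assert prevalence(df, under5=True) == pytest.approx(60.0)

    def test_no_cases_is_zero(self):
        df = pd.DataFrame({"site_id": ["s"], "under5": pd.array([False], dtype="boolean"),
                           "diarrhea_2wk": pd.array([False], dtype="boolean")})
        assert prevalence(df) == 0.0

    def test_empty_selection_rejected(self):
        df = pd.DataFrame({"site_id": ["s"], "under5": pd.array([False], dtype="boolean"),
                           "diarrhea_2wk": pd.array([False], dtype="boolean")})
        with pytest.raises(DomainError):
            prevalence(df, site="elsewhere")

    def test_simulated_defaults_near_design_prevalence(self, analysis_rows):
        assert prevalence(analysis_rows) == pytest.approx(15.0, abs=3.0)
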