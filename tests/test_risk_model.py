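"""Logistic risk model: fitting, AUC, selection, optimism, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import twostep as ts
from twostep.errors import ConfigurationError, DataError, EstimationError
from twostep.risk_model import (
    PredictorSpec,
    bootstrap_select,
    calibration_curve,
    compute_auc,
    fit_logistic,
    optimism_corrected_auc,
)

from conftest import logistic_cohort


def brute_force_auc(p, y):
    """Pairwise-concordance oracle: ties count 1/2."""
    p, y = np.asarray(p, float), np.asarray(y, bool)
    pos, neg = p[y], p[~y]
    wins = sum((pp > nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
    return 100.0 * wins / (len(pos) * len(neg))


class TestFitLogistic:
    def test_null_outcome_gives_small_coefficients_and_null_auc(self):
        df = logistic_cohort(0.0, 0.0, 0.0, 0.0, n=5000, seed=1)
        m = fit_logistic(df, ts.default_predictor_spec())
        assert all(abs(b) < 0.5 for b in m.coefficients.values())
        # apparent AUC of a fitted 3-predictor model carries a small
        # overfitting bias above chance even at n = 5000
        assert m.fit_stats.apparent_auc == pytest.approx(50.0, abs=4.0)

    def test_recovers_generating_coefficients(self):
        truth = {"const": -8.0, "ptau217": 3.0, "age": 0.05, "apoe4": 1.0}
        df = logistic_cohort(truth["const"], truth["ptau217"], truth["age"],
                             truth["apoe4"], n=20000, seed=2)
        m = fit_logistic(df, ts.default_predictor_spec())
        assert m.intercept == pytest.approx(truth["const"], rel=0.10)
        for name in ("ptau217", "age", "apoe4"):
            assert m.coefficients[name] == pytest.approx(truth[name], rel=0.10)

    def test_perfect_separation_raises(self):
        df = pd.DataFrame(
            {
                "ptau217": np.r_[np.full(10, 0.1), np.full(10, 2.0)],
                "abeta_pet_positive": np.r_[np.zeros(10, bool), np.ones(10, bool)],
            }
        )
        spec = PredictorSpec((("ptau217", "natural_log"),))
        with pytest.raises((EstimationError, DataError)):
            fit_logistic(df, spec)

    def test_matches_statsmodels_free_fit(self, cohort, fitted_model):
        import statsmodels.api as sm

        X = pd.DataFrame(
            {
                "const": 1.0,
                "logp": np.log(cohort["ptau217"]),
                "age": cohort["age"],
                "apoe": cohort["apoe4"].astype(float),
            }
        )
        res = sm.Logit(cohort["abeta_pet_positive"].astype(float), X).fit(disp=0)
        assert fitted_model.coefficients["ptau217"] == pytest.approx(res.params["logp"])
        assert fitted_model.fit_stats.aic == pytest.approx(res.aic)

    def test_nonpositive_value_under_log_raises(self):
        df = logistic_cohort(0, 1, 0, 0, n=50, seed=3)
        df.loc[0, "ptau217"] = 0.0
        with pytest.raises(DataError, match="positive"):
            fit_logistic(df, ts.default_predictor_spec())

    def test_missing_predictor_column_raises(self, fitted_model):
        with pytest.raises(DataError, match="missing"):
            fitted_model.predict(pd.DataFrame({"age": [70.0]}))


class TestPredictProbability:
    def test_zero_linear_predictor_gives_half(self):
        m = _toy_model(intercept=0.0, beta=1.0)
        df = pd.DataFrame({"x": [1.0]})  # ln(1) = 0
        assert ts.predict_probability(m, df)[0] == pytest.approx(0.5)

    def test_closed_form_logistic(self):
        m = _toy_model(intercept=2.0, beta=0.0)
        df = pd.DataFrame({"x": [1.0]})
        assert ts.predict_probability(m, df)[0] == pytest.approx(0.880797, abs=1e-6)

    def test_stored_apparent_auc_reproducible(self, fitted_model, cohort):
        auc = compute_auc(fitted_model.predict(cohort), cohort["abeta_pet_positive"])
        assert auc.auc == pytest.approx(fitted_model.fit_stats.apparent_auc, abs=1e-9)


def _toy_model(intercept, beta):
    spec = PredictorSpec((("x", "natural_log"),), outcome="y")
    stats = ts.ModelFitStats(50.0, 0.0, 50.0, (0.0, 100.0), 0.0, 0.0)
    return ts.FittedRiskModel(intercept, {"x": beta}, spec, 1, stats)


class TestAuc:
    def test_perfect_ranking(self):
        assert compute_auc([0.9, 0.8, 0.1], [1, 1, 0]).auc == 100.0

    def test_reversed_ranking(self):
        assert compute_auc([0.1, 0.9], [1, 0]).auc == 0.0

    def test_four_pair_example(self):
        assert compute_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]).auc == 75.0

    def test_single_class_raises(self):
        with pytest.raises(DataError):
            compute_auc([0.2, 0.4], [1, 1])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_equals_brute_force_oracle(self, data):
        n = data.draw(st.integers(4, 200))
        p = data.draw(
            st.lists(st.floats(0.01, 0.99), min_size=n, max_size=n).map(np.array)
        )
        y = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
        if y.all() or not y.any():
            y[0] = ~y[0]
        assert compute_auc(p, y).auc == pytest.approx(brute_force_auc(p, y), abs=1e-9)

    def test_invariant_under_monotone_transform(self, probabilities, cohort):
        y = cohort["abeta_pet_positive"]
        a = compute_auc(probabilities, y).auc
        b = compute_auc(np.log(probabilities / (1 - probabilities + 1e-15)), y).auc
        assert a == pytest.approx(b, abs=1e-9)

    def test_matches_sklearn(self, probabilities, cohort):
        sk = pytest.importorskip("sklearn.metrics")
        expected = 100.0 * sk.roc_auc_score(cohort["abeta_pet_positive"], probabilities)
        assert compute_auc(probabilities, cohort["abeta_pet_positive"]).auc == (
            pytest.approx(expected, abs=1e-9)
        )


class TestBootstrapSelect:
    def test_strong_predictor_retained_noise_dropped(self):
        rng = np.random.default_rng(10)
        n = 2000
        x = rng.normal(0, 1, n)
        noise = rng.normal(0, 1, n)
        y = rng.random(n) < 1 / (1 + np.exp(-(2.0 * x)))
        df = pd.DataFrame({"x": x, "noise": noise, "abeta_pet_positive": y})
        spec = PredictorSpec((("x", "identity"), ("noise", "identity")))
        sel = bootstrap_select(df, spec, n_boot=200, seed=1)
        retained_x = sum(
            f for subset, f in sel.frequencies.items() if "x" in subset
        )
        assert retained_x > 0.95
        assert "x" in sel.chosen_model

    def test_alpha_near_one_keeps_full_model(self, cohort):
        sel = bootstrap_select(
            cohort, ts.default_predictor_spec(), n_boot=20, alpha=1 - 1e-9, seed=2
        )
        assert sel.frequencies == {("age", "apoe4", "ptau217"): 1.0}

    def test_full_model_modal_when_all_predictors_carry_signal(self):
        # age contributes via age_beta; p-tau and APOE via their status
        # conditionals, mirroring a development cohort where the full
        # three-predictor model wins the bootstrap
        cfg = ts.CohortConfig(n_participants=1000, seed=21, age_beta=0.12)
        c = ts.generate_cohort(cfg)
        sel = bootstrap_select(c, ts.default_predictor_spec(), n_boot=100, seed=3)
        assert sel.chosen_model == ("age", "apoe4", "ptau217")

    def test_frequencies_sum_to_one(self, cohort):
        sel = bootstrap_select(cohort, ts.default_predictor_spec(), n_boot=50, seed=4)
        assert sum(sel.frequencies.values()) == pytest.approx(1.0)

    def test_invalid_settings_rejected(self, cohort):
        spec = ts.default_predictor_spec()
        with pytest.raises(ConfigurationError):
            bootstrap_select(cohort, spec, n_boot=0)
        with pytest.raises(ConfigurationError):
            bootstrap_select(cohort, spec, alpha=1.5)


class TestOptimism:
    def test_identity_and_sign_under_overfitting(self):
        # 20 noise predictors, random outcome, n = 100: large apparent AUC,
        # corrected AUC back near chance
        rng = np.random.default_rng(42)
        n, k = 100, 20
        df = pd.DataFrame(rng.normal(0, 1, (n, k)), columns=[f"x{i}" for i in range(k)])
        df["abeta_pet_positive"] = rng.random(n) < 0.5
        spec = PredictorSpec(tuple((f"x{i}", "identity") for i in range(k)))
        stats = optimism_corrected_auc(df, spec, n_boot=100, seed=5)
        assert stats.apparent_auc > 60.0
        assert stats.optimism > 0.0
        assert stats.corrected_auc == pytest.approx(
            stats.apparent_auc - stats.optimism, abs=1e-9
        )
        # the plain optimism bootstrap removes most but not all of the
        # inflation in this extreme p/n regime
        assert stats.corrected_auc < stats.apparent_auc - 10.0

    def test_optimism_vanishes_at_large_n(self):
        df = logistic_cohort(-8, 3, 0.05, 1, n=20000, seed=6)
        stats = optimism_corrected_auc(df, ts.default_predictor_spec(),
                                       n_boot=50, seed=7)
        assert abs(stats.optimism) < 0.5  # AUC percentage points


class TestGoodnessOfFit:
    def test_nagelkerke_zero_for_interceptish_model(self):
        rng = np.random.default_rng(8)
        n = 4000
        df = pd.DataFrame(
            {"x": rng.normal(0, 1, n), "abeta_pet_positive": rng.random(n) < 0.6}
        )
        m = fit_logistic(df, PredictorSpec((("x", "identity"),)))
        assert m.fit_stats.nagelkerke_r2 == pytest.approx(0.0, abs=0.01)

    def test_aic_drops_when_informative_predictor_added(self):
        df = logistic_cohort(-8, 3, 0.05, 1, n=5000, seed=9)
        full = fit_logistic(df, ts.default_predictor_spec())
        reduced = fit_logistic(
            df, PredictorSpec((("age", "identity"), ("apoe4", "identity")))
        )
        assert full.fit_stats.aic < reduced.fit_stats.aic


class TestCalibration:
    def test_self_consistency_at_large_n(self):
        rng = np.random.default_rng(11)
        p = rng.beta(2, 2, 50000)
        y = rng.random(50000) < p
        for pt in calibration_curve(p, y):
            assert abs(pt.predicted_mean - pt.observed_fraction) < 0.02

    def test_constant_probability_single_bin(self):
        rng = np.random.default_rng(12)
        y = rng.random(5000) < 0.6
        pts = calibration_curve(np.full(5000, 0.6), y)
        assert len(pts) == 1
        assert pts[0].observed_fraction == pytest.approx(0.6, abs=0.03)

    def test_all_negative_outcomes_in_top_bin(self):
        pts = calibration_curve(np.full(100, 0.9), np.zeros(100))
        assert pts[-1].observed_fraction == 0.0

    def test_bin_counts_cover_sample(self, probabilities, cohort):
        pts = calibration_curve(probabilities, cohort["abeta_pet_positive"])
        assert sum(pt.n for pt in pts) == len(cohort)
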