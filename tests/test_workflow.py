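"""Two-step workflow metrics: printed-count worked examples and identities."""

import numpy as np
import pytest

import twostep as ts
from twostep.errors import DataError
from twostep.thresholds import StratifiedCohort, ThresholdSet, ThresholdStrategy
from twostep.workflow import (
    ConfirmatoryMetrics,
    evaluate_step1,
    evaluate_step2,
    evaluate_workflow,
    proportion_ci,
)

# Published risk-stratification table for the three strategies
# (zone n, amyloid-negative n, amyloid-positive n):
TABLE1 = {
    "90":   {"low": (122, 100, 22), "intermediate": (47, 23, 24),  "high": (179, 14, 165)},
    "95":   {"low": (100, 89, 11),  "intermediate": (101, 41, 60), "high": (147, 7, 140)},
    "97.5": {"low": (76, 71, 5),    "intermediate": (143, 63, 80), "high": (129, 3, 126)},
}
EXPECTED_NPV = {"90": 82.0, "95": 89.0, "97.5": 93.4}
EXPECTED_PPV = {"90": 92.2, "95": 95.2, "97.5": 97.7}


def stratified_from_counts(zone_counts, thresholds=None) -> StratifiedCohort:
    """Reconstruct a stratified cohort from zone-by-outcome counts."""
    zones, outcomes = [], []
    for zone, (n, n_neg, n_pos) in zone_counts.items():
        assert n == n_neg + n_pos
        zones += [zone] * n
        outcomes += [False] * n_neg + [True] * n_pos
    thresholds = thresholds or ThresholdSet(
        lower=0.31, upper=0.80, strategy=ThresholdStrategy(95, 95),
        achieved_sensitivity=95.0, achieved_specificity=95.0,
        derivation_n=len(zones),
    )
    return StratifiedCohort(
        zones=np.array(zones, dtype=object), thresholds=thresholds,
        outcomes=np.array(outcomes),
    )


class TestStep1WorkedExamples:
    @pytest.mark.parametrize("strategy", list(TABLE1))
    def test_zone_npv_ppv_match_printed_percentages(self, strategy):
        metrics = evaluate_step1(stratified_from_counts(TABLE1[strategy]))
        assert metrics["low"].value == pytest.approx(EXPECTED_NPV[strategy], abs=0.05)
        assert metrics["high"].value == pytest.approx(EXPECTED_PPV[strategy], abs=0.05)

    def test_single_member_zone_has_wide_ci(self):
        m = evaluate_step1(
            stratified_from_counts(
                {"low": (1, 1, 0), "intermediate": (2, 1, 1), "high": (1, 0, 1)}
            )
        )["low"]
        assert m.value == 100.0
        assert m.ci[0] < 30.0  # Wilson lower bound far below the point estimate

    def test_empty_zone_undefined_not_error(self):
        m = evaluate_step1(
            stratified_from_counts({"low": (0, 0, 0), "intermediate": (2, 1, 1),
                                    "high": (3, 1, 2)})
        )["low"]
        assert m.value is None and m.ci is None


class TestStep2:
    def test_constructed_contingency(self):
        # counts consistent with the lenient strategy's intermediate zone
        m = ConfirmatoryMetrics.from_counts(tp=24, fp=5, fn=0, tn=18)
        assert m.ppv == pytest.approx(100 * 24 / 29, abs=1e-9)
        assert m.ppv == pytest.approx(82.8, abs=0.05)
        assert m.npv == 100.0

    def test_confirmatory_identical_to_pet(self):
        y = np.array([1, 0, 1, 1, 0], bool)
        m = evaluate_step2(y.copy(), y)
        assert m.ppv == m.npv == m.concordance == 100.0

    def test_confirmatory_complement_of_pet(self):
        y = np.array([1, 0, 1, 1, 0], bool)
        m = evaluate_step2(~y, y)
        assert m.ppv == 0.0 and m.npv == 0.0

    def test_missing_confirmatory_lists_ids(self):
        with pytest.raises(DataError, match="p3"):
            evaluate_step2(
                [1.0, np.nan, 0.0], [1, 0, 1], ids=["p1", "p3", "p9"]
            )

    def test_permissive_mode_excludes_missing(self):
        m = evaluate_step2([1.0, np.nan, 0.0], [1, 0, 0], permissive=True)
        assert m.n_tested == 2

    def test_empty_zone_yields_undefined_metrics(self):
        m = evaluate_step2([], [])
        assert m.ppv is None and m.npv is None and m.concordance is None


class TestWorkflow:
    def test_tests_avoided_from_printed_counts(self):
        s = stratified_from_counts(TABLE1["95"])
        conf = np.zeros(348)
        inter = s.mask("intermediate")
        conf[inter] = ~s.outcomes[inter]  # content irrelevant to avoided fraction
        wf = evaluate_workflow(s, (conf > 0).astype(float))
        assert wf.tests_avoided_fraction == pytest.approx(100 * 247 / 348, abs=1e-9)
        assert wf.tests_avoided_fraction == pytest.approx(71.0, abs=0.05)

    def test_decomposition_identity_and_printed_accuracy(self):
        # intermediate-zone confirmatory results arranged so 86 of 101 agree
        # with PET, alongside 89 correct low and 140 correct high
        s = stratified_from_counts(TABLE1["95"])
        conf = np.zeros(s.n)
        inter_pos = s.mask("intermediate") & s.outcomes
        inter_neg = s.mask("intermediate") & ~s.outcomes
        # 55 of 60 positives test positive; 31 of 41 negatives test negative
        pos_idx = np.flatnonzero(inter_pos)
        neg_idx = np.flatnonzero(inter_neg)
        conf[pos_idx[:55]] = 1.0
        conf[neg_idx[31:]] = 1.0
        wf = evaluate_workflow(s, conf)
        assert (wf.correct_low, wf.correct_high, wf.correct_confirmatory) == (89, 140, 86)
        assert wf.overall_accuracy == pytest.approx(100 * 315 / 348, abs=1e-9)
        assert wf.overall_accuracy == pytest.approx(90.5, abs=0.05)
        assert wf.overall_accuracy * wf.n / 100 == pytest.approx(
            wf.correct_low + wf.correct_high + wf.correct_confirmatory, abs=1e-9
        )

    def test_all_intermediate_perfect_confirmatory(self):
        s = stratified_from_counts({"intermediate": (20, 8, 12)})
        wf = evaluate_workflow(s, s.outcomes.astype(float))
        assert wf.overall_accuracy == 100.0
        assert wf.tests_avoided_fraction == 0.0

    def test_avoided_plus_intermediate_is_total(self, probabilities, cohort):
        tset = ts.derive_thresholds(
            probabilities, cohort["abeta_pet_positive"], ThresholdStrategy(95, 95)
        )
        s = ts.stratify(probabilities, tset, outcomes=cohort["abeta_pet_positive"])
        wf = evaluate_workflow(s, cohort["csf_positive"].astype(float))
        inter_frac = 100.0 * s.zone_counts["intermediate"] / s.n
        assert wf.tests_avoided_fraction + inter_frac == pytest.approx(100.0, abs=1e-9)

    def test_perfect_confirmatory_beats_majority_class_step1(self, probabilities, cohort):
        y = np.asarray(cohort["abeta_pet_positive"])
        tset = ts.derive_thresholds(probabilities, y, ThresholdStrategy(97.5, 97.5))
        s = ts.stratify(probabilities, tset, outcomes=y)
        wf = evaluate_workflow(s, y.astype(float))  # perfect confirmatory test
        inter = s.mask("intermediate")
        majority = max(y[inter].sum(), (~y[inter]).sum()) if inter.any() else 0
        step1_only = (wf.correct_low + wf.correct_high + majority) / s.n * 100
        assert wf.overall_accuracy >= step1_only - 1e-9

    def test_stringency_tradeoff_on_synthetic_cohort(self):
        cfg = ts.CohortConfig(n_participants=5000, seed=33)
        c = ts.generate_cohort(cfg)
        m = ts.fit_logistic(c, ts.default_predictor_spec())
        p = m.predict(c)
        accs, avoided = [], []
        for strategy in ts.default_strategies():
            tset = ts.derive_thresholds(p, c["abeta_pet_positive"], strategy)
            s = ts.stratify(p, tset, outcomes=c["abeta_pet_positive"])
            wf = evaluate_workflow(s, c["csf_positive"].astype(float))
            accs.append(wf.overall_accuracy)
            avoided.append(wf.tests_avoided_fraction)
        assert accs[0] <= accs[1] <= accs[2]
        assert avoided[0] >= avoided[1] >= avoided[2]


class TestProportionCi:
    def test_extremes(self):
        assert proportion_ci(0, 10)[0] == 0.0
        assert proportion_ci(10, 10)[1] == 100.0

    def test_wilson_closed_form(self):
        # direct evaluation of the Wilson score formula at 5/10
        from scipy.stats import norm

        z = norm.ppf(0.975)
        n, phat = 10, 0.5
        centre = (phat + z**2 / (2 * n)) / (1 + z**2 / n)
        half = (z / (1 + z**2 / n)) * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))
        lo, hi = proportion_ci(5, 10)
        assert lo == pytest.approx(100 * (centre - half), abs=1e-9)
        assert hi == pytest.approx(100 * (centre + half), abs=1e-9)

    def test_zero_n_rejected(self):
        with pytest.raises(DataError):
            proportion_ci(0, 0)
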