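"""Two-step workflow evaluation: zone accuracy, confirmatory testing, totals.

Step 1 classifies by blood-based risk zone; its accuracy is the NPV of the
low zone (% amyloid-negative) and the PPV of the high zone (% positive).
Step 2 sends only the intermediate zone to a confirmatory binary test (CSF
Ab42/Ab40 by default) and scores that test's PPV/NPV/concordance against
amyloid-PET within the zone.  Overall workflow accuracy decomposes exactly:

    accuracy * N / 100 = correct_low + correct_high + correct_confirmatory

where low-zone records count as correct when PET-negative, high-zone when
PET-positive, and intermediate when the confirmatory result matches PET.
The tests-avoided fraction is the share of the cohort resolved at step 1.

All proportion CIs are two-sided 95% Wilson score intervals, computed for
any supplied confirmatory column so alternative CSF markers slot in without
bespoke code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError
from .thresholds import StratifiedCohort, ZONES

__all__ = [
    "ZoneMetrics",
    "ConfirmatoryMetrics",
    "WorkflowResult",
    "proportion_ci",
    "evaluate_step1",
    "evaluate_step2",
    "evaluate_workflow",
]


def proportion_ci(successes: int, n: int) -> tuple[float, float]:
    """Two-sided 95% Wilson score interval, in percent."""
    if n < 1:
        raise DataError("proportion CI requires n >= 1")
    if not (0 <= successes <= n):
        raise DataError(f"successes must lie in [0, n], got {successes}/{n}")
    lo, hi = proportion_confint(successes, n, alpha=0.05, method="wilson")
    return (100.0 * float(lo), 100.0 * float(hi))


@dataclass(frozen=True)
class ZoneMetrics:
    """Accuracy summary for one risk zone.

    ``metric`` is "npv" for the low zone (% amyloid-negative), "ppv" for the
    high zone (% positive), and "positivity_rate" for the intermediate zone.
    ``value`` is None (undefined) for an empty zone.
    """

    zone: str
    n: int
    n_abeta_negative: int
    n_abeta_positive: int
    metric: str
    value: float | None
    ci: tuple[float, float] | None

    def __post_init__(self) -> None:
        if self.n != self.n_abeta_negative + self.n_abeta_positive:
            raise DataError("zone counts must sum to zone n")
        if self.value is not None:
            relevant = (
                self.n_abeta_negative if self.metric == "npv" else self.n_abeta_positive
            )
            if abs(self.value - 100.0 * relevant / self.n) > 1e-9:
                raise DataError(f"{self.metric} inconsistent with zone counts")


@dataclass(frozen=True)
class ConfirmatoryMetrics:
    """Confirmatory-test accuracy within the intermediate zone.

    Contingency counts are (test_result, PET status); values are None when
    the corresponding denominator is empty (including an empty zone, in
    which case step 1 decided everyone and the workflow is still valid).
    """

    n_tested: int
    n_test_pos_pet_pos: int
    n_test_pos_pet_neg: int
    n_test_neg_pet_pos: int
    n_test_neg_pet_neg: int
    ppv: float | None
    ppv_ci: tuple[float, float] | None
    npv: float | None
    npv_ci: tuple[float, float] | None
    concordance: float | None

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tn: int) -> "ConfirmatoryMetrics":
        n = tp + fp + fn + tn
        n_test_pos, n_test_neg = tp + fp, fn + tn
        ppv = 100.0 * tp / n_test_pos if n_test_pos else None
        npv = 100.0 * tn / n_test_neg if n_test_neg else None
        return cls(
            n_tested=n,
            n_test_pos_pet_pos=tp,
            n_test_pos_pet_neg=fp,
            n_test_neg_pet_pos=fn,
            n_test_neg_pet_neg=tn,
            ppv=ppv,
            ppv_ci=proportion_ci(tp, n_test_pos) if n_test_pos else None,
            npv=npv,
            npv_ci=proportion_ci(tn, n_test_neg) if n_test_neg else None,
            concordance=100.0 * (tp + tn) / n if n else None,
        )


@dataclass(frozen=True)
class WorkflowResult:
    """Full two-step evaluation for one thresholding strategy."""

    strategy_label: str
    n: int
    zone_metrics: dict[str, ZoneMetrics]
    confirmatory: ConfirmatoryMetrics
    correct_low: int
    correct_high: int
    correct_confirmatory: int
    overall_accuracy: float
    overall_accuracy_ci: tuple[float, float]
    tests_avoided_fraction: float

    def __post_init__(self) -> None:
        total = self.correct_low + self.correct_high + self.correct_confirmatory
        if abs(self.overall_accuracy * self.n / 100.0 - total) > 1e-9:
            raise DataError("overall accuracy violates the decomposition identity")
        avoided = self.zone_metrics["low"].n + self.zone_metrics["high"].n
        if abs(self.tests_avoided_fraction - 100.0 * avoided / self.n) > 1e-9:
            raise DataError("tests_avoided_fraction inconsistent with zone sizes")

    def to_dict(self) -> dict:
        zm = {
            z: {
                "n": m.n,
                "n_abeta_negative": m.n_abeta_negative,
                "n_abeta_positive": m.n_abeta_positive,
                "metric": m.metric,
                "value": m.value,
                "ci": list(m.ci) if m.ci else None,
            }
            for z, m in self.zone_metrics.items()
        }
        c = self.confirmatory
        return {
            "strategy": self.strategy_label,
            "n": self.n,
            "zones": zm,
            "confirmatory": {
                "n_tested": c.n_tested,
                "ppv": c.ppv,
                "ppv_ci": list(c.ppv_ci) if c.ppv_ci else None,
                "npv": c.npv,
                "npv_ci": list(c.npv_ci) if c.npv_ci else None,
                "concordance": c.concordance,
            },
            "correct_low": self.correct_low,
            "correct_high": self.correct_high,
            "correct_confirmatory": self.correct_confirmatory,
            "overall_accuracy": self.overall_accuracy,
            "overall_accuracy_ci": list(self.overall_accuracy_ci),
            "tests_avoided_fraction": self.tests_avoided_fraction,
        }


def _zone_metrics(zone: str, n_neg: int, n_pos: int) -> ZoneMetrics:
    n = n_neg + n_pos
    metric = {"low": "npv", "high": "ppv", "intermediate": "positivity_rate"}[zone]
    if n == 0:
        return ZoneMetrics(zone, 0, 0, 0, metric, None, None)
    relevant = n_neg if metric == "npv" else n_pos
    return ZoneMetrics(
        zone, n, n_neg, n_pos, metric, 100.0 * relevant / n, proportion_ci(relevant, n)
    )


def evaluate_step1(stratified: StratifiedCohort) -> dict[str, ZoneMetrics]:
    """NPV of the low zone, PPV of the high zone, intermediate positivity rate."""
    if stratified.outcomes is None:
        raise DataError("step-1 evaluation requires amyloid-PET outcomes")
    cont = stratified.contingency
    return {z: _zone_metrics(z, *cont[z]) for z in ZONES}


def _clean_confirmatory(conf, ids=None, permissive: bool = False):
    c = np.asarray(conf, dtype=float)
    missing = ~np.isfinite(c)
    if missing.any():
        if not permissive:
            where = (
                [ids[i] for i in np.flatnonzero(missing)]
                if ids is not None
                else np.flatnonzero(missing).tolist()
            )
            raise DataError(
                f"confirmatory status missing for {int(missing.sum())} "
                f"intermediate-zone records: {where[:20]}"
            )
        return c.astype(bool, copy=False), missing
    return c.astype(bool), missing


def evaluate_step2(
    confirmatory_status, outcome, ids=None, permissive: bool = False
) -> ConfirmatoryMetrics:
    """Confirmatory-test PPV/NPV/concordance against amyloid-PET.

    Call with the intermediate-zone records only.  Missing confirmatory
    results raise (listing record ids/positions) unless ``permissive``,
    which excludes them.  An empty zone yields undefined (None) metrics.
    """
    y = np.asarray(outcome).astype(bool)
    if y.size == 0:
        return ConfirmatoryMetrics.from_counts(0, 0, 0, 0)
    c_raw = np.asarray(confirmatory_status, dtype=float)
    _, missing = _clean_confirmatory(c_raw, ids=ids, permissive=permissive)
    keep = ~missing
    c = c_raw[keep].astype(bool)
    y = y[keep]
    tp = int((c & y).sum())
    fp = int((c & ~y).sum())
    fn = int((~c & y).sum())
    tn = int((~c & ~y).sum())
    return ConfirmatoryMetrics.from_counts(tp, fp, fn, tn)


def evaluate_workflow(
    stratified: StratifiedCohort,
    confirmatory_status,
    strategy_label: str | None = None,
    ids=None,
    permissive: bool = False,
) -> WorkflowResult:
    """Score the complete two-step workflow on one stratified cohort.

    ``confirmatory_status`` is a full-cohort binary column; only its
    intermediate-zone entries are consulted.
    """
    if stratified.outcomes is None:
        raise DataError("workflow evaluation requires amyloid-PET outcomes")
    y = stratified.outcomes
    zones = stratified.zones
    n = stratified.n
    conf = np.asarray(confirmatory_status, dtype=float)
    if conf.shape[0] != n:
        raise DataError("confirmatory column length must match the cohort")

    zone_metrics = evaluate_step1(stratified)
    inter = stratified.mask("intermediate")
    inter_ids = [ids[i] for i in np.flatnonzero(inter)] if ids is not None else None
    confirmatory = evaluate_step2(
        conf[inter], y[inter], ids=inter_ids, permissive=permissive
    )

    correct_low = int((stratified.mask("low") & ~y).sum())
    correct_high = int((stratified.mask("high") & y).sum())
    correct_conf = confirmatory.n_test_pos_pet_pos + confirmatory.n_test_neg_pet_neg
    total_correct = correct_low + correct_high + correct_conf
    return WorkflowResult(
        strategy_label=strategy_label or stratified.thresholds.strategy.label,
        n=n,
        zone_metrics=zone_metrics,
        confirmatory=confirmatory,
        correct_low=correct_low,
        correct_high=correct_high,
        correct_confirmatory=correct_conf,
        overall_accuracy=100.0 * total_correct / n,
        overall_accuracy_ci=proportion_ci(total_correct, n),
        tests_avoided_fraction=100.0 * (n - int(inter.sum())) / n,
    )
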