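"""Blood-based logistic risk model with internal validation.

The diagnostic model is an ordinary logistic regression for amyloid-PET
positivity,

    logit P(Ab+) = b0 + b1 * log(p-tau217) + b2 * age + b3 * APOEe4,

with plasma p-tau217 natural-log-transformed (right-skewed concentrations)
and age linear.  Development follows clinical-prediction-model practice:

* backward variable elimination inside a bootstrap (per-step Wald p-values
  against a configurable stopping criterion, conventionally alpha = 0.157),
  reporting how often each predictor subset survives;
* Harrell's optimism bootstrap for the AUC: each resample's model is scored
  on its own resample and on the original data, the mean gap is the
  optimism, and corrected AUC = apparent AUC - optimism;
* Nagelkerke pseudo-R2, AIC, and a decile calibration curve.

AUCs are reported on the percentage scale throughout, with DeLong
large-sample confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm, rankdata
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import ConfigurationError, DataError, EstimationError

__all__ = [
    "PredictorSpec",
    "ModelFitStats",
    "FittedRiskModel",
    "SelectionResult",
    "AucResult",
    "CalibrationPoint",
    "default_predictor_spec",
    "fit_logistic",
    "predict_probability",
    "compute_auc",
    "bootstrap_select",
    "optimism_corrected_auc",
    "calibration_curve",
]

log = logging.getLogger(__name__)

_TRANSFORMS = ("natural_log", "identity")
# |coefficient| beyond this on the logit scale is treated as divergence
_SEPARATION_BOUND = 40.0


@dataclass(frozen=True)
class PredictorSpec:
    """Ordered predictor definitions: ((name, transform), ...) plus outcome.

    transform is "natural_log" (predictor must be strictly positive) or
    "identity".
    """

    predictors: tuple[tuple[str, str], ...]
    outcome: str = "abeta_pet_positive"

    def __post_init__(self) -> None:
        names = [n for n, _ in self.predictors]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate predictor names in {names}")
        for n, t in self.predictors:
            if t not in _TRANSFORMS:
                raise ConfigurationError(
                    f"transform for {n!r} must be one of {_TRANSFORMS}, got {t!r}"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.predictors)

    def subset(self, keep) -> "PredictorSpec":
        keep = set(keep)
        return replace(
            self, predictors=tuple(p for p in self.predictors if p[0] in keep)
        )

    def design_matrix(self, data: pd.DataFrame, require_outcome: bool = True):
        """(X with constant, y or None) after applying transforms.

        Raises DataError on missing columns, NaNs, or non-positive values
        under a log transform (complete-case filtering happens upstream).
        """
        missing = [n for n, _ in self.predictors if n not in data.columns]
        if require_outcome and self.outcome not in data.columns:
            missing.append(self.outcome)
        if missing:
            raise DataError(f"cohort is missing required columns: {missing}")
        cols = {}
        for name, transform in self.predictors:
            x = np.asarray(data[name], dtype=float)
            if np.isnan(x).any():
                raise DataError(f"predictor {name!r} contains missing values")
            if transform == "natural_log":
                if (x <= 0).any():
                    raise DataError(
                        f"predictor {name!r} must be strictly positive for log transform"
                    )
                x = np.log(x)
            cols[name] = x
        X = pd.DataFrame(cols, index=data.index)
        X.insert(0, "const", 1.0)
        y = None
        if require_outcome:
            y = np.asarray(data[self.outcome], dtype=float)
            if np.isnan(y).any():
                raise DataError(f"outcome {self.outcome!r} contains missing values")
        return X, y


def default_predictor_spec() -> PredictorSpec:
    """log p-tau217 + linear age + APOE e4 carrier status."""
    return PredictorSpec(
        predictors=(
            ("ptau217", "natural_log"),
            ("age", "identity"),
            ("apoe4", "identity"),
        )
    )


@dataclass(frozen=True)
class CalibrationPoint:
    predicted_mean: float
    observed_fraction: float
    n: int


@dataclass(frozen=True)
class ModelFitStats:
    """Discrimination / goodness-of-fit summary; AUC fields in percent."""

    apparent_auc: float
    optimism: float
    corrected_auc: float
    auc_ci: tuple[float, float]
    nagelkerke_r2: float
    aic: float
    calibration_curve: tuple[CalibrationPoint, ...] = ()

    def __post_init__(self) -> None:
        for v in (self.apparent_auc, self.corrected_auc):
            if not (0.0 <= v <= 100.0):
                raise EstimationError(f"AUC out of range: {v}")
        if abs(self.corrected_auc - (self.apparent_auc - self.optimism)) > 1e-9:
            raise EstimationError("corrected_auc must equal apparent_auc - optimism")
        if not (0.0 <= self.nagelkerke_r2 <= 1.0):
            raise EstimationError(f"Nagelkerke R2 out of range: {self.nagelkerke_r2}")


@dataclass(frozen=True)
class FittedRiskModel:
    """Logistic model: intercept + per-predictor coefficients (log-odds)."""

    intercept: float
    coefficients: dict[str, float]
    predictor_spec: PredictorSpec
    n_fit: int
    fit_stats: ModelFitStats

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        X, _ = self.predictor_spec.design_matrix(data, require_outcome=False)
        lp = np.full(len(X), self.intercept)
        for name, beta in self.coefficients.items():
            lp += beta * X[name].to_numpy()
        return lp

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(data))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "predictors": [list(p) for p in self.predictor_spec.predictors],
            "outcome": self.predictor_spec.outcome,
            "n_fit": self.n_fit,
            "apparent_auc": self.fit_stats.apparent_auc,
            "optimism": self.fit_stats.optimism,
            "corrected_auc": self.fit_stats.corrected_auc,
            "auc_ci": list(self.fit_stats.auc_ci),
            "nagelkerke_r2": self.fit_stats.nagelkerke_r2,
            "aic": self.fit_stats.aic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedRiskModel":
        spec = PredictorSpec(
            predictors=tuple((n, t) for n, t in d["predictors"]), outcome=d["outcome"]
        )
        stats = ModelFitStats(
            apparent_auc=d["apparent_auc"],
            optimism=d["optimism"],
            corrected_auc=d["corrected_auc"],
            auc_ci=tuple(d["auc_ci"]),
            nagelkerke_r2=d["nagelkerke_r2"],
            aic=d["aic"],
        )
        return cls(
            intercept=d["intercept"],
            coefficients=dict(d["coefficients"]),
            predictor_spec=spec,
            n_fit=d["n_fit"],
            fit_stats=stats,
        )


@dataclass(frozen=True)
class AucResult:
    """AUC in percent with a DeLong 95% CI."""

    auc: float
    ci: tuple[float, float]
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class SelectionResult:
    """Bootstrap backward-elimination outcome.

    frequencies maps each surviving predictor subset (sorted name tuple) to
    its fraction among successful resamples; chosen_model is the modal
    subset (ties broken toward the larger subset).
    """

    frequencies: dict[tuple[str, ...], float]
    chosen_model: tuple[str, ...]
    n_boot: int
    alpha: float
    n_redrawn: int = 0
    n_failed: int = 0


def _raw_logit_fit(X: pd.DataFrame, y: np.ndarray):
    """statsmodels Logit fit with separation turned into EstimationError."""
    if y.sum() == 0 or y.sum() == len(y):
        raise DataError("outcome has a single class; logistic fit undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
            raise EstimationError(f"logistic estimation failed: {exc}") from exc
    params = np.asarray(res.params)
    nonconst = [c for c in X.columns if c != "const"]
    big = np.abs(res.params[nonconst]) if nonconst else pd.Series(dtype=float)
    if (not res.mle_retvals.get("converged", True)) or (len(big) and big.max() > _SEPARATION_BOUND):
        worst = big.idxmax() if len(big) else "const"
        raise EstimationError(
            f"quasi-complete separation suspected: coefficient for {worst!r} diverges"
        )
    if not np.isfinite(params).all():
        raise EstimationError("non-finite coefficients in logistic fit")
    return res


def _nagelkerke(res, n: int) -> float:
    ll1, ll0 = res.llf, res.llnull
    denom = 1.0 - np.exp(2.0 * ll0 / n)
    if denom <= 0:
        return 0.0
    r2 = (1.0 - np.exp(2.0 * (ll0 - ll1) / n)) / denom
    return float(min(max(r2, 0.0), 1.0))


def fit_logistic(cohort: pd.DataFrame, spec: PredictorSpec) -> FittedRiskModel:
    """Maximum-likelihood logistic fit with full fit statistics.

    The returned fit_stats carry the apparent AUC (optimism 0 until
    :func:`optimism_corrected_auc` replaces it), Nagelkerke R2, AIC and a
    decile calibration curve on the training data.
    """
    X, y = spec.design_matrix(cohort)
    res = _raw_logit_fit(X, y)
    probs = np.asarray(res.predict(X))
    auc = compute_auc(probs, y)
    stats = ModelFitStats(
        apparent_auc=auc.auc,
        optimism=0.0,
        corrected_auc=auc.auc,
        auc_ci=auc.ci,
        nagelkerke_r2=_nagelkerke(res, len(y)),
        aic=float(res.aic),
        calibration_curve=tuple(calibration_curve(probs, y)),
    )
    coefs = {name: float(res.params[name]) for name in spec.names}
    return FittedRiskModel(
        intercept=float(res.params["const"]),
        coefficients=coefs,
        predictor_spec=spec,
        n_fit=len(y),
        fit_stats=stats,
    )


def predict_probability(model: FittedRiskModel, records: pd.DataFrame) -> np.ndarray:
    """Predicted probability of amyloid-PET positivity for each record."""
    return model.predict(records)


def compute_auc(probabilities, outcomes) -> AucResult:
    """AUC (percent) as pairwise concordance, ties counted 1/2, DeLong 95% CI.

    The point estimate is the Mann-Whitney statistic: the probability that a
    random positive receives a higher score than a random negative.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float).astype(bool)
    if p.shape != y.shape:
        raise DataError("probabilities and outcomes must have the same length")
    m, n = int(y.sum()), int((~y).sum())
    if m == 0 or n == 0:
        raise DataError("AUC requires both outcome classes to be present")

    # DeLong placements via midranks
    ranks_all = rankdata(p)
    ranks_pos = rankdata(p[y])
    ranks_neg = rankdata(p[~y])
    v10 = (ranks_all[y] - ranks_pos) / n          # placement of each positive
    v01 = 1.0 - (ranks_all[~y] - ranks_neg) / m   # placement of each negative
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    zq = norm.ppf(0.975)
    lo = max(0.0, auc - zq * se)
    hi = min(1.0, auc + zq * se)
    return AucResult(auc=100.0 * auc, ci=(100.0 * lo, 100.0 * hi), n_pos=m, n_neg=n)


def _backward_eliminate(X: pd.DataFrame, y: np.ndarray, alpha: float) -> tuple[str, ...]:
    """Drop the worst Wald p-value >= alpha until all survivors beat alpha."""
    cols = [c for c in X.columns if c != "const"]
    while cols:
        res = _raw_logit_fit(X[["const"] + cols], y)
        pvals = res.pvalues[cols]
        worst = pvals.idxmax()
        if pvals[worst] < alpha:
            break
        cols.remove(worst)
    return tuple(sorted(cols))


def _resample_both_classes(rng: np.random.Generator, y: np.ndarray, max_tries: int = 1000):
    """Bootstrap index vector redrawn until both outcome classes appear."""
    n = len(y)
    redraws = 0
    for _ in range(max_tries):
        idx = rng.integers(0, n, n)
        ys = y[idx]
        if 0.0 < ys.mean() < 1.0:
            return idx, redraws
        redraws += 1
    raise EstimationError("could not draw a bootstrap resample containing both classes")


def bootstrap_select(
    cohort: pd.DataFrame,
    spec: PredictorSpec,
    n_boot: int = 1000,
    alpha: float = 0.157,
    seed: int = 0,
) -> SelectionResult:
    """Backward variable elimination inside a bootstrap.

    Each resample (with replacement, original size) gets a full-model fit
    followed by iterative deletion of the predictor with the largest Wald
    p-value >= alpha; the surviving subset is recorded.  Single-class
    resamples are redrawn (counted), estimation failures are logged and
    excluded from the frequencies.
    """
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError("alpha must lie in (0, 1)")
    X, y = spec.design_matrix(cohort)
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, ...], int] = {}
    n_redrawn = n_failed = 0
    for _ in range(n_boot):
        idx, redraws = _resample_both_classes(rng, y)
        n_redrawn += redraws
        try:
            survivors = _backward_eliminate(X.iloc[idx], y[idx], alpha)
        except EstimationError as exc:
            n_failed += 1
            log.info("bootstrap resample excluded: %s", exc)
            continue
        counts[survivors] = counts.get(survivors, 0) + 1
    if not counts:
        raise EstimationError("all bootstrap resamples failed estimation")
    total = sum(counts.values())
    freqs = {k: v / total for k, v in counts.items()}
    # modal subset; ties broken toward the larger subset, then lexicographic
    best = max(freqs.items(), key=lambda kv: (kv[1], len(kv[0]), tuple(reversed(kv[0]))))
    runners = sorted(freqs.items(), key=lambda kv: -kv[1])[:3]
    log.info("bootstrap selection frequencies (top): %s", runners)
    return SelectionResult(
        frequencies=freqs,
        chosen_model=best[0],
        n_boot=n_boot,
        alpha=alpha,
        n_redrawn=n_redrawn,
        n_failed=n_failed,
    )


def optimism_corrected_auc(
    cohort: pd.DataFrame,
    spec: PredictorSpec,
    n_boot: int = 1000,
    seed: int = 0,
    reselect: bool = False,
    alpha: float = 0.157,
) -> ModelFitStats:
    """Harrell's optimism bootstrap for the AUC.

    For each resample: (optionally re-run backward selection, then) fit on
    the resample; optimism_b = AUC(model_b on resample) - AUC(model_b on
    original data).  optimism = mean over resamples; corrected apparent
    AUC and the original-fit R2/AIC/calibration are reported together.
    """
    X, y = spec.design_matrix(cohort)
    res_full = _raw_logit_fit(X, y)
    probs = np.asarray(res_full.predict(X))
    apparent = compute_auc(probs, y)

    rng = np.random.default_rng(seed)
    optimisms = []
    n_failed = 0
    for _ in range(n_boot):
        idx, _ = _resample_both_classes(rng, y)
        Xb, yb = X.iloc[idx], y[idx]
        try:
            if reselect:
                keep = _backward_eliminate(Xb, yb, alpha)
                cols = ["const"] + [c for c in X.columns if c in keep]
            else:
                cols = list(X.columns)
            res_b = _raw_logit_fit(Xb[cols], yb)
            auc_boot = compute_auc(np.asarray(res_b.predict(Xb[cols])), yb).auc
            auc_orig = compute_auc(np.asarray(res_b.predict(X[cols])), y).auc
        except EstimationError as exc:
            n_failed += 1
            log.info("optimism resample excluded: %s", exc)
            continue
        optimisms.append(auc_boot - auc_orig)
    if not optimisms:
        raise EstimationError("all optimism-bootstrap resamples failed estimation")
    if n_failed:
        log.info("optimism bootstrap excluded %d failed resamples", n_failed)
    optimism = float(np.mean(optimisms))
    return ModelFitStats(
        apparent_auc=apparent.auc,
        optimism=optimism,
        corrected_auc=apparent.auc - optimism,
        auc_ci=apparent.ci,
        nagelkerke_r2=_nagelkerke(res_full, len(y)),
        aic=float(res_full.aic),
        calibration_curve=tuple(calibration_curve(probs, y)),
    )


def calibration_curve(probabilities, outcomes, n_bins: int = 10) -> list[CalibrationPoint]:
    """Quantile-binned (default decile) calibration points.

    Bins left empty by heavy ties are merged into their neighbour (logged).
    """
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.size == 0:
        raise DataError("empty probability vector")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 3:  # effectively constant predictions: one bin
        return [CalibrationPoint(float(p.mean()), float(y.mean()), int(p.size))]
    which = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, edges.size - 2)
    points = []
    n_merged = 0
    for b in range(edges.size - 1):
        mask = which == b
        if not mask.any():
            n_merged += 1
            continue
        points.append(
            CalibrationPoint(float(p[mask].mean()), float(y[mask].mean()), int(mask.sum()))
        )
    if n_merged:
        log.info("calibration: %d empty bins merged into neighbours", n_merged)
    return points
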