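"""z-score harmonization of plasma p-tau217 across assays and cohorts.

Different p-tau217 immunoassays report on different concentration scales,
so a model trained on one assay's pg/ml values does not transfer directly.
Expressing each patient's concentration as a z-score against a local
cognitively-unimpaired amyloid-negative reference sample,

    z = (x - mean_ref) / sd_ref,

puts all assays on a common scale: the model is re-fitted once with the
z-scored predictor entering *linearly* (z-scores can be negative, so the
log transform is dropped - a deliberate structural change from the
concentration model), after which the fitted coefficients and the original
probability thresholds are applied unchanged to any external cohort that
supplies its own reference summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import ReferenceSample
from .errors import ConfigurationError, DataError
from .risk_model import FittedRiskModel, PredictorSpec, fit_logistic
from .thresholds import ThresholdSet, stratify
from .workflow import WorkflowResult, evaluate_workflow

__all__ = [
    "ZTransform",
    "z_transform",
    "reference_from_values",
    "refit_on_z",
    "transfer_workflow",
]

#: Below this reference size the z-scale itself is noisy; published
#: reference samples run to a few hundred participants.
MIN_REFERENCE_N = 50


@dataclass(frozen=True)
class ZTransform:
    """A reference-anchored standardization for one assay/cohort."""

    reference: ReferenceSample
    cohort_label: str = ""

    def __post_init__(self) -> None:
        if not self.reference.sd_ptau > 0:
            raise ConfigurationError("reference sd must be > 0")
        if self.reference.n < MIN_REFERENCE_N:
            warnings.warn(
                f"reference sample n = {self.reference.n} < {MIN_REFERENCE_N}; "
                "z-scores will be unstable",
                stacklevel=2,
            )

    def apply(self, values) -> np.ndarray:
        return z_transform(values, self)

    def invert(self, z) -> np.ndarray:
        return self.reference.mean_ptau + self.reference.sd_ptau * np.asarray(z, dtype=float)


def z_transform(values, zt: ZTransform) -> np.ndarray:
    """(x - reference mean) / reference sd, elementwise; NaN propagates."""
    x = np.asarray(values, dtype=float)
    return (x - zt.reference.mean_ptau) / zt.reference.sd_ptau


def reference_from_values(values, assay_label: str = "assay") -> ReferenceSample:
    """Summarize a raw reference-sample concentration vector (helper for
    sites that hold raw values rather than published summaries)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise DataError("reference sample requires >= 2 finite values")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise DataError("reference sample has zero variance")
    return ReferenceSample(n=int(x.size), mean_ptau=float(x.mean()), sd_ptau=sd,
                           assay_label=assay_label)


def _with_z_column(
    cohort: pd.DataFrame, zt: ZTransform, ptau_col: str, z_col: str
) -> pd.DataFrame:
    if ptau_col not in cohort.columns:
        raise DataError(f"cohort has no column {ptau_col!r}")
    out = cohort.copy()
    out[z_col] = z_transform(out[ptau_col], zt)
    return out


def z_predictor_spec(spec: PredictorSpec, ptau_col: str = "ptau217",
                     z_col: str = "ptau217_z") -> PredictorSpec:
    """Replace the (log-)concentration p-tau term with a linear z-score term."""
    if ptau_col not in spec.names:
        raise ConfigurationError(f"spec has no predictor {ptau_col!r} to z-replace")
    predictors = tuple(
        (z_col, "identity") if name == ptau_col else (name, transform)
        for name, transform in spec.predictors
    )
    return replace(spec, predictors=predictors)


def refit_on_z(
    cohort: pd.DataFrame,
    zt: ZTransform,
    spec: PredictorSpec,
    ptau_col: str = "ptau217",
    z_col: str = "ptau217_z",
) -> FittedRiskModel:
    """Re-fit the risk model with z-scored p-tau217 entering linearly."""
    data = _with_z_column(cohort, zt, ptau_col, z_col)
    return fit_logistic(data, z_predictor_spec(spec, ptau_col, z_col))


def transfer_workflow(
    model_z: FittedRiskModel,
    thresholds: ThresholdSet,
    external_cohort: pd.DataFrame,
    zt_external: ZTransform,
    confirmatory_col: str = "csf_positive",
    ptau_col: str = "ptau217",
    z_col: str = "ptau217_z",
    outcome_col: str | None = None,
) -> WorkflowResult:
    """Apply a z-scored model and its ORIGINAL thresholds to a new cohort.

    The external cohort's p-tau217 values (possibly from a different assay)
    are z-scored against the external site's own reference sample; the model
    coefficients and probability thresholds are used unchanged - this is the
    cross-assay validation the z-harmonization exists for.
    """
    if zt_external is None:
        raise DataError("external cohort requires its own reference sample")
    if confirmatory_col not in external_cohort.columns:
        raise DataError(f"cohort has no confirmatory column {confirmatory_col!r}")
    outcome_col = outcome_col or model_z.predictor_spec.outcome
    if outcome_col not in external_cohort.columns:
        raise DataError(f"cohort has no outcome column {outcome_col!r}")
    data = _with_z_column(external_cohort, zt_external, ptau_col, z_col)
    probs = model_z.predict(data)
    stratified = stratify(probs, thresholds, outcomes=data[outcome_col])
    ids = list(data["id"]) if "id" in data.columns else None
    return evaluate_workflow(
        stratified, data[confirmatory_col], ids=ids
    )
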