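"""Synthetic memory-clinic cohorts for the two-step amyloid triage workflow.

Real patient-level data behind blood-based amyloid screening studies are
available only on request, so this module generates seeded cohorts with the
statistical structure the downstream analysis assumes: a roughly 60%
amyloid-PET-positive prevalence among patients with mild cognitive
impairment, strongly right-skewed plasma p-tau217 with a large fold-change
between amyloid-positive and amyloid-negative patients, APOE e4 enrichment
among the positives, bimodal continuous PET SUVr and CSF Ab42/Ab40
distributions, and a second p-tau217 assay on a different concentration
scale.

The cohort container is a pandas DataFrame with the column schema documented
in :data:`COHORT_COLUMNS`; booleans are stored as 0/1 on disk.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigurationError, DataError

__all__ = [
    "CohortConfig",
    "ReferenceSample",
    "COHORT_COLUMNS",
    "REQUIRED_COLUMNS",
    "biofinder_like",
    "generate_cohort",
    "generate_reference_sample",
]

#: Full cohort column schema (order used when writing CSV).
COHORT_COLUMNS = [
    "id",
    "ptau217",
    "ptau217_alt",
    "age",
    "apoe4",
    "pet_suvr",
    "abeta_pet_positive",
    "csf_ratio",
    "csf_positive",
]

#: Columns every cohort must carry; the rest are optional.
REQUIRED_COLUMNS = ["id", "ptau217", "age", "apoe4", "abeta_pet_positive"]


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters for one synthetic cohort.

    ``ptau_neg_mean``/``ptau_neg_sd`` are the arithmetic mean and SD (pg/ml)
    of the log-normal p-tau217 distribution among amyloid-negatives; the
    amyloid-positive geometric mean is ``ptau_fold_change`` times the
    negative geometric mean, with the same log-scale SD unless
    ``ptau_log_sd_ratio`` differs from 1.

    ``pet_suvr_params`` and ``csf_ratio_params`` give per-status Gaussian
    (location, scale) pairs as ``((neg_loc, neg_scale), (pos_loc,
    pos_scale))``.  ``csf_pet_concordance`` is the probability that the
    binary CSF status agrees with the binary PET status.  The second assay
    is ``ptau217 * assay_scale`` perturbed by multiplicative log-normal
    noise with coefficient of variation ``assay_noise_cv``.

    ``age_beta`` (default 0: age independent of amyloid status) adds a
    linear age term, on the log-odds scale per year, to the positivity
    probability.
    """

    n_participants: int = 348
    prevalence: float = 0.60
    ptau_neg_mean: float = 0.153
    ptau_neg_sd: float = 0.077
    ptau_fold_change: float = 3.0
    ptau_log_sd_ratio: float = 1.0
    age_mean: float = 71.0
    age_sd: float = 6.0
    age_beta: float = 0.0
    apoe4_rate_neg: float = 0.35
    apoe4_rate_pos: float = 0.70
    pet_suvr_params: tuple = ((1.02, 0.07), (1.45, 0.20))
    csf_ratio_params: tuple = ((0.095, 0.012), (0.052, 0.010))
    csf_pet_concordance: float = 0.90
    assay_scale: float = 1.0
    assay_noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (isinstance(self.n_participants, (int, np.integer)) and self.n_participants >= 1):
            raise ConfigurationError("n_participants must be a positive integer")
        for name in ("prevalence", "apoe4_rate_neg", "apoe4_rate_pos", "csf_pet_concordance"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        for name in (
            "ptau_neg_mean",
            "ptau_neg_sd",
            "ptau_fold_change",
            "ptau_log_sd_ratio",
            "age_sd",
            "assay_scale",
        ):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigurationError(f"{name} must be > 0, got {v!r}")
        if self.assay_noise_cv < 0:
            raise ConfigurationError(f"assay_noise_cv must be >= 0, got {self.assay_noise_cv!r}")
        for name in ("pet_suvr_params", "csf_ratio_params"):
            params = getattr(self, name)
            try:
                (n_loc, n_sc), (p_loc, p_sc) = params
            except (TypeError, ValueError) as exc:
                raise ConfigurationError(
                    f"{name} must be ((neg_loc, neg_scale), (pos_loc, pos_scale))"
                ) from exc
            if not (n_sc > 0 and p_sc > 0):
                raise ConfigurationError(f"{name} scales must be > 0")

    def replace(self, **kwargs) -> "CohortConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **kwargs)

    def lognormal_params(self, positive: bool) -> tuple[float, float]:
        """(mu, sigma) of log p-tau217 for the given amyloid status.

        The negative-status arithmetic mean/SD are converted to log-scale
        parameters; positives shift the log-mean by log(fold_change).
        """
        cv2 = (self.ptau_neg_sd / self.ptau_neg_mean) ** 2
        sigma = np.sqrt(np.log1p(cv2))
        mu = np.log(self.ptau_neg_mean) - 0.5 * sigma**2
        if positive:
            return mu + np.log(self.ptau_fold_change), sigma * self.ptau_log_sd_ratio
        return mu, sigma


@dataclass(frozen=True)
class ReferenceSample:
    """Summary of a cognitively-unimpaired amyloid-negative reference sample.

    Clinics hold assay reference distributions as summaries, not raw values,
    so only (n, mean, sd) travel with a model.
    """

    n: int
    mean_ptau: float
    sd_ptau: float
    assay_label: str = "assay"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError(f"reference sample n must be >= 2, got {self.n}")
        if not self.sd_ptau > 0:
            raise ConfigurationError(f"reference sd_ptau must be > 0, got {self.sd_ptau!r}")


def biofinder_like(**overrides) -> CohortConfig:
    """Default fixture configuration echoing published memory-clinic cohort
    descriptives: prevalence 0.60, APOE e4 carrier rates 0.35/0.70 by
    amyloid status, p-tau217 fold-change 3.0, n = 348.

    These values are illustrative, not estimates of any specific cohort.
    """
    return CohortConfig(**overrides)


def _draw_status(cfg: CohortConfig, age: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if cfg.age_beta == 0.0:
        return rng.random(cfg.n_participants) < cfg.prevalence
    # Linear age effect on the log-odds scale, centred so the marginal
    # prevalence stays near the configured value.
    if cfg.prevalence in (0.0, 1.0):
        return np.full(cfg.n_participants, bool(cfg.prevalence))
    lp = logit(cfg.prevalence) + cfg.age_beta * (age - cfg.age_mean)
    return rng.random(cfg.n_participants) < expit(lp)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one synthetic cohort as a DataFrame (schema: COHORT_COLUMNS).

    Identical configs (including seed) reproduce bit-identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    n = config.n_participants

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 40.0, 100.0)
    status = _draw_status(config, age, rng)

    mu_neg, sd_neg = config.lognormal_params(False)
    mu_pos, sd_pos = config.lognormal_params(True)
    mu = np.where(status, mu_pos, mu_neg)
    sd = np.where(status, sd_pos, sd_neg)
    ptau = np.exp(rng.normal(mu, sd))

    apoe_rate = np.where(status, config.apoe4_rate_pos, config.apoe4_rate_neg)
    apoe4 = rng.random(n) < apoe_rate

    (sn_loc, sn_sc), (sp_loc, sp_sc) = config.pet_suvr_params
    suvr = rng.normal(np.where(status, sp_loc, sn_loc), np.where(status, sp_sc, sn_sc))
    (cn_loc, cn_sc), (cp_loc, cp_sc) = config.csf_ratio_params
    csf = rng.normal(np.where(status, cp_loc, cn_loc), np.where(status, cp_sc, cn_sc))
    csf = np.maximum(csf, 1e-4)  # ratios are physically positive

    csf_positive = status ^ (rng.random(n) >= config.csf_pet_concordance)

    if config.assay_noise_cv > 0:
        noise_sd = np.sqrt(np.log1p(config.assay_noise_cv**2))
        noise = np.exp(rng.normal(0.0, noise_sd, n))
    else:
        noise = 1.0
    ptau_alt = ptau * config.assay_scale * noise

    return pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(n)],
            "ptau217": ptau,
            "ptau217_alt": ptau_alt,
            "age": age,
            "apoe4": apoe4,
            "pet_suvr": suvr,
            "abeta_pet_positive": status,
            "csf_ratio": csf,
            "csf_positive": csf_positive,
        }
    )


def generate_reference_sample(
    config: CohortConfig, n_ref: int, assay: str = "primary", assay_label: str | None = None
) -> ReferenceSample:
    """Draw an amyloid-negative p-tau217 reference sample and summarize it.

    ``assay="alt"`` draws the same analyte on the second-assay scale
    (``assay_scale`` plus multiplicative noise), matching the cohort's
    ``ptau217_alt`` column.  Uses an RNG stream independent of
    :func:`generate_cohort` so reference and cohort draws do not interleave;
    deterministic for a given (config.seed, n_ref, assay).
    """
    if n_ref < 2:
        raise DataError(f"reference sample requires n_ref >= 2, got {n_ref}")
    if assay not in ("primary", "alt"):
        raise ConfigurationError(f"assay must be 'primary' or 'alt', got {assay!r}")
    config.validate()
    stream = 1 if assay == "primary" else 2
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))
    mu, sd = config.lognormal_params(False)
    values = np.exp(rng.normal(mu, sd, n_ref))
    if assay == "alt":
        values = values * config.assay_scale
        if config.assay_noise_cv > 0:
            noise_sd = np.sqrt(np.log1p(config.assay_noise_cv**2))
            values = values * np.exp(rng.normal(0.0, noise_sd, n_ref))
    return ReferenceSample(
        n=n_ref,
        mean_ptau=float(values.mean()),
        sd_ptau=float(values.std(ddof=1)),
        assay_label=assay_label or assay,
    )
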