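"""Binary biomarker positivity from two-component Gaussian mixture models.

Amyloid-PET SUVr and CSF Ab42/Ab40 are continuous but are used clinically as
binary statuses.  The standard procedure fits a univariate two-component
Gaussian mixture (normal vs abnormal population) and places the cutoff where
the weighted component densities cross, i.e. where posterior membership
probability is 50/50.  PET SUVr is abnormal when high, the CSF ratio when
low; printed cutoffs such as "SUVr >= 1.138" or "ratio <= 0.066" follow the
boundary-inclusive convention replicated by :func:`apply_cutoff`.

The EM fit is fully deterministic: components are initialized by a median
split, iterated to a 1e-8 log-likelihood tolerance (max 500 iterations),
with no random restarts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import norm

from .errors import DataError, DerivationError

__all__ = [
    "GmmFit",
    "BinaryCutoff",
    "fit_two_component_gmm",
    "derive_cutoff",
    "apply_cutoff",
]

log = logging.getLogger(__name__)

_TOL = 1e-8
_MAX_ITER = 500


@dataclass(frozen=True)
class GmmFit:
    """Converged (or max-iteration) two-component univariate Gaussian mixture.

    Components are ordered by ascending mean.  ``loglik_trace`` records the
    log-likelihood at every EM iteration (non-decreasing by construction).
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    loglik: float
    converged: bool
    n_iter: int
    loglik_trace: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise DerivationError(f"mixture weights must sum to 1, got {self.weights}")
        if not all(0.0 < w < 1.0 for w in self.weights):
            raise DerivationError(f"mixture weights must lie in (0, 1), got {self.weights}")
        if not all(s > 0 for s in self.sds):
            raise DerivationError(f"mixture sds must be > 0, got {self.sds}")
        if self.means[0] > self.means[1]:
            raise DerivationError("components must be ordered by ascending mean")


@dataclass(frozen=True)
class BinaryCutoff:
    """A positivity threshold on a marker's own scale.

    direction "abnormal_high": positive iff value >= cutoff (PET SUVr);
    direction "abnormal_low":  positive iff value <= cutoff (CSF Ab42/Ab40).
    ``rule`` records which mixture-to-cutoff rule produced a GMM cutoff.
    """

    value: float
    direction: str
    source: str = "fixed"
    rule: str | None = None
    gmm: GmmFit | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise DerivationError(f"cutoff value must be finite, got {self.value!r}")
        if self.direction not in ("abnormal_high", "abnormal_low"):
            raise DerivationError(
                f"direction must be 'abnormal_high' or 'abnormal_low', got {self.direction!r}"
            )

    def to_json(self) -> str:
        d = {"value": self.value, "direction": self.direction, "source": self.source,
             "rule": self.rule}
        if self.gmm is not None:
            g = asdict(self.gmm)
            g.pop("loglik_trace", None)
            d["gmm"] = g
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BinaryCutoff":
        d = json.loads(text)
        gmm = d.pop("gmm", None)
        if gmm is not None:
            gmm = GmmFit(
                weights=tuple(gmm["weights"]), means=tuple(gmm["means"]),
                sds=tuple(gmm["sds"]), loglik=gmm["loglik"],
                converged=gmm["converged"], n_iter=gmm["n_iter"],
            )
        return cls(gmm=gmm, **d)


def fit_two_component_gmm(values, tol: float = _TOL, max_iter: int = _MAX_ITER) -> GmmFit:
    """EM fit of a univariate two-component Gaussian mixture.

    Deterministic: initialized by splitting the sample at its median.
    Requires >= 10 finite values with nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise DataError(f"need >= 10 finite values to fit a mixture, got {x.size}")
    overall_sd = x.std()
    if overall_sd == 0.0:
        raise DataError("marker values have zero variance; no mixture is identifiable")

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # heavy ties at the median
        lo, hi = x[x < med], x[x >= med]
    if lo.size == 0 or hi.size == 0:
        raise DataError("median split produced an empty component; variance too degenerate")
    sd_floor = 1e-6 * overall_sd
    means = np.array([lo.mean(), hi.mean()])
    sds = np.maximum(np.array([lo.std(), hi.std()]), max(sd_floor, 1e-3 * overall_sd))
    weights = np.array([lo.size, hi.size], dtype=float) / x.size

    trace: list[float] = []
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step in log space for numerical stability
        log_dens = np.log(weights) + norm.logpdf(x[:, None], means, sds)
        log_norm = np.logaddexp(log_dens[:, 0], log_dens[:, 1])
        resp = np.exp(log_dens - log_norm[:, None])
        ll = float(log_norm.sum())
        trace.append(ll)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        sds = np.maximum(np.sqrt(var), sd_floor)
        weights = nk / x.size

    order = np.argsort(means)
    if abs(means[0] - means[1]) < 2.0 * sds.min():
        log.info(
            "GMM components overlap heavily (means %.4g, %.4g); "
            "sample may be effectively unimodal", *means[order]
        )
    return GmmFit(
        weights=tuple(float(w) for w in weights[order]),
        means=tuple(float(m) for m in means[order]),
        sds=tuple(float(s) for s in sds[order]),
        loglik=trace[-1],
        converged=converged,
        n_iter=n_iter,
        loglik_trace=tuple(trace),
    )


def _posterior_crossing(fit: GmmFit) -> float:
    """x in (m1, m2) where w1*N(x; m1, s1) = w2*N(x; m2, s2)."""
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    # log w1 - log s1 - (x-m1)^2/(2 s1^2) = log w2 - log s2 - (x-m2)^2/(2 s2^2)
    a = 0.5 * (1.0 / s2**2 - 1.0 / s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2)) + np.log(w1 / w2) + np.log(s2 / s1)
    if abs(a) < 1e-14:  # equal sds: linear equation
        roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            raise DerivationError("component densities do not cross; cutoff undefined")
        sq = np.sqrt(disc)
        roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if m1 < r < m2]
    if not inside:
        raise DerivationError(
            f"no density crossing between component means ({m1:.4g}, {m2:.4g}); "
            "components overlap too asymmetrically for a posterior-based cutoff"
        )
    return float(inside[0])


def derive_cutoff(
    fit: GmmFit, direction: str, rule: str = "posterior", k: float = 2.0
) -> BinaryCutoff:
    """Turn a mixture fit into a binary cutoff.

    rule "posterior" (default): the point between the component means where
    posterior membership probabilities are equal (weighted-density crossing).
    rule "normal_k_sd": mean +/- k*sd of the *normal* component (the
    lower-mean component for abnormal_high markers, the higher-mean
    component for abnormal_low markers).
    """
    if not fit.converged:
        raise DerivationError("mixture fit did not converge; refusing to derive a cutoff")
    m1, m2 = fit.means
    if abs(m2 - m1) < 1e-12:
        raise DerivationError("component means are equal; no cutoff separates them")
    if rule == "posterior":
        value = _posterior_crossing(fit)
    elif rule == "normal_k_sd":
        if direction == "abnormal_high":
            value = m1 + k * fit.sds[0]
        else:
            value = m2 - k * fit.sds[1]
    else:
        raise DerivationError(f"unknown cutoff rule {rule!r}")
    return BinaryCutoff(value=value, direction=direction, source="gmm", rule=rule, gmm=fit)


def apply_cutoff(values, cutoff: BinaryCutoff):
    """Binarize marker values; missing values stay missing.

    Returns a boolean array when the input has no missing values, otherwise
    a float array with 1.0/0.0/NaN.  Boundary values count as positive in
    both directions, matching the ">=" / "<=" cutoff notation.
    """
    x = np.asarray(values, dtype=float)
    if cutoff.direction == "abnormal_high":
        pos = x >= cutoff.value
    else:
        pos = x <= cutoff.value
    missing = ~np.isfinite(x)
    if not missing.any():
        return pos
    out = pos.astype(float)
    out[missing] = np.nan
    return out
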