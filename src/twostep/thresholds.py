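"""Sensitivity/specificity-anchored probability thresholds and risk zones.

Step 1 of the workflow turns the model's predicted probability of
amyloid-PET positivity into three zones:

* **low risk**   p < lower   — lower is anchored so that at most
  (100 - Se)% of true positives fall below it (a sensitivity floor for the
  non-low zone);
* **high risk**  p >= upper  — upper is anchored so that at most
  (100 - Sp)% of true negatives reach it (a specificity floor);
* **intermediate** otherwise — the only patients referred to confirmatory
  CSF testing.

Thresholds are taken from the empirical grid of observed probabilities:
lower is the *largest* observed value still meeting the sensitivity target,
upper the *smallest* observed value meeting the specificity target, so the
achieved metrics always meet or exceed their targets and printed values are
floors.  Zone boundaries are half-open: intermediate = [lower, upper).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError, DegenerateThresholdError

__all__ = [
    "ThresholdStrategy",
    "ThresholdSet",
    "StratifiedCohort",
    "ZONES",
    "default_strategies",
    "derive_thresholds",
    "stratify",
]

ZONES = ("low", "intermediate", "high")


@dataclass(frozen=True)
class ThresholdStrategy:
    """Paired Se/Sp targets in percent, e.g. ThresholdStrategy(95, 95)."""

    target_sensitivity: float
    target_specificity: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("target_sensitivity", "target_specificity"):
            v = getattr(self, name)
            if not (50.0 < v < 100.0):
                raise ConfigurationError(f"{name} must lie in (50, 100), got {v!r}")
        if not self.label:
            object.__setattr__(self, "label", f"Se/Sp {self.target_sensitivity:g}%")


def default_strategies() -> list[ThresholdStrategy]:
    """The lenient / moderate / stringent paired strategies: 90, 95, 97.5%."""
    return [ThresholdStrategy(t, t) for t in (90.0, 95.0, 97.5)]


@dataclass(frozen=True)
class ThresholdSet:
    """Derived lower/upper probability thresholds for one strategy."""

    lower: float
    upper: float
    strategy: ThresholdStrategy
    achieved_sensitivity: float
    achieved_specificity: float
    derivation_n: int

    def __post_init__(self) -> None:
        if not (0.0 < self.lower <= self.upper < 1.0):
            raise DegenerateThresholdError(
                f"need 0 < lower <= upper < 1, got ({self.lower}, {self.upper})"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "lower": self.lower,
                "upper": self.upper,
                "target_sensitivity": self.strategy.target_sensitivity,
                "target_specificity": self.strategy.target_specificity,
                "label": self.strategy.label,
                "achieved_sensitivity": self.achieved_sensitivity,
                "achieved_specificity": self.achieved_specificity,
                "derivation_n": self.derivation_n,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ThresholdSet":
        d = json.loads(text)
        strategy = ThresholdStrategy(
            d["target_sensitivity"], d["target_specificity"], d["label"]
        )
        return cls(
            lower=d["lower"],
            upper=d["upper"],
            strategy=strategy,
            achieved_sensitivity=d["achieved_sensitivity"],
            achieved_specificity=d["achieved_specificity"],
            derivation_n=d["derivation_n"],
        )


@dataclass
class StratifiedCohort:
    """Per-participant risk zone plus zone-level contingency counts.

    ``contingency[zone]`` is (n_abeta_negative, n_abeta_positive) when
    outcomes were supplied, else None.
    """

    zones: np.ndarray
    thresholds: ThresholdSet
    outcomes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.zones = np.asarray(self.zones, dtype=object)
        if self.outcomes is not None:
            self.outcomes = np.asarray(self.outcomes).astype(bool)
            if len(self.outcomes) != len(self.zones):
                raise DataError("outcomes and zones must have the same length")

    @property
    def n(self) -> int:
        return len(self.zones)

    @property
    def zone_counts(self) -> dict[str, int]:
        return {z: int((self.zones == z).sum()) for z in ZONES}

    @property
    def contingency(self) -> dict[str, tuple[int, int] | None]:
        if self.outcomes is None:
            return {z: None for z in ZONES}
        out = {}
        for z in ZONES:
            mask = self.zones == z
            pos = int((self.outcomes & mask).sum())
            out[z] = (int(mask.sum()) - pos, pos)
        return out

    def mask(self, zone: str) -> np.ndarray:
        return self.zones == zone


def _sensitivity_at(t: float, p_pos: np.ndarray) -> float:
    return float((p_pos >= t).mean())


def _specificity_at(t: float, p_neg: np.ndarray) -> float:
    return float((p_neg < t).mean())


def derive_thresholds(
    probabilities,
    outcomes,
    strategy: ThresholdStrategy,
    round_to_percent: bool = False,
) -> ThresholdSet:
    """Derive the empirical-grid thresholds for one Se/Sp strategy.

    ``round_to_percent=True`` additionally expresses the thresholds as
    integer percentages, rounding conservatively (lower floored, upper
    ceiled) so achieved sensitivity and specificity still meet their
    targets.  When the independently derived thresholds cross (a strongly
    separating model), they collapse to one cutoff meeting both targets
    and the intermediate zone is empty; DegenerateThresholdError is raised
    only if no single cutoff can meet both targets.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    if p.shape != y.shape:
        raise DataError("probabilities and outcomes must have the same length")
    if not ((p >= 0) & (p <= 1)).all():
        raise DataError("probabilities must lie in [0, 1]")
    # logistic predictions can saturate to exactly 0/1 in floating point;
    # nudge inside the open interval so threshold invariants stay valid
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    p_pos, p_neg = p[y], p[~y]
    if p_pos.size == 0 or p_neg.size == 0:
        raise DataError("threshold derivation requires both outcome classes")

    se_target = strategy.target_sensitivity / 100.0
    sp_target = strategy.target_specificity / 100.0
    grid = np.unique(p)

    lower_candidates = grid[[_sensitivity_at(t, p_pos) >= se_target for t in grid]]
    lower = float(lower_candidates.max())  # min(p) always qualifies (Se = 1)

    upper_grid = np.append(grid, 0.5 * (grid.max() + 1.0))  # sentinel: empty high zone
    upper_candidates = upper_grid[[_specificity_at(t, p_neg) >= sp_target for t in upper_grid]]
    upper = float(upper_candidates.min())

    if round_to_percent:
        lower_r = math.floor(lower * 100.0) / 100.0
        upper_r = math.ceil(upper * 100.0) / 100.0
        # keep the unrounded value when rounding would hit the (0, 1) bounds
        lower = lower_r if lower_r > 0.0 else lower
        upper = upper_r if upper_r < 1.0 else upper

    if lower > upper:
        # The independently derived thresholds crossed: the model separates
        # the classes so well that both targets are achievable at a single
        # cutoff.  Collapse to one threshold (empty intermediate zone),
        # picking the grid point meeting both targets with the best combined
        # sensitivity + specificity so the choice is target-independent.
        se_all = np.array([_sensitivity_at(t, p_pos) for t in grid])
        sp_all = np.array([_specificity_at(t, p_neg) for t in grid])
        feasible = (se_all >= se_target) & (sp_all >= sp_target)
        if not feasible.any():
            raise DegenerateThresholdError(
                f"derived lower ({lower:.3f}) exceeds upper ({upper:.3f}) and no "
                f"single cutoff meets both targets for strategy {strategy.label!r}; "
                "consider a less stringent Se/Sp target"
            )
        score = np.where(feasible, se_all + sp_all, -np.inf)
        lower = upper = float(grid[int(np.argmax(score))])
    return ThresholdSet(
        lower=lower,
        upper=upper,
        strategy=strategy,
        achieved_sensitivity=100.0 * _sensitivity_at(lower, p_pos),
        achieved_specificity=100.0 * _specificity_at(upper, p_neg),
        derivation_n=int(p.size),
    )


def stratify(probabilities, thresholds: ThresholdSet, outcomes=None) -> StratifiedCohort:
    """Assign risk zones: low if p < lower, high if p >= upper, else intermediate."""
    p = np.asarray(probabilities, dtype=float)
    zones = np.full(p.shape, "intermediate", dtype=object)
    zones[p < thresholds.lower] = "low"
    zones[p >= thresholds.upper] = "high"
    return StratifiedCohort(zones=zones, thresholds=thresholds, outcomes=outcomes)
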