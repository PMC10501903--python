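"""End-to-end pipeline: develop -> validate -> thresholds -> two-step evaluation.

Reproduces the full analysis sequence on synthetic or user cohorts:

1. fit the blood-based logistic model on the development cohort, run
   bootstrapped backward elimination and Harrell's optimism bootstrap;
2. validate discrimination on a held-out cohort when one is supplied
   (two-cohort mode) or reuse the development cohort (single-cohort mode);
3. derive Se/Sp-anchored probability thresholds on the configured
   derivation set (combined cohorts by default, as appropriate when the
   model validates well and calibrates);
4. stratify and evaluate step 1, step 2 and the whole workflow per
   strategy; optionally re-fit on z-scores and transfer across assays.

All randomness flows from the single configured seed; a manifest with the
package version, seed and config hash makes re-runs checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, DataError
from .harmonization import ZTransform, refit_on_z
from .risk_model import (
    PredictorSpec,
    bootstrap_select,
    compute_auc,
    default_predictor_spec,
    fit_logistic,
    optimism_corrected_auc,
)
from .thresholds import ThresholdStrategy, default_strategies, derive_thresholds, stratify
from .workflow import evaluate_workflow

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "complete_cases"]

log = logging.getLogger(__name__)


def complete_cases(cohort: pd.DataFrame, columns) -> pd.DataFrame:
    """Drop rows missing any analysis column, logging the excluded count."""
    cols = [c for c in columns if c in cohort.columns]
    missing = [c for c in columns if c not in cohort.columns]
    if missing:
        raise DataError(f"cohort is missing analysis columns: {missing}")
    mask = cohort[cols].notna().all(axis=1)
    n_excluded = int((~mask).sum())
    if n_excluded:
        log.info("complete-case filter excluded %d of %d rows", n_excluded, len(cohort))
    return cohort.loc[mask]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run (paths optional; DataFrames accepted)."""

    dev_cohort: pd.DataFrame | None = None
    val_cohort: pd.DataFrame | None = None
    predictor_spec: PredictorSpec = field(default_factory=default_predictor_spec)
    strategies: list[ThresholdStrategy] = field(default_factory=default_strategies)
    n_boot: int = 1000
    alpha: float = 0.157
    seed: int = 0
    confirmatory_col: str = "csf_positive"
    threshold_set: str = "combined"  # "combined" | "dev" | "val"
    reselect_optimism: bool = False
    run_z_model: bool = False
    dev_reference: object | None = None  # ReferenceSample for the z-model
    output_dir: str | Path | None = None

    def validate(self) -> None:
        if self.dev_cohort is None:
            raise ConfigurationError("dev_cohort is required (generate one via twostep.cohort)")
        if not self.strategies:
            raise ConfigurationError("strategies must be non-empty")
        if self.threshold_set not in ("combined", "dev", "val"):
            raise ConfigurationError(
                f"threshold_set must be 'combined', 'dev' or 'val', got {self.threshold_set!r}"
            )
        if self.run_z_model and self.dev_reference is None:
            raise ConfigurationError("run_z_model requires dev_reference")

    def settings_dict(self) -> dict:
        return {
            "predictors": [list(p) for p in self.predictor_spec.predictors],
            "outcome": self.predictor_spec.outcome,
            "strategies": [
                [s.target_sensitivity, s.target_specificity] for s in self.strategies
            ],
            "n_boot": self.n_boot,
            "alpha": self.alpha,
            "seed": self.seed,
            "confirmatory_col": self.confirmatory_col,
            "threshold_set": self.threshold_set,
            "reselect_optimism": self.reselect_optimism,
            "run_z_model": self.run_z_model,
        }


@dataclass
class PipelineResult:
    model: object
    selection: object
    fit_stats: object
    validation_auc: object | None
    thresholds: dict
    workflows: dict
    z_model: object | None
    metrics: dict
    manifest: dict


def _config_hash(settings: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(settings, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; writes artifacts when output_dir is set."""
    config.validate()
    spec = config.predictor_spec
    analysis_cols = list(spec.names) + [spec.outcome, config.confirmatory_col]

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            try:
                wrapped = type(exc)(f"pipeline stage {name!r}: {exc}")
            except Exception:
                raise  # exotic constructor: propagate the original
            raise wrapped from exc

    dev = _stage("develop/complete-case", complete_cases, config.dev_cohort, analysis_cols)
    two_cohort = config.val_cohort is not None
    val = (
        _stage("validate/complete-case", complete_cases, config.val_cohort, analysis_cols)
        if two_cohort
        else dev
    )

    # develop
    selection = _stage(
        "develop/selection",
        bootstrap_select,
        dev, spec, n_boot=config.n_boot, alpha=config.alpha, seed=config.seed,
    )
    chosen_spec = spec.subset(selection.chosen_model)
    fit_stats = _stage(
        "develop/optimism",
        optimism_corrected_auc,
        dev, chosen_spec, n_boot=config.n_boot, seed=config.seed + 1,
        reselect=config.reselect_optimism, alpha=config.alpha,
    )
    model = _stage("develop/fit", fit_logistic, dev, chosen_spec)
    model = dataclasses.replace(model, fit_stats=fit_stats)

    # validate
    validation_auc = None
    if two_cohort:
        val_probs = model.predict(val)
        validation_auc = _stage(
            "validate/auc", compute_auc, val_probs, val[spec.outcome]
        )

    # threshold derivation set
    if config.threshold_set == "dev":
        der = dev
    elif config.threshold_set == "val":
        der = val
    else:
        der = pd.concat([dev, val]) if two_cohort else dev
    der_probs = model.predict(der)

    thresholds, workflows = {}, {}
    eval_set = pd.concat([dev, val]) if two_cohort else dev
    eval_probs = model.predict(eval_set)
    for strategy in config.strategies:
        ts = _stage(
            f"thresholds/{strategy.label}",
            derive_thresholds, der_probs, der[spec.outcome], strategy,
        )
        thresholds[strategy.label] = ts
        stratified = stratify(eval_probs, ts, outcomes=eval_set[spec.outcome])
        workflows[strategy.label] = _stage(
            f"workflow/{strategy.label}",
            evaluate_workflow,
            stratified, eval_set[config.confirmatory_col],
            ids=list(eval_set["id"]) if "id" in eval_set.columns else None,
        )

    z_model = None
    if config.run_z_model:
        zt = ZTransform(config.dev_reference)
        z_model = _stage("harmonize/refit", refit_on_z, dev, zt, chosen_spec)

    metrics = {
        "selection": {
            "chosen_model": list(selection.chosen_model),
            "frequencies": {
                "+".join(k) if k else "(intercept only)": v
                for k, v in sorted(selection.frequencies.items(), key=lambda kv: -kv[1])
            },
            "n_redrawn": selection.n_redrawn,
            "n_failed": selection.n_failed,
        },
        "development": {
            "n": int(len(dev)),
            "apparent_auc": fit_stats.apparent_auc,
            "optimism": fit_stats.optimism,
            "corrected_auc": fit_stats.corrected_auc,
            "auc_ci": list(fit_stats.auc_ci),
            "nagelkerke_r2": fit_stats.nagelkerke_r2,
            "aic": fit_stats.aic,
        },
        "validation": (
            {
                "n": int(len(val)),
                "auc": validation_auc.auc,
                "auc_ci": list(validation_auc.ci),
            }
            if validation_auc is not None
            else None
        ),
        "thresholds": {
            label: json.loads(ts.to_json()) for label, ts in thresholds.items()
        },
        "workflows": {label: wf.to_dict() for label, wf in workflows.items()},
    }
    manifest = {
        "package": "twostep",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config.settings_dict()),
        "settings": config.settings_dict(),
        "n_dev": int(len(dev)),
        "n_val": int(len(val)) if two_cohort else None,
    }

    if config.output_dir is not None:
        from .io import save_model, save_thresholds  # local import avoids cycle

        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_model(model, outdir / "model.json")
        if z_model is not None:
            save_model(z_model, outdir / "model_z.json")
        for label, ts in thresholds.items():
            safe = label.replace("/", "-").replace(" ", "_").replace("%", "")
            save_thresholds(ts, outdir / f"thresholds_{safe}.json")
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (outdir / "report.md").write_text(render_report(metrics))

    return PipelineResult(
        model=model,
        selection=selection,
        fit_stats=fit_stats,
        validation_auc=validation_auc,
        thresholds=thresholds,
        workflows=workflows,
        z_model=z_model,
        metrics=metrics,
        manifest=manifest,
    )


def render_report(metrics: dict) -> str:
    """Human-readable Markdown report: model summary, per-strategy risk-zone
    table and two-step workflow counts."""
    dev = metrics["development"]
    lines = [
        "# Two-step amyloid triage workflow report",
        "",
        "## Blood-based risk model",
        f"- development n = {dev['n']}",
        f"- apparent AUC = {dev['apparent_auc']:.1f}%, optimism = {dev['optimism']:.2f}, "
        f"corrected AUC = {dev['corrected_auc']:.1f}%",
        f"- Nagelkerke R2 = {dev['nagelkerke_r2']:.3f}, AIC = {dev['aic']:.1f}",
        f"- selected predictors: {', '.join(metrics['selection']['chosen_model'])}",
    ]
    if metrics.get("validation"):
        v = metrics["validation"]
        lines.append(
            f"- external validation: n = {v['n']}, AUC = {v['auc']:.1f}% "
            f"(95% CI {v['auc_ci'][0]:.1f}-{v['auc_ci'][1]:.1f}%)"
        )
    lines += ["", "## Risk stratification and two-step workflow", ""]
    for label, wf in metrics["workflows"].items():
        z = wf["zones"]
        c = wf["confirmatory"]
        lines += [
            f"### {label}",
            "",
            "| zone | n | Ab-PET negative | Ab-PET positive | metric |",
            "|---|---|---|---|---|",
        ]
        for zone in ("low", "intermediate", "high"):
            m = z[zone]
            val = f"{m['value']:.1f}% {m['metric']}" if m["value"] is not None else "undefined"
            lines.append(
                f"| {zone} | {m['n']} | {m['n_abeta_negative']} | "
                f"{m['n_abeta_positive']} | {val} |"
            )
        ppv = f"{c['ppv']:.1f}%" if c["ppv"] is not None else "undefined"
        npv = f"{c['npv']:.1f}%" if c["npv"] is not None else "undefined"
        lines += [
            "",
            f"- confirmatory test (intermediate zone, n = {c['n_tested']}): "
            f"PPV {ppv}, NPV {npv}",
            f"- overall accuracy = {wf['overall_accuracy']:.1f}% "
            f"(95% CI {wf['overall_accuracy_ci'][0]:.1f}-{wf['overall_accuracy_ci'][1]:.1f}%)",
            f"- confirmatory tests avoided: {wf['tests_avoided_fraction']:.1f}% of the cohort",
            "",
        ]
    return "\n".join(lines)
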