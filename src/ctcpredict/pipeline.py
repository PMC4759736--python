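"""End-to-end orchestration of the discovery and validation workflows.

``run_discovery`` wires the stages in paper order: quality gates ->
delta-Ct normalization -> variance filter -> responder labeling -> nested
LOOCV -> permutation test -> full-cohort predictor -> 2x2 test performance
-> survival analysis by profile -> hierarchical clustering of the
signature.  ``run_external_validation`` applies a frozen model to a new
cohort (no retraining) and evaluates it the same way.

Every run writes a ``manifest.json`` recording the package version, seed,
a hash of the configuration, and per-stage sample accounting so a cohort's
78 -> 73 -> 45 style attrition is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .datatypes import (
    ConfigurationError,
    CtMatrix,
    ExpressionMatrix,
    PipelineError,
    PredictorModel,
    profile_from_class,
    validate_clinical,
)
from . import cluster as cluster_mod
from . import performance as perf_mod
from . import prediction as pred_mod
from . import qc as qc_mod
from . import survival as surv_mod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths plus the analysis constants, all overridable.

    Defaults are the study constants: reference gate at 26 Ct, top-75%
    variance filter, univariate alpha 0.1, 9-month (274-day) outcome
    dichotomy, 100 label permutations.
    """

    ct_path: str = "ct.tsv"
    roles_path: str = "gene_roles.tsv"
    clinical_path: str = "clinical.tsv"
    out_dir: str = "results"
    reference_ct_cutoff: float = 26.0
    epithelial_min_detected: int = 1
    epithelial_min_delta_ct: float = -15.0
    undetected_ct: float = 40.0
    keep_fraction: float = 0.75
    alpha: float = 0.1
    cutoff_days: float = 274.0
    n_permutations: int = 100
    svm_cost: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.keep_fraction <= 1:
            raise ConfigurationError("keep_fraction must lie in (0, 1]")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.cutoff_days <= 0:
            raise ConfigurationError("cutoff_days must be > 0")
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if self.reference_ct_cutoff <= 0:
            raise ConfigurationError("reference_ct_cutoff must be > 0")
        if self.epithelial_min_detected < 0:
            raise ConfigurationError("epithelial_min_detected must be >= 0")
        if self.svm_cost <= 0:
            raise ConfigurationError("svm_cost must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            # user-input problems keep their type (CLI maps them to exit 1);
            # anything else is surfaced as a stage failure
            passthrough = (PipelineError, FileNotFoundError, ConfigurationError)
            if exc is not None and not isinstance(exc, passthrough):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def _load_inputs(config: PipelineConfig) -> tuple[CtMatrix, pd.DataFrame]:
    for p in (config.ct_path, config.roles_path, config.clinical_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    ct = CtMatrix.from_tsv(config.ct_path, config.roles_path)
    clinical = validate_clinical(
        pd.read_csv(config.clinical_path, sep="\t", index_col="sample")
    )
    missing = set(ct.samples) - set(clinical.index)
    if missing:
        raise PipelineError(f"samples without clinical data: {sorted(missing)[:5]}")
    return ct, clinical.loc[ct.samples]


@dataclass
class DiscoveryResult:
    """All artifacts of a discovery run (also written to ``out_dir``)."""

    qc_report: qc_mod.QcReport
    expression: ExpressionMatrix
    labels: pd.Series
    cross_val: pred_mod.CrossValResult
    model: PredictorModel
    calls: pd.Series  # profile per retained sample
    confusion: perf_mod.ConfusionTable
    metrics: perf_mod.TestMetrics
    logrank: tuple[float, float]
    cox: Optional[surv_mod.CoxResult]
    cluster: cluster_mod.ClusterResult
    manifest: dict = field(default_factory=dict)


def run_discovery(config: PipelineConfig) -> DiscoveryResult:
    """Run the full discovery workflow and write its artifact set."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("load"):
        ct, clinical = _load_inputs(config)

    with _stage("qc"):
        retained_ct, qc_report = qc_mod.apply_qc(
            ct,
            reference_cutoff=config.reference_ct_cutoff,
            epithelial_min_detected=config.epithelial_min_detected,
            epithelial_min_delta_ct=config.epithelial_min_delta_ct,
        )
        qc_report.to_tsv(out / "qc_report.tsv")
        expr = qc_mod.delta_ct_normalize(retained_ct, undetected_ct=config.undetected_ct)
        expr.to_tsv(out / "expression.tsv")

    with _stage("variance_filter"):
        filtered = qc_mod.variance_filter(expr, keep_fraction=config.keep_fraction)

    with _stage("label"):
        resp = surv_mod.label_responders(
            clinical.loc[retained_ct.samples], cutoff_days=config.cutoff_days
        )
        labels = resp.labels
        analysis_samples = list(labels.index)
        filtered = filtered.subset_samples(analysis_samples)

    with _stage("loocv"):
        cv = pred_mod.loocv(filtered, labels, alpha=config.alpha, cost=config.svm_cost)

    with _stage("permutation"):
        cv = pred_mod.permutation_test(
            filtered,
            labels,
            n_permutations=config.n_permutations,
            seed=config.seed,
            alpha=config.alpha,
            cost=config.svm_cost,
            observed=cv,
        )
        (out / "cross_val.json").write_text(json.dumps(cv.to_dict(), indent=2))

    with _stage("finalize"):
        model = pred_mod.finalize_predictor(
            filtered, labels, alpha=config.alpha, cost=config.svm_cost
        )
        model.metadata.update(
            {"seed": config.seed, "config_hash": config.config_hash()}
        )
        model.save(out / "model.json")
        calls = profile_from_class(pred_mod.apply_predictor(model, filtered))
        calls.rename("profile").to_csv(out / "calls.tsv", sep="\t", index_label="sample")

    with _stage("evaluate"):
        tab = perf_mod.confusion(calls, labels)
        mets = perf_mod.metrics(tab)
        mets.to_json(out / "metrics.json")
        tab.to_frame().to_csv(out / "confusion.tsv", sep="\t")

    with _stage("survival"):
        clin = clinical.loc[analysis_samples]
        km = surv_mod.kaplan_meier(clin["pfs_days"], clin["event"], calls)
        surv_mod.km_to_tsv(km, out / "km.tsv")
        lr = surv_mod.logrank(clin["pfs_days"], clin["event"], calls)
        cov = surv_mod.encode_covariates(clin, profile=calls)
        cox: Optional[surv_mod.CoxResult] = None
        try:
            cox = surv_mod.cox_fit(clin["pfs_days"], clin["event"], cov)
            cox.to_json(out / "cox.json")
        except (PipelineError, ValueError) as exc:
            logger.warning("cox fit skipped: %s", exc)

    with _stage("cluster"):
        signature_expr = expr.subset_genes(model.genes).subset_samples(
            analysis_samples
        )
        clu = cluster_mod.cluster_expression(signature_expr)
        ann = pd.DataFrame(
            {"class": labels, "ctc_count": clinical.loc[analysis_samples, "ctc_count"]}
        )
        cluster_mod.export_clustered(clu, out, basename="signature", annotations=ann)

    counts = qc_report.counts
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "counts": {
            **counts,
            "n_unevaluable_outcome": len(resp.unevaluable),
            "n_analyzed": len(analysis_samples),
            "n_poor": resp.n_poor,
            "n_good": resp.n_good,
        },
        "signature_genes": model.genes,
        "loocv_error": cv.error,
        "permutation_p": cv.permutation_p,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return DiscoveryResult(
        qc_report=qc_report,
        expression=expr,
        labels=labels,
        cross_val=cv,
        model=model,
        calls=calls,
        confusion=tab,
        metrics=mets,
        logrank=lr,
        cox=cox,
        cluster=clu,
        manifest=manifest,
    )


@dataclass
class ValidationResult:
    """Artifacts from applying a frozen model to an independent cohort."""

    calls: pd.Series
    confusion: perf_mod.ConfusionTable
    metrics: perf_mod.TestMetrics
    logrank: tuple[float, float]
    manifest: dict = field(default_factory=dict)


def run_external_validation(
    config: PipelineConfig, model_path: str | Path
) -> ValidationResult:
    """Apply a trained predictor to a new cohort without retraining."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not Path(model_path).exists():
        raise FileNotFoundError(f"model file not found: {model_path}")
    model = PredictorModel.load(model_path)

    with _stage("load"):
        ct, clinical = _load_inputs(config)

    with _stage("qc"):
        retained_ct, qc_report = qc_mod.apply_qc(
            ct,
            reference_cutoff=config.reference_ct_cutoff,
            epithelial_min_detected=config.epithelial_min_detected,
            epithelial_min_delta_ct=config.epithelial_min_delta_ct,
        )
        expr = qc_mod.delta_ct_normalize(
            retained_ct, undetected_ct=config.undetected_ct
        )

    with _stage("predict"):
        missing = [g for g in model.genes if g not in expr.delta_ct.index]
        if missing:
            raise PipelineError(
                f"model genes absent from validation cohort: {missing}"
            )
        calls = profile_from_class(pred_mod.apply_predictor(model, expr))
        calls.rename("profile").to_csv(
            out / "validation_calls.tsv", sep="\t", index_label="sample"
        )

    with _stage("evaluate"):
        resp = surv_mod.label_responders(
            clinical.loc[retained_ct.samples], cutoff_days=config.cutoff_days
        )
        eval_samples = list(resp.labels.index)
        tab = perf_mod.confusion(calls.loc[eval_samples], resp.labels)
        mets = perf_mod.metrics(tab)
        mets.to_json(out / "validation_metrics.json")

    with _stage("survival"):
        clin = clinical.loc[eval_samples]
        lr = surv_mod.logrank(clin["pfs_days"], clin["event"], calls.loc[eval_samples])

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "counts": {
            **qc_report.counts,
            "n_evaluated": len(eval_samples),
            "n_unfavorable": int((calls == "unfavorable").sum()),
            "n_favorable": int((calls == "favorable").sum()),
        },
        "chi_square": mets.chi_square,
        "chi_p": mets.chi_p,
    }
    (out / "validation_manifest.json").write_text(json.dumps(manifest, indent=2))
    return ValidationResult(
        calls=calls, confusion=tab, metrics=mets, logrank=lr, manifest=manifest
    )
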