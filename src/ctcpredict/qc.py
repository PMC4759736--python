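"""Reference-gene normalization and sample quality gates.

Two gates are applied in fixed order:

1. *reference gate* — the arithmetic mean Ct of the detected reference
   genes must not exceed a cutoff (default 26 cycles; the boundary value
   itself passes); samples with no detected reference gene are
   unevaluable and fail;
2. *epithelial gate* — among samples passing the reference gate, at least
   ``min_detected`` genes of the epithelial cluster must be detected with
   delta-Ct at or above ``min_delta_ct``.

Relative expression of the surviving samples is the delta-Ct,
``mean reference Ct - target Ct``; undetected targets are imputed at a
detection-limit Ct before normalization so they rank lowest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CtMatrix, ExpressionMatrix, PipelineError

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_CUTOFF = 26.0
DEFAULT_UNDETECTED_CT = 40.0
DEFAULT_EPITHELIAL_MIN_DETECTED = 1
DEFAULT_EPITHELIAL_MIN_DELTA_CT = -15.0


def mean_reference_ct(ct: CtMatrix, sample: str | None = None):
    """Mean Ct of the *detected* reference genes.

    With ``sample`` given returns a float (NaN when no reference gene was
    detected, flagging the sample unevaluable); otherwise a per-sample
    Series.
    """
    ref = ct.ct.loc[ct.reference_genes]
    means = ref.mean(axis=0, skipna=True)
    if sample is not None:
        if sample not in means.index:
            raise KeyError(f"unknown sample {sample!r}")
        return float(means[sample])
    return means


def reference_detected_count(ct: CtMatrix) -> pd.Series:
    """How many reference genes were detected per sample."""
    return ct.ct.loc[ct.reference_genes].notna().sum(axis=0)


def reference_quality_gate(
    ct: CtMatrix, cutoff: float = DEFAULT_REFERENCE_CUTOFF
) -> pd.Series:
    """Pass iff mean reference Ct <= cutoff; unevaluable samples fail."""
    means = mean_reference_ct(ct)
    return (means <= cutoff).fillna(False).astype(bool)


def epithelial_quality_gate(
    ct: CtMatrix,
    min_detected: int = DEFAULT_EPITHELIAL_MIN_DETECTED,
    min_delta_ct: float = DEFAULT_EPITHELIAL_MIN_DELTA_CT,
) -> pd.Series:
    """Pass iff >= ``min_detected`` epithelial genes are detected with
    delta-Ct >= ``min_delta_ct``.

    Computed for every sample; the pipeline applies it only to samples
    that already passed the reference gate.
    """
    epi = ct.ct.loc[ct.epithelial_genes]
    delta = mean_reference_ct(ct) - epi  # NaN stays NaN for undetected
    ok = (delta >= min_delta_ct).sum(axis=0)
    return (ok >= min_detected).astype(bool)


@dataclass
class QcReport:
    """Per-sample gate outcomes plus exclusion accounting in gate order."""

    per_sample: pd.DataFrame
    excluded_reference: list[str]
    excluded_epithelial: list[str]
    retained: list[str]

    @property
    def counts(self) -> dict[str, int]:
        n0 = len(self.per_sample)
        return {
            "n_initial": n0,
            "n_excluded_reference_gate": len(self.excluded_reference),
            "n_after_reference_gate": n0 - len(self.excluded_reference),
            "n_excluded_epithelial_gate": len(self.excluded_epithelial),
            "n_retained": len(self.retained),
        }

    def to_tsv(self, path: str | Path) -> None:
        self.per_sample.to_csv(path, sep="\t", index_label="sample")


def apply_qc(
    ct: CtMatrix,
    reference_cutoff: float = DEFAULT_REFERENCE_CUTOFF,
    epithelial_min_detected: int = DEFAULT_EPITHELIAL_MIN_DETECTED,
    epithelial_min_delta_ct: float = DEFAULT_EPITHELIAL_MIN_DELTA_CT,
) -> tuple[CtMatrix, QcReport]:
    """Apply both gates in order and return the retained matrix + report."""
    ref_mean = mean_reference_ct(ct)
    ref_pass = reference_quality_gate(ct, cutoff=reference_cutoff)
    epi_detected = epithelial_quality_gate(
        ct, min_detected=epithelial_min_detected, min_delta_ct=epithelial_min_delta_ct
    )
    epi_count = (
        (ref_mean - ct.ct.loc[ct.epithelial_genes] >= epithelial_min_delta_ct)
        .sum(axis=0)
        .astype(int)
    )

    samples = ct.samples
    excluded_reference = [s for s in samples if not ref_pass[s]]
    epi_pass = ref_pass & epi_detected
    excluded_epithelial = [s for s in samples if ref_pass[s] and not epi_detected[s]]
    retained = [s for s in samples if epi_pass[s]]

    report = QcReport(
        per_sample=pd.DataFrame(
            {
                "mean_reference_ct": ref_mean,
                "reference_detected": reference_detected_count(ct),
                "reference_pass": ref_pass,
                "epithelial_detected": epi_count,
                "epithelial_pass": epi_pass,
                "retained": pd.Series(
                    [s in set(retained) for s in samples], index=samples
                ),
            }
        ),
        excluded_reference=excluded_reference,
        excluded_epithelial=excluded_epithelial,
        retained=retained,
    )
    return ct.subset_samples(retained), report


def delta_ct_normalize(
    ct: CtMatrix, undetected_ct: float = DEFAULT_UNDETECTED_CT
) -> ExpressionMatrix:
    """Delta-Ct normalization: ``mean reference Ct - target Ct``.

    Undetected non-reference genes are imputed at ``undetected_ct`` cycles
    (detection-limit convention) before subtraction.  Reference genes are
    dropped from the output, so a 96-gene panel yields 93 targets.
    """
    if not ct.samples:
        raise PipelineError("delta_ct_normalize: no samples retained after QC")
    ref_mean = mean_reference_ct(ct)
    if ref_mean.isna().any():
        bad = list(ref_mean.index[ref_mean.isna()])
        raise PipelineError(
            f"delta_ct_normalize: no detected reference gene in samples {bad}"
        )
    non_ref = [g for g in ct.genes if g not in set(ct.reference_genes)]
    values = ct.ct.loc[non_ref].fillna(undetected_ct)
    delta = ref_mean - values  # broadcast over rows
    return ExpressionMatrix(delta)


def variance_filter(
    expr: ExpressionMatrix, keep_fraction: float = 0.75
) -> ExpressionMatrix:
    """Keep the ``ceil(keep_fraction * G)`` most variable genes.

    Variance is the unbiased (n-1) across-sample variance of delta-Ct;
    ties break by panel order.  Output preserves panel order.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    if expr.n_samples < 2:
        raise ValueError("variance_filter requires >= 2 samples")
    k = math.ceil(keep_fraction * expr.n_genes)
    var = expr.delta_ct.var(axis=1, ddof=1)
    if float(var.max()) == 0.0:
        logger.warning(
            "variance_filter: all genes constant; keeping first %d in panel order", k
        )
    order = sorted(range(expr.n_genes), key=lambda i: (-var.iloc[i], i))
    keep_idx = sorted(order[:k])
    return ExpressionMatrix(expr.delta_ct.iloc[keep_idx])
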