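"""Core containers shared by the pipeline stages.

Conventions used throughout the package:

* a Ct (cycle-threshold) matrix is genes x samples; ``NaN`` means the
  transcript was not detected within the instrument's cycle range;
* relative expression is the delta-Ct, ``mean reference Ct - target Ct``,
  so *higher* delta-Ct means *more* transcript;
* responder classes are ``"good"`` / ``"poor"`` (progression or death
  before the PFS cut-off); classifier calls map to the profile labels
  ``"favorable"`` / ``"unfavorable"`` (unfavorable = predicted poor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

GOOD = "good"
POOR = "poor"
FAVORABLE = "favorable"
UNFAVORABLE = "unfavorable"

ROLE_REFERENCE = "reference"
ROLE_EPITHELIAL = "epithelial"
ROLE_TARGET = "target"
GENE_ROLES = (ROLE_REFERENCE, ROLE_EPITHELIAL, ROLE_TARGET)

#: housekeeping transcripts used for normalization
DEFAULT_REFERENCE_GENES = ("HMBS", "HPRT1", "GUSB")

CT_MAX = 45.0


class ConfigurationError(ValueError):
    """A configuration value is out of its documented range."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def profile_from_class(calls: pd.Series) -> pd.Series:
    """Map responder-class calls (good/poor) to profile labels."""
    mapping = {GOOD: FAVORABLE, POOR: UNFAVORABLE}
    bad = set(calls.unique()) - set(mapping)
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    return calls.map(mapping)


@dataclass
class CtMatrix:
    """Raw qRT-PCR cycle-threshold values with detection status.

    Parameters
    ----------
    ct
        genes x samples frame of Ct values in cycles; ``NaN`` encodes an
        undetected transcript (no numeric stand-in is ever stored here).
    gene_roles
        Series indexed like ``ct`` rows with values ``reference``,
        ``epithelial`` or ``target``.
    """

    ct: pd.DataFrame
    gene_roles: pd.Series

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        self.ct.index.name = "gene"
        self.ct.columns.name = None
        self.gene_roles = self.gene_roles.reindex(self.ct.index)
        self.gene_roles.index.name = "gene"
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.ct.index)

    @property
    def samples(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def detected(self) -> pd.DataFrame:
        return self.ct.notna()

    def genes_with_role(self, role: str) -> list[str]:
        return list(self.gene_roles.index[self.gene_roles == role])

    @property
    def reference_genes(self) -> list[str]:
        return self.genes_with_role(ROLE_REFERENCE)

    @property
    def epithelial_genes(self) -> list[str]:
        return self.genes_with_role(ROLE_EPITHELIAL)

    @property
    def target_genes(self) -> list[str]:
        return self.genes_with_role(ROLE_TARGET)

    def validate(self) -> None:
        if self.gene_roles.isna().any():
            missing = list(self.gene_roles.index[self.gene_roles.isna()])
            raise ValueError(f"genes without a role: {missing[:5]}")
        bad_roles = set(self.gene_roles.unique()) - set(GENE_ROLES)
        if bad_roles:
            raise ValueError(f"unknown gene roles: {sorted(bad_roles)}")
        vals = self.ct.to_numpy()
        present = ~np.isnan(vals)
        if present.any():
            v = vals[present]
            if (v <= 0).any() or (v > CT_MAX).any():
                raise ValueError(f"Ct values must lie in (0, {CT_MAX}]")

    def subset_samples(self, samples: Sequence[str]) -> "CtMatrix":
        return CtMatrix(self.ct.loc[:, list(samples)], self.gene_roles)

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, ct_path: str | Path, roles_path: str | Path) -> None:
        self.ct.to_csv(ct_path, sep="\t", na_rep="NA", index_label="gene")
        self.gene_roles.rename("role").to_csv(
            roles_path, sep="\t", index_label="gene"
        )

    @classmethod
    def from_tsv(cls, ct_path: str | Path, roles_path: str | Path) -> "CtMatrix":
        ct = pd.read_csv(ct_path, sep="\t", index_col="gene", na_values=["NA"])
        roles = pd.read_csv(roles_path, sep="\t", index_col="gene")["role"]
        return cls(ct, roles)


@dataclass
class ExpressionMatrix:
    """Delta-Ct relative expression, genes x samples (references removed)."""

    delta_ct: pd.DataFrame

    def __post_init__(self) -> None:
        self.delta_ct = self.delta_ct.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.delta_ct.index)

    @property
    def samples(self) -> list[str]:
        return list(self.delta_ct.columns)

    @property
    def n_genes(self) -> int:
        return self.delta_ct.shape[0]

    @property
    def n_samples(self) -> int:
        return self.delta_ct.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.delta_ct.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.delta_ct.loc[:, list(samples)])

    def to_tsv(self, path: str | Path) -> None:
        self.delta_ct.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="gene"))


#: required columns of a clinical table
CLINICAL_COLUMNS = (
    "pfs_days",
    "event",
    "ctc_count",
    "ctc_group",
    "dfi_group",
    "relapse_site",
    "treatment",
)

DFI_GROUPS = ("<=5y", ">5y", "metastatic-at-diagnosis")


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check a per-sample clinical table (index = sample ids).

    ``pfs_days`` must be positive, ``event`` boolean-coercible,
    ``ctc_group`` consistent with ``ctc_count`` where both are present.
    """
    missing = [c for c in ("pfs_days", "event") if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    out = clinical.copy()
    out["pfs_days"] = out["pfs_days"].astype(float)
    if (out["pfs_days"] <= 0).any():
        raise ValueError("pfs_days must be > 0")
    out["event"] = out["event"].astype(bool)
    if "ctc_count" in out.columns and "ctc_group" in out.columns:
        have = out["ctc_count"].notna() & out["ctc_group"].notna()
        expected = np.where(out.loc[have, "ctc_count"] >= 5, ">=5", "<5")
        if (out.loc[have, "ctc_group"] != expected).any():
            raise ValueError("ctc_group inconsistent with ctc_count")
    return out


@dataclass
class PredictorModel:
    """Linear maximum-margin classifier over a selected gene panel.

    The decision score for a sample with expression vector ``x`` (ordered
    like ``genes``) is ``w . (x - center) / scale + intercept``; a positive
    score calls the sample a poor responder (unfavorable profile).
    """

    genes: list[str]
    weights: np.ndarray
    intercept: float
    center: np.ndarray
    scale: np.ndarray
    alpha: float = 0.1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        n = len(self.genes)
        for name, arr in (
            ("weights", self.weights),
            ("center", self.center),
            ("scale", self.scale),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")

    def decision(self, expr: ExpressionMatrix) -> pd.Series:
        missing = [g for g in self.genes if g not in expr.delta_ct.index]
        if missing:
            raise ValueError(f"model genes absent from expression matrix: {missing}")
        X = expr.delta_ct.loc[self.genes].to_numpy().T  # samples x genes
        Z = (X - self.center) / self.scale
        return pd.Series(Z @ self.weights + self.intercept, index=expr.samples)

    def predict(self, expr: ExpressionMatrix) -> pd.Series:
        """Responder-class call per sample (``poor`` iff score > 0)."""
        score = self.decision(expr)
        return pd.Series(
            np.where(score > 0, POOR, GOOD), index=score.index, name="class"
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "weights": self.weights.tolist(),
            "intercept": float(self.intercept),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "alpha": self.alpha,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictorModel":
        return cls(
            genes=list(d["genes"]),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            alpha=float(d.get("alpha", 0.1)),
            metadata=dict(d.get("metadata", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PredictorModel":
        return cls.from_dict(json.loads(Path(path).read_text()))
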