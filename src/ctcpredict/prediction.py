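"""LOOCV class prediction with nested univariate gene selection.

The discovery procedure: for each leave-one-out fold, genes differentially
expressed between good and poor responders are selected by a pooled-variance
two-sample t-test (p < alpha, default 0.1) on the *training* samples only,
a standardized linear soft-margin SVM is trained on the selected genes, and
the held-out sample is called.  Significance of the observed
misclassification rate is assessed by rerunning the whole nested procedure
under label permutations.  The reported signature comes from selection and
training on the full cohort.

Sign convention for the t statistic: ``(mean good - mean poor) / SE`` —
a negative t means higher expression in poor responders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .datatypes import GOOD, POOR, ExpressionMatrix, PredictorModel

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.1
DEFAULT_SVM_COST = 1.0


class NoInformativeGenesError(ValueError):
    """No gene reached the selection threshold."""


@dataclass(frozen=True)
class GeneStat:
    """Two-sample t-test result for one gene (positive t = higher in good)."""

    gene: str
    t_value: float
    p_value: float


def _as_arrays(
    expr: ExpressionMatrix, labels: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    labels = labels.reindex(expr.samples)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise ValueError(f"samples without labels: {missing[:5]}")
    bad = set(labels.unique()) - {GOOD, POOR}
    if bad:
        raise ValueError(f"labels must be good/poor, got {sorted(bad)}")
    X = expr.delta_ct.to_numpy()
    y = (labels.to_numpy() == POOR)
    return X, y


def _t_and_p(X: np.ndarray, is_poor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled-variance two-sample t over rows (genes).

    Returns (t, p); genes are flagged unevaluable (NaN) when either class
    has fewer than 2 samples or the pooled variance is zero with equal
    means handled as t=0, p=1.
    """
    Xg = X[:, ~is_poor]
    Xp = X[:, is_poor]
    n1, n2 = Xg.shape[1], Xp.shape[1]
    if n1 < 2 or n2 < 2:
        nan = np.full(X.shape[0], np.nan)
        return nan, nan
    m1, m2 = Xg.mean(axis=1), Xp.mean(axis=1)
    v1 = Xg.var(axis=1, ddof=1)
    v2 = Xp.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # constant gene, equal means -> no evidence of difference
    t[(se == 0) & (diff == 0)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=n1 + n2 - 2)
    p[np.isinf(t)] = 0.0
    return t, p


def gene_stats(expr: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per-gene pooled-variance two-sample t statistics (good minus poor)."""
    X, is_poor = _as_arrays(expr, labels)
    t, p = _t_and_p(X, is_poor)
    return pd.DataFrame({"t_value": t, "p_value": p}, index=expr.genes)


def two_sample_t(expr: ExpressionMatrix, labels: pd.Series, gene: str) -> GeneStat:
    """Pooled-variance two-sample t for one gene, two-sided p (df = n - 2)."""
    row = gene_stats(expr, labels).loc[gene]
    return GeneStat(gene=gene, t_value=float(row.t_value), p_value=float(row.p_value))


def select_genes(
    expr: ExpressionMatrix, labels: pd.Series, alpha: float = DEFAULT_ALPHA
) -> list[str]:
    """Genes with p < alpha, ordered by ascending p then panel order."""
    st = gene_stats(expr, labels)
    pos = {g: i for i, g in enumerate(expr.genes)}
    hits = st.index[(st.p_value < alpha).fillna(False)]
    return sorted(hits, key=lambda g: (st.loc[g, "p_value"], pos[g]))


def train_linear_svm(
    expr: ExpressionMatrix,
    labels: pd.Series,
    genes: Sequence[str],
    cost: float = DEFAULT_SVM_COST,
    alpha: float = DEFAULT_ALPHA,
) -> PredictorModel:
    """Standardized linear soft-margin SVM on the given genes.

    Features are centered and scaled per gene on the training data (the
    center/scale are stored in the model for later application).  The fit
    is deterministic for a fixed input.
    """
    genes = list(genes)
    if not genes:
        raise NoInformativeGenesError("no genes supplied for training")
    sub = expr.subset_genes(genes)
    X, is_poor = _as_arrays(sub, labels)
    if is_poor.all() or not is_poor.any():
        raise ValueError("training requires both classes present")
    Xs = X.T  # samples x genes
    center = Xs.mean(axis=0)
    scale = Xs.std(axis=0, ddof=1)
    scale = np.where(scale == 0, 1.0, scale)
    Z = (Xs - center) / scale
    clf = SVC(kernel="linear", C=cost)
    clf.fit(Z, np.where(is_poor, POOR, GOOD))
    # classes_ is sorted ('good' < 'poor'), so a positive decision score
    # already means poor
    return PredictorModel(
        genes=genes,
        weights=clf.coef_[0],
        intercept=float(clf.intercept_[0]),
        center=center,
        scale=scale,
        alpha=alpha,
        metadata={"cost": cost, "n_training_samples": int(Xs.shape[0])},
    )


@dataclass
class CrossValResult:
    """Held-out calls and accounting from a leave-one-out run."""

    predictions: pd.Series
    fold_genes: list[list[str]]
    error: float
    n_samples: int
    permutation_p: Optional[float] = None
    n_permutations: int = 0
    seed: Optional[int] = None
    permuted_errors: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "predictions": self.predictions.to_dict(),
            "fold_genes": self.fold_genes,
            "error": self.error,
            "n_samples": self.n_samples,
            "permutation_p": self.permutation_p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _loocv_arrays(
    X: np.ndarray, is_poor: np.ndarray, alpha: float, cost: float
) -> tuple[np.ndarray, list[np.ndarray]]:
    """LOOCV on raw arrays; returns held-out poor-calls and per-fold gene
    index lists.  The held-out column is removed before selection and
    training (nested selection)."""
    n = X.shape[1]
    calls = np.zeros(n, dtype=bool)
    fold_genes: list[np.ndarray] = []
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        Xt, yt = X[:, mask], is_poor[mask]
        t, p = _t_and_p(Xt, yt)
        with np.errstate(invalid="ignore"):
            hit = p < alpha
        hit = np.where(np.isnan(p), False, hit)
        sel = np.flatnonzero(hit)
        sel = sel[np.lexsort((sel, p[sel]))]
        fold_genes.append(sel)
        if sel.size == 0:
            # no informative gene in this fold: call the majority class
            calls[i] = yt.sum() > (~yt).sum()
            continue
        Zt = Xt[sel].T
        center = Zt.mean(axis=0)
        scale = Zt.std(axis=0, ddof=1)
        scale = np.where(scale == 0, 1.0, scale)
        clf = SVC(kernel="linear", C=cost)
        clf.fit((Zt - center) / scale, yt)
        z = (X[sel, i] - center) / scale
        calls[i] = bool(clf.decision_function(z[None, :])[0] > 0)
    return calls, fold_genes


def loocv(
    expr: ExpressionMatrix,
    labels: pd.Series,
    alpha: float = DEFAULT_ALPHA,
    cost: float = DEFAULT_SVM_COST,
) -> CrossValResult:
    """Leave-one-out cross-validation with selection nested in each fold."""
    X, is_poor = _as_arrays(expr, labels)
    n = X.shape[1]
    n_poor = int(is_poor.sum())
    if n < 10 or min(n_poor, n - n_poor) < 3:
        raise ValueError(
            f"loocv requires n >= 10 with >= 3 samples per class "
            f"(got n={n}, poor={n_poor}, good={n - n_poor})"
        )
    calls, fold_idx = _loocv_arrays(X, is_poor, alpha, cost)
    genes = expr.genes
    predictions = pd.Series(
        np.where(calls, POOR, GOOD), index=expr.samples, name="class"
    )
    error = float(np.mean(calls != is_poor))
    return CrossValResult(
        predictions=predictions,
        fold_genes=[[genes[j] for j in sel] for sel in fold_idx],
        error=error,
        n_samples=n,
    )


def permutation_test(
    expr: ExpressionMatrix,
    labels: pd.Series,
    n_permutations: int = 100,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    cost: float = DEFAULT_SVM_COST,
    observed: Optional[CrossValResult] = None,
) -> CrossValResult:
    """Permutation significance of the LOOCV misclassification rate.

    Labels are permuted uniformly; the *entire* nested LOOCV (selection
    included) is rerun per permutation.  The add-one estimator
    ``p = (1 + #{permuted error <= observed}) / (B + 1)`` never returns 0;
    its floor at B=100 is 1/101 ~ 0.0099.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X, is_poor = _as_arrays(expr, labels)
    result = observed if observed is not None else loocv(expr, labels, alpha, cost)
    rng = np.random.default_rng(seed)
    perm_errors = []
    for _ in range(n_permutations):
        y = is_poor[rng.permutation(len(is_poor))]
        calls, _ = _loocv_arrays(X, y, alpha, cost)
        perm_errors.append(float(np.mean(calls != y)))
    hits = sum(e <= result.error for e in perm_errors)
    result.permutation_p = (1 + hits) / (n_permutations + 1)
    result.n_permutations = n_permutations
    result.seed = seed
    result.permuted_errors = perm_errors
    return result


def finalize_predictor(
    expr: ExpressionMatrix,
    labels: pd.Series,
    alpha: float = DEFAULT_ALPHA,
    cost: float = DEFAULT_SVM_COST,
) -> PredictorModel:
    """Select genes and train on the full cohort (the reported signature)."""
    genes = select_genes(expr, labels, alpha=alpha)
    if not genes:
        raise NoInformativeGenesError(
            f"no gene reached p < {alpha} on the full cohort"
        )
    return train_linear_svm(expr, labels, genes, cost=cost, alpha=alpha)


def apply_predictor(model: PredictorModel, expr: ExpressionMatrix) -> pd.Series:
    """Apply a trained model; returns good/poor calls per sample.

    A ``poor`` call corresponds to an unfavorable profile.  Raises when
    model genes are absent from the matrix.
    """
    return model.predict(expr)
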