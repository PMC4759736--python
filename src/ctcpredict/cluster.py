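"""Two-dimensional average-linkage hierarchical clustering (Cluster 3.0
style) of samples and signature genes.

Distance is 1 minus the centered Pearson correlation; an item with zero
variance has no defined correlation and is assigned the maximal
dissimilarity 1 to every other item.  Linkage is average (UPGMA) with
deterministic tie-breaking by input order; no optimal leaf reordering is
applied.  Expression is median-centered per gene before display so the
sign of a cell encodes above/below the across-sample median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)


def median_center(expr: ExpressionMatrix) -> pd.DataFrame:
    """Subtract each gene's across-sample median; constant genes go to 0."""
    m = expr.delta_ct
    return m.sub(m.median(axis=1), axis=0)


def correlation_distance(matrix: pd.DataFrame) -> np.ndarray:
    """1 - centered Pearson correlation between rows.

    Zero-variance rows get distance 1 to everything (logged); identical
    rows get 0, perfectly anti-correlated rows get 2.
    """
    X = matrix.to_numpy(dtype=float)
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    flat = norms == 0
    if flat.any():
        logger.warning(
            "correlation distance: %d zero-variance items set to maximal "
            "dissimilarity", int(flat.sum()),
        )
    safe = np.where(flat, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[flat, :] = 1.0
    dist[:, flat] = 1.0
    np.fill_diagonal(dist, 0.0)
    # numerical guard: clip to the valid [0, 2] range and symmetrize
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    return dist


def hcluster(matrix: pd.DataFrame, axis: str = "rows") -> np.ndarray:
    """Average-linkage tree over rows (or columns) of ``matrix``.

    Returns a scipy linkage matrix.  Merge heights are the mean pairwise
    distance between clusters (UPGMA) and are non-decreasing.
    """
    if axis == "columns":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    if matrix.shape[0] < 2:
        raise ValueError("clustering requires at least 2 items")
    dist = correlation_distance(matrix)
    return linkage(squareform(dist, checks=False), method="average")


@dataclass
class ClusterResult:
    """Sample and gene dendrograms plus the display-ready matrix."""

    sample_linkage: np.ndarray
    gene_linkage: Optional[np.ndarray]
    sample_order: list[str]
    gene_order: list[str]
    matrix: pd.DataFrame  # median-centered, reordered to leaf order
    input_samples: list[str] = None
    input_genes: list[str] = None

    def __post_init__(self) -> None:
        if self.input_samples is None:
            self.input_samples = list(self.sample_order)
        if self.input_genes is None:
            self.input_genes = list(self.gene_order)


def cluster_expression(
    expr: ExpressionMatrix, cluster_genes: bool = True
) -> ClusterResult:
    """Median-center and cluster samples (columns) and genes (rows)."""
    centered = median_center(expr)
    sample_link = hcluster(centered, axis="columns")
    sample_order = [expr.samples[i] for i in leaves_list(sample_link)]
    if cluster_genes and centered.shape[0] >= 2:
        gene_link = hcluster(centered, axis="rows")
        gene_order = [expr.genes[i] for i in leaves_list(gene_link)]
    else:
        gene_link, gene_order = None, list(expr.genes)
    return ClusterResult(
        sample_linkage=sample_link,
        gene_linkage=gene_link,
        sample_order=sample_order,
        gene_order=gene_order,
        matrix=centered.loc[gene_order, sample_order],
        input_samples=list(expr.samples),
        input_genes=list(expr.genes),
    )


def _write_tree(
    link: np.ndarray, ids: list[str], prefix: str, path: Path
) -> None:
    """Write a GTR/ATR-style node list: node id, children, 1 - height."""
    n = len(ids)
    lines = []
    names = {i: f"{prefix}{i}X" for i in range(n)}
    for k, (a, b, height, _) in enumerate(link):
        a, b = int(a), int(b)
        node = f"NODE{k + 1}X"
        lines.append(
            f"{node}\t{names.get(a, f'NODE{a - n + 1}X')}"
            f"\t{names.get(b, f'NODE{b - n + 1}X')}\t{1.0 - height:.6f}"
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def export_clustered(
    result: ClusterResult,
    out_dir: str | Path,
    basename: str = "clustered",
    annotations: Optional[pd.DataFrame] = None,
) -> dict[str, Path]:
    """Write CDT/GTR/ATR files readable by standard tree viewers plus a
    plain ordered TSV with per-sample annotation rows.

    ``annotations`` is a samples x columns frame (e.g. responder class and
    CTC count); it is reordered to the sample leaf order and emitted as
    leading rows of the ordered TSV.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    genes, samples = result.gene_order, result.sample_order
    paths: dict[str, Path] = {}

    # ids reference input order (linkage indices), Cluster 3.0 style
    gene_pos = {g: i for i, g in enumerate(result.input_genes)}
    sample_pos = {s: i for i, s in enumerate(result.input_samples)}

    cdt = out / f"{basename}.cdt"
    with cdt.open("w") as fh:
        fh.write("GID\tNAME\tGWEIGHT\t" + "\t".join(samples) + "\n")
        fh.write(
            "AID\t\t\t"
            + "\t".join(f"ARRY{sample_pos[s]}X" for s in samples)
            + "\n"
        )
        fh.write("EWEIGHT\t\t\t" + "\t".join(["1"] * len(samples)) + "\n")
        for g in genes:
            row = result.matrix.loc[g, samples]
            fh.write(
                f"GENE{gene_pos[g]}X\t{g}\t1\t"
                + "\t".join(f"{v:.6f}" for v in row)
                + "\n"
            )
    paths["cdt"] = cdt

    if result.gene_linkage is not None:
        gtr = out / f"{basename}.gtr"
        _write_tree(result.gene_linkage, result.input_genes, "GENE", gtr)
        paths["gtr"] = gtr
    atr = out / f"{basename}.atr"
    _write_tree(result.sample_linkage, result.input_samples, "ARRY", atr)
    paths["atr"] = atr

    # plain ordered TSV with annotation rows on top
    tsv = out / f"{basename}.ordered.tsv"
    blocks = []
    if annotations is not None and len(annotations.columns) > 0:
        ann = annotations.reindex(samples).T
        ann.index.name = "gene"
        blocks.append(ann)
    blocks.append(result.matrix.loc[genes, samples])
    pd.concat(blocks).to_csv(tsv, sep="\t", index_label="gene")
    paths["ordered_tsv"] = tsv
    return paths
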