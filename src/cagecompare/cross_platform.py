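"""Global cross-platform structure: rank correlation, clustering, ratio statistics.

All-against-all Spearman correlation between the samples of two expression
matrices is computed on a shared gene universe (by default, genes expressed in
at least one sample of *both* datasets).  Within-dataset sample relationships
are summarised by average-linkage (UPGMA) hierarchical clustering on
``1 - correlation`` distances.  Tissue-specificity is summarised per gene by
max/mean and max/median ratios across tissue-aggregated values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression_classes import aggregate_by_tissue
from .io_formats import ExpressionMatrix, SampleSheet

__all__ = [
    "CorrelationMatrix",
    "Dendrogram",
    "RatioStats",
    "expressed_universe",
    "spearman_all_vs_all",
    "cluster_samples",
    "ratio_stats",
    "exclude_enriched_and_recorrelate",
]


def expressed_universe(
    mat_a: ExpressionMatrix, mat_b: ExpressionMatrix, threshold: float = 1.0
) -> set[str]:
    """Genes above threshold in >= 1 sample in BOTH datasets (the correlation universe)."""
    shared = mat_a.values.index.intersection(mat_b.values.index)
    in_a = (mat_a.values.loc[shared] > threshold).any(axis=1)
    in_b = (mat_b.values.loc[shared] > threshold).any(axis=1)
    return set(shared[in_a & in_b])


@dataclass
class CorrelationMatrix:
    """samples_A x samples_B Spearman coefficients on a recorded gene universe.

    Sample pairs where either expression vector is constant have an undefined
    coefficient; they are stored as NaN and listed in ``constant_samples``.
    """

    values: pd.DataFrame
    gene_universe: frozenset[str]
    constant_samples: frozenset[str] = frozenset()
    label_a: str = "A"
    label_b: str = "B"


def spearman_all_vs_all(
    mat_a: ExpressionMatrix,
    mat_b: ExpressionMatrix,
    gene_universe: Iterable[str] | None = None,
    threshold: float = 1.0,
) -> CorrelationMatrix:
    """Spearman correlation of every sample of A against every sample of B.

    Ranks use average tie handling (standard Spearman).  When
    ``gene_universe`` is omitted it is built as the genes expressed (>
    threshold) in at least one sample of both datasets.
    """
    if gene_universe is None:
        gene_universe = expressed_universe(mat_a, mat_b, threshold)
    genes = sorted(gene_universe)
    if len(genes) < 3:
        raise ValueError("gene universe must contain at least 3 genes")
    missing_a = set(genes) - set(mat_a.values.index)
    missing_b = set(genes) - set(mat_b.values.index)
    if missing_a or missing_b:
        raise ValueError("gene_universe contains genes absent from a matrix")

    a = mat_a.values.loc[genes]
    b = mat_b.values.loc[genes]
    const = [s for s in a.columns if a[s].nunique() == 1] + [
        s for s in b.columns if b[s].nunique() == 1
    ]
    rho = stats.spearmanr(a.to_numpy(), b.to_numpy(), axis=0).statistic
    n_a = a.shape[1]
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    block = rho[:n_a, n_a:]
    values = pd.DataFrame(block, index=a.columns, columns=b.columns)
    for s in const:
        if s in values.index:
            values.loc[s, :] = np.nan
        if s in values.columns:
            values.loc[:, s] = np.nan
    return CorrelationMatrix(
        values=values,
        gene_universe=frozenset(genes),
        constant_samples=frozenset(const),
        label_a=mat_a.dataset_label or "A",
        label_b=mat_b.dataset_label or "B",
    )


@dataclass
class Dendrogram:
    """Average-linkage tree over samples, from 1 - correlation distances."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    distances: pd.DataFrame = field(repr=False, default=None)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Serialise the tree as Newick with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.10g}"

        inner = f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)})"
        return inner + ";"


def cluster_samples(corr: pd.DataFrame, tol: float = 1e-9) -> Dendrogram:
    """UPGMA clustering of samples using 1 - correlation as the distance.

    The input must be a square symmetric correlation matrix (within-dataset,
    e.g. the Spearman matrix of a dataset's samples against themselves).
    """
    if corr.shape[0] != corr.shape[1] or not corr.index.equals(corr.columns):
        raise ValueError("correlation matrix must be square with matching labels")
    m = corr.to_numpy(dtype=float)
    if np.nanmax(np.abs(m - m.T)) > tol:
        raise ValueError(f"correlation matrix not symmetric within {tol}")
    d = 1.0 - (m + m.T) / 2.0
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=z, labels=list(corr.index), distances=pd.DataFrame(d, index=corr.index, columns=corr.columns))


@dataclass
class RatioStats:
    """Per-gene tissue-specificity ratios for two datasets, with summaries.

    ``per_gene`` columns: max_mean_a/b, max_median_a/b, diff_max_mean
    (A - B), folddiff_max_median (larger / smaller).  Summary fractions count
    genes whose max/mean difference is within +/- ``mean_bound`` and whose
    max/median ratios differ by at most ``median_fold_bound``-fold.  Genes with
    a zero mean or median in either dataset are excluded from the respective
    summary, with counts recorded.
    """

    per_gene: pd.DataFrame
    frac_max_mean_within: float
    frac_max_median_within: float
    mean_bound: float = 6.0
    median_fold_bound: float = 10.0
    n_excluded_zero_mean: int = 0
    n_excluded_zero_median: int = 0


def ratio_stats(
    mat_a: ExpressionMatrix,
    mat_b: ExpressionMatrix,
    sheet_a: SampleSheet,
    sheet_b: SampleSheet,
    aggregation: str = "mean",
    genes: Iterable[str] | None = None,
    mean_bound: float = 6.0,
    median_fold_bound: float = 10.0,
) -> RatioStats:
    """Max/mean and max/median tissue-specificity ratios and their cross-dataset drift."""
    agg_a = aggregate_by_tissue(mat_a, sheet_a, aggregation)
    agg_b = aggregate_by_tissue(mat_b, sheet_b, aggregation)
    if genes is None:
        genes = agg_a.index.intersection(agg_b.index)
    genes = sorted(set(genes))
    a = agg_a.loc[genes].to_numpy(float)
    b = agg_b.loc[genes].to_numpy(float)

    def ratios(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mx = m.max(axis=1)
        mean = m.mean(axis=1)
        med = np.median(m, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(mean > 0, mx / mean, np.nan), np.where(med > 0, mx / med, np.nan)

    mm_a, md_a = ratios(a)
    mm_b, md_b = ratios(b)
    diff_mean = mm_a - mm_b
    with np.errstate(divide="ignore", invalid="ignore"):
        folddiff = np.maximum(md_a, md_b) / np.minimum(md_a, md_b)

    ok_mean = ~np.isnan(diff_mean)
    ok_med = ~np.isnan(folddiff)
    frac_mean = float((np.abs(diff_mean[ok_mean]) <= mean_bound).mean()) if ok_mean.any() else float("nan")
    frac_med = float((folddiff[ok_med] <= median_fold_bound).mean()) if ok_med.any() else float("nan")

    per_gene = pd.DataFrame(
        {
            "max_mean_a": mm_a,
            "max_mean_b": mm_b,
            "max_median_a": md_a,
            "max_median_b": md_b,
            "diff_max_mean": diff_mean,
            "folddiff_max_median": folddiff,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return RatioStats(
        per_gene=per_gene,
        frac_max_mean_within=frac_mean,
        frac_max_median_within=frac_med,
        mean_bound=mean_bound,
        median_fold_bound=median_fold_bound,
        n_excluded_zero_mean=int((~ok_mean).sum()),
        n_excluded_zero_median=int((~ok_med).sum()),
    )


def exclude_enriched_and_recorrelate(
    mat_a: ExpressionMatrix,
    mat_b: ExpressionMatrix,
    enriched_sets: Sequence[Iterable[str]],
    gene_universe: Iterable[str] | None = None,
    threshold: float = 1.0,
) -> CorrelationMatrix:
    """Recompute the all-vs-all correlation after dropping named enriched genes.

    ``enriched_sets`` are typically the testis- and brain-enriched gene sets
    from both datasets; their union is removed from the correlation universe.
    """
    if gene_universe is None:
        gene_universe = expressed_universe(mat_a, mat_b, threshold)
    excluded: set[str] = set()
    for s in enriched_sets:
        excluded |= set(s)
    universe = set(gene_universe) - excluded
    if len(universe) < 3:
        raise ValueError("fewer than 3 genes remain after exclusion")
    return spearman_all_vs_all(mat_a, mat_b, gene_universe=universe)
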