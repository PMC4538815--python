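"""Expressed/ubiquitous/single-tissue-enriched gene classification and agreement.

The operational definitions:

* A gene is *expressed* in a sample when its abundance is strictly greater
  than a threshold (1 TPM for CAGE, 1 FPKM for RNA-Seq).
* A gene is *ubiquitously expressed* in a dataset when it is expressed in
  every sample of that dataset.
* Two datasets *agree* on a ubiquitous gene when it is ubiquitous (100% of
  samples) in one dataset and expressed in at least a tolerance fraction
  (default 95%) of the samples of the other.  With 79 and 27 samples this
  instantiates to >=75/79 and >=25/27, i.e. ``k_min = floor(tolerance * n)``.
* A gene is *single-tissue enriched* at cutoff x when its aggregated
  expression in its top tissue is at least x-fold the second-highest tissue
  (with a small floor preventing division by zero) and the top tissue is
  itself expressed.
* Relaxed cross-dataset agreement at (x, y), y < x: same top tissue in both
  datasets, >=x-fold in one and >=y-fold in the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, SampleSheet

__all__ = [
    "ExpressionCallMatrix",
    "EnrichmentCriteria",
    "EnrichmentResult",
    "CategoryAgreement",
    "TissueDistribution",
    "call_expressed",
    "ubiquitous_set",
    "min_count_for_tolerance",
    "ubiquity_agreement",
    "aggregate_by_tissue",
    "enrichment_call",
    "enrichment_agreement",
    "tissue_distribution",
    "expressed_agreement_per_tissue",
]


@dataclass
class ExpressionCallMatrix:
    """Boolean genes x samples expressed-calls with the threshold that made them."""

    calls: pd.DataFrame  # bool
    threshold: float
    unit: str
    dataset_label: str = ""

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)


def call_expressed(matrix: ExpressionMatrix, threshold: float = 1.0) -> ExpressionCallMatrix:
    """Strictly-greater-than threshold call: value must exceed, not equal, the cutoff."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return ExpressionCallMatrix(
        calls=matrix.values > threshold,
        threshold=threshold,
        unit=matrix.unit,
        dataset_label=matrix.dataset_label,
    )


def ubiquitous_set(calls: ExpressionCallMatrix) -> set[str]:
    """Genes expressed in every sample of the dataset."""
    if calls.calls.shape[1] < 1:
        raise ValueError("need at least one sample")
    mask = calls.calls.all(axis=1)
    return set(calls.calls.index[mask])


def min_count_for_tolerance(tolerance: float, n_samples: int) -> int:
    """Smallest expressed-sample count accepted by the tolerance rule.

    ``floor(tolerance * n)`` — reproduces the printed instantiations
    0.95 of 79 -> 75 and 0.95 of 27 -> 25.  A tiny epsilon guards against
    floating-point representation of products like 0.95 * 20.
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    return int(math.floor(tolerance * n_samples + 1e-9))


@dataclass
class CategoryAgreement:
    """Cross-dataset contingency of a gene category: common / A-only / B-only.

    ``discordant`` holds genes qualifying in both datasets but with conflicting
    evidence (e.g. different top tissues); it is empty for ubiquity.
    All percentages are derived from the stored sets, never free-floating.
    """

    common: frozenset[str]
    a_only: frozenset[str]
    b_only: frozenset[str]
    discordant: frozenset[str] = frozenset()
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        sets = [self.common, self.a_only, self.b_only, self.discordant]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("agreement categories must be disjoint")

    @property
    def universe(self) -> frozenset[str]:
        return self.common | self.a_only | self.b_only | self.discordant

    @property
    def counts(self) -> dict[str, int]:
        return {
            "common": len(self.common),
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
            "discordant": len(self.discordant),
            "total": len(self.universe),
        }

    @property
    def percent_common(self) -> float:
        n = len(self.universe)
        return 100.0 * len(self.common) / n if n else float("nan")


def ubiquity_agreement(
    calls_a: ExpressionCallMatrix,
    calls_b: ExpressionCallMatrix,
    tolerance: float = 0.95,
) -> CategoryAgreement:
    """Partition ubiquitous genes into common / A-only / B-only.

    Common: expressed in 100% of one dataset's samples and in at least the
    tolerance fraction of the other's.  A-only / B-only: ubiquitous in exactly
    one dataset and below tolerance in the other.
    """
    genes_a, genes_b = set(calls_a.calls.index), set(calls_b.calls.index)
    if genes_a != genes_b:
        raise ValueError(
            f"gene universes differ: symmetric difference of size {len(genes_a ^ genes_b)}"
        )
    n_a, n_b = calls_a.calls.shape[1], calls_b.calls.shape[1]
    k_a = min_count_for_tolerance(tolerance, n_a)
    k_b = min_count_for_tolerance(tolerance, n_b)
    count_a = calls_a.calls.sum(axis=1)
    count_b = calls_b.calls.sum(axis=1).reindex(calls_a.calls.index)
    ub_a = count_a == n_a
    ub_b = count_b == n_b
    common = (ub_a & (count_b >= k_b)) | (ub_b & (count_a >= k_a))
    idx = calls_a.calls.index
    return CategoryAgreement(
        common=frozenset(idx[common]),
        a_only=frozenset(idx[ub_a & ~common]),
        b_only=frozenset(idx[ub_b & ~common]),
        label_a=calls_a.dataset_label or "A",
        label_b=calls_b.dataset_label or "B",
    )


def aggregate_by_tissue(
    matrix: ExpressionMatrix, samples: SampleSheet, how: str = "mean"
) -> pd.DataFrame:
    """Collapse replicate samples to one column per tissue (mean or max)."""
    if how not in ("mean", "max"):
        raise ValueError(f"aggregation must be 'mean' or 'max', got {how!r}")
    tmap = samples.tissue_map()
    cols = {}
    for tissue in sorted(tmap):
        sids = [s for s in tmap[tissue] if s in matrix.values.columns]
        if not sids:
            raise ValueError(f"tissue {tissue!r} has no samples in the matrix")
        block = matrix.values[sids]
        cols[tissue] = block.mean(axis=1) if how == "mean" else block.max(axis=1)
    return pd.DataFrame(cols)


@dataclass
class EnrichmentCriteria:
    """Parameters of the single-tissue enrichment call.

    ``floor`` replaces the second-highest tissue value when it falls below it,
    so clean single-tissue genes get a large finite fold instead of a division
    by zero.  ``expression_threshold`` requires the top tissue itself to be
    expressed.
    """

    aggregation: str = "mean"  # mean | max over a tissue's replicates
    floor: float = 0.1
    expression_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.floor <= 0:
            raise ValueError("floor must be > 0")
        if self.aggregation not in ("mean", "max"):
            raise ValueError("aggregation must be 'mean' or 'max'")


@dataclass
class EnrichmentResult:
    """Per-gene top tissue and fold over the second-highest tissue.

    ``table`` columns: top_tissue, second_tissue, top_value, second_value,
    fold, tie.  Genes whose top value is exactly tied across tissues get no
    call (``tie`` flag, top_tissue NA) — a gene cannot be *higher* than all
    other tissues if another tissue equals it.
    """

    table: pd.DataFrame
    criteria: EnrichmentCriteria
    dataset_label: str = ""

    def qualifying(self, x: float) -> set[str]:
        """Genes enriched at >= x-fold with an expressed, untied top tissue."""
        t = self.table
        mask = (~t["tie"]) & (t["fold"] >= x) & (t["top_value"] > self.criteria.expression_threshold)
        return set(t.index[mask])

    def top_tissue_of(self, gene: str) -> str | None:
        v = self.table.loc[gene, "top_tissue"]
        return None if pd.isna(v) else str(v)


def enrichment_call(
    matrix: ExpressionMatrix,
    samples: SampleSheet,
    criteria: EnrichmentCriteria = EnrichmentCriteria(),
) -> EnrichmentResult:
    """Compute each gene's top tissue and its fold over the runner-up tissue.

    fold = aggregated(top) / max(aggregated(second), floor).
    """
    agg = aggregate_by_tissue(matrix, samples, criteria.aggregation)
    if agg.shape[1] < 2:
        raise ValueError("enrichment needs at least two tissues")
    tissues = np.array(agg.columns)
    vals = agg.to_numpy(dtype=float)
    order = np.argsort(vals, axis=1)
    rows = np.arange(vals.shape[0])
    top_i, second_i = order[:, -1], order[:, -2]
    top = vals[rows, top_i]
    second = vals[rows, second_i]
    tie = (vals == top[:, None]).sum(axis=1) > 1
    fold = top / np.maximum(second, criteria.floor)
    table = pd.DataFrame(
        {
            "top_tissue": np.where(tie, None, tissues[top_i]),
            "second_tissue": tissues[second_i],
            "top_value": top,
            "second_value": second,
            "fold": np.where(tie, np.nan, fold),
            "tie": tie,
        },
        index=agg.index,
    )
    return EnrichmentResult(table=table, criteria=criteria, dataset_label=matrix.dataset_label)


def enrichment_agreement(
    res_a: EnrichmentResult, res_b: EnrichmentResult, x: float, y: float | None = None
) -> CategoryAgreement:
    """Cross-dataset agreement of single-tissue enrichment at cutoffs (x, y).

    Common: same top tissue and (>=x-fold in one dataset while >=y-fold in the
    other).  ``y = x`` gives the strict variant (default).  Genes reaching x in
    both datasets but with different top tissues are ``discordant``.
    """
    if y is None:
        y = x
    if y > x:
        raise ValueError("relaxed cutoff y must satisfy y <= x")
    qa_x, qb_x = res_a.qualifying(x), res_b.qualifying(x)
    qa_y, qb_y = res_a.qualifying(y), res_b.qualifying(y)
    top_a, top_b = res_a.table["top_tissue"], res_b.table["top_tissue"]

    candidates = (qa_x & qb_y) | (qb_x & qa_y)
    common = {g for g in candidates if top_a.get(g) is not None and top_a.get(g) == top_b.get(g)}
    discordant = (qa_x & qb_x) - common
    return CategoryAgreement(
        common=frozenset(common),
        a_only=frozenset(qa_x - common - discordant),
        b_only=frozenset(qb_x - common - discordant),
        discordant=frozenset(discordant),
        label_a=res_a.dataset_label or "A",
        label_b=res_b.dataset_label or "B",
    )


def _ttest_two_sample(xs: Sequence[float], ys: Sequence[float], eps: float = 1e-12) -> tuple[float, float]:
    """Pooled two-sample Student's t with an epsilon-stabilised variance.

    Identical groups with zero variance give t = 0, p = 1; separated groups
    with zero within-group variance give a huge |t| and p ~ 0 instead of NaN.
    """
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    n1, n2 = len(xs), len(ys)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * xs.var(ddof=1) + (n2 - 1) * ys.var(ddof=1)) / df + eps
    t = (xs.mean() - ys.mean()) / math.sqrt(pooled * (1 / n1 + 1 / n2))
    return float(t), float(2 * stats.t.sf(abs(t), df))


def _ttest_one_sample(xs: Sequence[float], mu: float, eps: float = 1e-12) -> tuple[float, float]:
    xs = np.asarray(xs, float)
    n = len(xs)
    if n < 2:
        raise ValueError("need at least 2 values")
    var = xs.var(ddof=1) + eps
    t = (xs.mean() - mu) / math.sqrt(var / n)
    return float(t), float(2 * stats.t.sf(abs(t), n - 1))


@dataclass
class TissueDistribution:
    """Per-tissue proportions of enriched genes across cutoff settings.

    ``proportions``: tissues x cutoff-settings.  ``tests``: per tissue, the
    two-sample t-test of strict-group vs relaxed-group proportions and the
    one-sample t-test against the uniform expectation 1/n_tissues, each
    labelled with the test used.  Tests are omitted (NaN + flag) when a group
    has fewer than two settings.
    """

    proportions: pd.DataFrame
    tests: pd.DataFrame
    strict_settings: list[str] = field(default_factory=list)
    relaxed_settings: list[str] = field(default_factory=list)


def tissue_distribution(
    top_tissues_by_setting: Mapping[str, Iterable[str]],
    tissues: Sequence[str],
    strict_settings: Sequence[str] = (),
    relaxed_settings: Sequence[str] = (),
) -> TissueDistribution:
    """Distribution of enriched genes among tissues, with significance tests.

    ``top_tissues_by_setting`` maps a cutoff label (e.g. "7x", "7x-3x") to the
    top tissues of the genes enriched under that setting.
    """
    tissues = list(tissues)
    props = {}
    for label, tops in top_tissues_by_setting.items():
        tops = [t for t in tops if t is not None]
        n = len(tops)
        counts = pd.Series(0.0, index=tissues)
        for t in tops:
            if t in counts.index:
                counts[t] += 1
        props[label] = counts / n if n else counts
    proportions = pd.DataFrame(props)

    rows = []
    uniform = 1.0 / len(tissues)
    for tissue in tissues:
        row: dict[str, object] = {"tissue": tissue}
        strict = proportions.loc[tissue, list(strict_settings)].to_numpy(float) if strict_settings else np.array([])
        relaxed = proportions.loc[tissue, list(relaxed_settings)].to_numpy(float) if relaxed_settings else np.array([])
        if len(strict) >= 2 and len(relaxed) >= 2:
            t, p = _ttest_two_sample(strict, relaxed)
            row.update(t_strict_vs_relaxed=t, p_strict_vs_relaxed=p, test_groups="two-sample pooled Student t")
        else:
            row.update(t_strict_vs_relaxed=np.nan, p_strict_vs_relaxed=np.nan, test_groups="omitted: <2 values in a group")
        allvals = proportions.loc[tissue].to_numpy(float)
        if len(allvals) >= 2:
            t, p = _ttest_one_sample(allvals, uniform)
            row.update(t_vs_uniform=t, p_vs_uniform=p, test_uniform="one-sample Student t vs 1/n_tissues")
        else:
            row.update(t_vs_uniform=np.nan, p_vs_uniform=np.nan, test_uniform="omitted: <2 settings")
        rows.append(row)
    tests = pd.DataFrame(rows).set_index("tissue")
    return TissueDistribution(
        proportions=proportions,
        tests=tests,
        strict_settings=list(strict_settings),
        relaxed_settings=list(relaxed_settings),
    )


def expressed_agreement_per_tissue(
    calls_a: ExpressionCallMatrix,
    calls_b: ExpressionCallMatrix,
    sheet_a: SampleSheet,
    sheet_b: SampleSheet,
) -> pd.DataFrame:
    """Per paired tissue, agreement of which genes are called expressed.

    A gene counts as expressed in a tissue when expressed in *any* of its
    replicate samples.  Two agreement statistics are emitted per tissue —
    Jaccard |both| / |either| over expressed genes, and simple concordance
    (|both| + |neither|) / |universe| — since the published "percentage of
    agreement" formula is ambiguous.  Tissues present in only one sheet are
    skipped with a warning.
    """
    import warnings as _warnings

    tmap_a, tmap_b = sheet_a.tissue_map(), sheet_b.tissue_map()
    shared = sorted(set(tmap_a) & set(tmap_b))
    for t in sorted(set(tmap_a) ^ set(tmap_b)):
        _warnings.warn(f"tissue {t!r} present in only one dataset; skipped")
    genes = calls_a.calls.index
    if not genes.equals(calls_b.calls.index):
        raise ValueError("call matrices must share the same gene universe and order")

    rows = []
    for tissue in shared:
        ea = calls_a.calls[[s for s in tmap_a[tissue] if s in calls_a.calls.columns]].any(axis=1)
        eb = calls_b.calls[[s for s in tmap_b[tissue] if s in calls_b.calls.columns]].any(axis=1)
        both = int((ea & eb).sum())
        either = int((ea | eb).sum())
        neither = len(genes) - either
        jaccard = both / either if either else 1.0
        concordance = (both + neither) / len(genes)
        rows.append(
            {
                "tissue": tissue,
                "expressed_both": both,
                "expressed_a_only": int((ea & ~eb).sum()),
                "expressed_b_only": int((eb & ~ea).sum()),
                "expressed_neither": neither,
                "jaccard": jaccard,
                "concordance": concordance,
            }
        )
    cols = ["tissue", "expressed_both", "expressed_a_only", "expressed_b_only",
            "expressed_neither", "jaccard", "concordance"]
    return pd.DataFrame(rows, columns=cols).set_index("tissue")
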