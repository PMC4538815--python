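"""Independent brute-force reference implementations used to check the package.

Everything here is written in the most direct way possible (all-pairs scans,
explicit set algebra, O(n^3) clustering) and stays independent of the code
paths it validates.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import rankdata


def brute_assign(peaks, genes, window_bp, strand_policy="same_strand"):
    """All-pairs peak-to-gene assignment: test every (peak, TSS) distance."""
    out = {}
    p = peaks.peaks
    for peak_id, row in p.iterrows():
        hit = set()
        for g in genes:
            if g.chrom != row["chrom"]:
                continue
            if strand_policy == "same_strand" and g.strand != row["strand"]:
                continue
            if min(abs(int(row["rep_pos"]) - t) for t in g.tss_positions) <= window_bp:
                hit.add(g.gene_id)
        out[peak_id] = frozenset(hit)
    return out


def brute_closest(peaks, genes, strand_policy="same_strand"):
    """All-pairs nearest distances, both directions."""
    p = peaks.peaks
    gene_dist, peak_dist = {}, {}
    for g in genes:
        best = math.inf
        for _, row in p.iterrows():
            if g.chrom != row["chrom"]:
                continue
            if strand_policy == "same_strand" and g.strand != row["strand"]:
                continue
            for t in g.tss_positions:
                best = min(best, abs(int(row["rep_pos"]) - t))
        gene_dist[g.gene_id] = best
    for peak_id, row in p.iterrows():
        best = math.inf
        for g in genes:
            if g.chrom != row["chrom"]:
                continue
            if strand_policy == "same_strand" and g.strand != row["strand"]:
                continue
            for t in g.tss_positions:
                best = min(best, abs(int(row["rep_pos"]) - t))
        peak_dist[peak_id] = best
    return gene_dist, peak_dist


def brute_gene_sum(peaks, assignment_map):
    """Re-sum peak expression per gene directly from the assignment map."""
    out = {}
    for peak_id, gene_set in assignment_map.items():
        row = peaks.expression.loc[peak_id]
        for g in gene_set:
            if g not in out:
                out[g] = row * 0.0
            out[g] = out[g] + row
    return out


def brute_enrichment(agg, floor, threshold):
    """Per-gene scan for top tissue, second-max and fold (None on exact tie)."""
    out = {}
    for gene, row in agg.iterrows():
        vals = sorted(((v, t) for t, v in row.items()), reverse=True)
        (top_v, top_t), (sec_v, _sec_t) = vals[0], vals[1]
        if top_v == sec_v:
            out[gene] = (None, math.nan, False)
            continue
        fold = top_v / max(sec_v, floor)
        out[gene] = (top_t, fold, top_v > threshold)
    return out


def brute_ubiquity_category(count_a, n_a, count_b, n_b, tolerance):
    """Direct evaluation of the 100%/tolerance agreement rule for one gene."""
    k_a = math.floor(tolerance * n_a + 1e-9)
    k_b = math.floor(tolerance * n_b + 1e-9)
    ub_a, ub_b = count_a == n_a, count_b == n_b
    if (ub_a and count_b >= k_b) or (ub_b and count_a >= k_a):
        return "common"
    if ub_a:
        return "a_only"
    if ub_b:
        return "b_only"
    return None


def brute_enrichment_category(top_a, fold_a, top_b, fold_b, x, y):
    """Direct evaluation of the relaxed (x, y) agreement rule for one gene.

    fold values of None mean the gene has no call in that dataset.
    """
    qa_x = fold_a is not None and fold_a >= x
    qb_x = fold_b is not None and fold_b >= x
    qa_y = fold_a is not None and fold_a >= y
    qb_y = fold_b is not None and fold_b >= y
    same = top_a is not None and top_a == top_b
    if same and ((qa_x and qb_y) or (qb_x and qa_y)):
        return "common"
    if qa_x and qb_x:
        return "discordant"
    if qa_x:
        return "a_only"
    if qb_x:
        return "b_only"
    return None


def rank_pearson(x, y):
    """Spearman by definition: Pearson correlation of average ranks."""
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


def naive_upgma_heights(dist):
    """O(n^3) average-linkage: merge heights from the original distance matrix."""
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (math.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


def random_instance(rng, n_peaks=20, n_genes=5, n_chroms=2, span=5000):
    """A random small peak/gene instance for oracle-equivalence checks."""
    from cagecompare.io_formats import GeneModel, PeakTable
    import pandas as pd

    genes = []
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_tss = int(rng.integers(1, 4))
        tss = frozenset(int(rng.integers(1000, span)) for _ in range(n_tss))
        genes.append(GeneModel(f"g{i}", f"g{i}", "protein_coding", chrom, strand, tss))
    rows, expr = [], []
    for i in range(n_peaks):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        strand = "+" if rng.random() < 0.5 else "-"
        rep = int(rng.integers(1000, span))
        rows.append((chrom, rep - 1, rep + 10, f"p{i}", strand, rep))
        expr.append(rng.random(2) * 10)
    import pandas as pd

    peaks_df = pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id", "strand", "rep_pos"]).set_index("peak_id")
    expr_df = pd.DataFrame(expr, index=peaks_df.index, columns=["s1", "s2"])
    return PeakTable(peaks=peaks_df, expression=expr_df), genes
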