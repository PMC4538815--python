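"""Paired two-platform synthetic tissue transcriptomes with known ground truth.

The generator emulates the comparison of a 5'-tag (CAGE-like, platform A) and
a full-length (RNA-Seq-like, platform B) tissue panel sharing one underlying
truth: a genes x tissues mean-expression matrix containing planted
ubiquitously expressed genes, single-tissue-enriched genes at an exact fold,
and background "other" genes.  On top of the shared truth, each platform
observes replicate samples with multiplicative lognormal noise and
platform-specific corruptions drawn from the known discrepancy taxonomy:

* polyA(-) loss      — platform B signal multiplied by a depletion factor
                       (these transcripts are under-captured by polyA
                       selection, not absent);
* multi-mapping loss — platform A signal zeroed and no peak emitted (tags
                       aligning to several genomic locations are discarded);
* distal TSS         — the gene's peak is displaced beyond the assignment
                       window, so window-based quantification loses it while
                       the peak itself still carries signal;
* contamination      — one platform's samples of a destination tissue are
                       mixed with a source tissue's profile (the
                       muscle-in-adipose scenario).

Genes are laid out on a single synthetic chromosome with 10 kb spacing so
window assignment is unambiguous except where deliberately planted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneModel,
    PeakTable,
    SampleSheet,
    write_expression_matrix,
    write_peak_table,
    write_sample_sheet,
)

__all__ = [
    "TISSUES_22",
    "SimulationParams",
    "TruthLabels",
    "SyntheticBundle",
    "generate_truth",
    "observe_platforms",
    "write_bundle",
    "recovery_report",
]

# The 22 tissues shared by both published panels.
TISSUES_22 = (
    "adipose", "appendix", "bladder", "brain", "colon", "esophagus",
    "gallbladder", "heart", "kidney", "liver", "lung", "lymph_node",
    "ovary", "pancreas", "placenta", "prostate", "salivary_gland",
    "small_intestine", "spleen", "testis", "thyroid", "uterus",
)

# CAGE-like panel: 27 samples over 22 tissues (brain, colon, heart, lung and
# testis sampled twice, everything else once).
_DUPLICATED_A = ("brain", "colon", "heart", "lung", "testis")


def _default_replicates_a(tissues: Sequence[str]) -> dict[str, int]:
    return {t: (2 if t in _DUPLICATED_A else 1) for t in tissues}


def _default_replicates_b(tissues: Sequence[str]) -> dict[str, int]:
    # RNA-Seq-like panel: 79 samples over 22 tissues; per-tissue counts are
    # not published, so the first 13 tissues (alphabetical) get 4 replicates
    # and the rest 3, reproducing the stated total.
    return {t: (4 if i < 13 else 3) for i, t in enumerate(sorted(tissues))}


def _default_enriched_weights(tissues: Sequence[str]) -> dict[str, float]:
    # Skewed tissue assignment mirroring the observed distribution of
    # single-tissue-enriched genes: testis-dominated, then brain and liver.
    skew = {"testis": 0.38, "brain": 0.21, "liver": 0.10}
    rest = [t for t in tissues if t not in skew]
    w = (1.0 - sum(skew.values())) / len(rest)
    out = {t: skew.get(t, w) for t in tissues}
    return out


@dataclass
class SimulationParams:
    """Knobs of the paired-platform simulation; defaults are the study conditions."""

    n_genes: int = 2000
    tissues: tuple[str, ...] = TISSUES_22
    replicates_a: Mapping[str, int] | None = None  # None -> 27-sample layout
    replicates_b: Mapping[str, int] | None = None  # None -> 79-sample layout
    fraction_ubiquitous: float = 0.30
    fraction_enriched: float = 0.10
    f_planted: float = 8.0
    enriched_tissue_weights: Mapping[str, float] | None = None
    noise_sd_a: float = 0.2  # sd of log-signal, natural log
    noise_sd_b: float = 0.2
    polyA_minus_fraction: float = 0.02
    polyA_depletion: float = 0.05
    multimap_loss_fraction: float = 0.02
    distal_tss_fraction: float = 0.02
    distal_offset_range: tuple[int, int] = (600, 5000)
    contamination: tuple[str, str, float] | None = None  # (src, dst, weight) on platform A
    ubiquitous_base_range: tuple[float, float] = (5.0, 500.0)
    polyA_base_range: tuple[float, float] = (3.0, 15.0)
    enriched_background_range: tuple[float, float] = (0.15, 0.5)
    other_log_median: float = 0.8
    other_log_sd: float = 1.5
    gene_spacing_bp: int = 10_000
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = [
            self.fraction_ubiquitous,
            self.fraction_enriched,
            self.polyA_minus_fraction,
            self.multimap_loss_fraction,
            self.distal_tss_fraction,
        ]
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("all gene-class fractions must lie in [0, 1]")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValueError(f"gene-class fractions sum to {sum(fracs):.3f} > 1")
        if self.f_planted <= 1:
            raise ValueError("f_planted must be > 1")
        if not 0 < self.polyA_depletion < 1:
            raise ValueError("polyA_depletion must be in (0, 1)")
        if self.contamination is not None:
            src, dst, w = self.contamination
            if src not in self.tissues or dst not in self.tissues:
                raise ValueError("contamination tissues must be in the tissue panel")
            if not 0 <= w <= 1:
                raise ValueError("contamination weight must be in [0, 1]")
        lo, hi = self.distal_offset_range
        if lo <= 500:
            raise ValueError("distal offsets must exceed the 500 bp window")
        if hi >= self.gene_spacing_bp - 500:
            raise ValueError("distal offsets must stay clear of the neighbouring gene")

    def resolved_replicates(self) -> tuple[dict[str, int], dict[str, int]]:
        a = dict(self.replicates_a) if self.replicates_a is not None else _default_replicates_a(self.tissues)
        b = dict(self.replicates_b) if self.replicates_b is not None else _default_replicates_b(self.tissues)
        return a, b


@dataclass
class TruthLabels:
    """Ground truth of one simulation: per-gene class labels and the mean matrix.

    ``labels`` columns: gene_class (ubiquitous | enriched | other |
    polyA_minus | multimap_lost | distal_tss), tissue (planted tissue for
    enriched genes, else empty), base (the gene's background scale),
    distal_offset_bp (0 except for distal genes).  ``mean_matrix`` is the
    uncorrupted genes x tissues truth; for enriched genes its top/second
    tissue ratio equals ``f_planted`` exactly.
    """

    labels: pd.DataFrame
    mean_matrix: pd.DataFrame
    params: SimulationParams

    def genes_of_class(self, gene_class: str) -> list[str]:
        return list(self.labels.index[self.labels["gene_class"] == gene_class])


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def generate_truth(params: SimulationParams) -> TruthLabels:
    """Draw the shared ground-truth mean matrix and gene class labels."""
    rng = np.random.default_rng([params.seed, 0])
    n = params.n_genes
    tissues = list(params.tissues)
    n_t = len(tissues)
    width = len(str(max(n - 1, 1)))
    gene_ids = [f"g{i:0{width}d}" for i in range(n)]

    counts = {
        "ubiquitous": round(params.fraction_ubiquitous * n),
        "enriched": round(params.fraction_enriched * n),
        "polyA_minus": round(params.polyA_minus_fraction * n),
        "multimap_lost": round(params.multimap_loss_fraction * n),
        "distal_tss": round(params.distal_tss_fraction * n),
    }
    if sum(counts.values()) > n:
        raise ValueError("gene-class fractions are infeasible for n_genes")
    classes: list[str] = []
    for cls, c in counts.items():
        classes.extend([cls] * c)
    classes.extend(["other"] * (n - len(classes)))

    mean = np.zeros((n, n_t))
    tissue_col = [""] * n
    base_col = np.zeros(n)
    offsets = np.zeros(n, dtype=int)

    weights = params.enriched_tissue_weights or _default_enriched_weights(tissues)
    wvec = np.array([weights.get(t, 0.0) for t in tissues], dtype=float)
    if wvec.sum() <= 0:
        raise ValueError("enriched tissue weights must have positive mass")
    wvec = wvec / wvec.sum()

    for i, cls in enumerate(classes):
        if cls in ("ubiquitous", "multimap_lost", "distal_tss"):
            base = _loguniform(rng, *params.ubiquitous_base_range, 1)[0]
            mean[i, :] = base
        elif cls == "polyA_minus":
            # abundant enough to call everywhere, low enough that the polyA
            # depletion factor pushes the RNA-Seq-like signal below detection
            base = _loguniform(rng, *params.polyA_base_range, 1)[0]
            mean[i, :] = base
        elif cls == "enriched":
            base = _loguniform(rng, *params.enriched_background_range, 1)[0]
            ti = int(rng.choice(n_t, p=wvec))
            mean[i, :] = base
            mean[i, ti] = params.f_planted * base
            tissue_col[i] = tissues[ti]
        else:  # other: independent per-tissue profile, mostly sub-threshold
            base = params.other_log_median
            mean[i, :] = base * np.exp(rng.normal(0.0, params.other_log_sd, n_t))
        base_col[i] = base
        if cls == "distal_tss":
            lo, hi = params.distal_offset_range
            offsets[i] = int(rng.integers(lo, hi + 1)) * (1 if rng.random() < 0.5 else -1)

    labels = pd.DataFrame(
        {
            "gene_class": classes,
            "tissue": tissue_col,
            "base": base_col,
            "distal_offset_bp": offsets,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    mean_matrix = pd.DataFrame(mean, index=labels.index, columns=tissues)
    return TruthLabels(labels=labels, mean_matrix=mean_matrix, params=params)


@dataclass
class SyntheticBundle:
    """Everything a pipeline run needs, in memory."""

    mat_a: ExpressionMatrix  # CAGE-like gene-level TPM (post-corruption)
    mat_b: ExpressionMatrix  # RNA-Seq-like FPKM (post-corruption)
    peaks: PeakTable
    genes: list[GeneModel]
    sheet: SampleSheet


def _sample_matrix(
    mean: pd.DataFrame,
    replicates: Mapping[str, int],
    noise_sd: float,
    rng: np.random.Generator,
    suffix: str,
    contamination: tuple[str, str, float] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str, int]]]:
    cols = {}
    sheet_rows = []
    for tissue in mean.columns:
        profile = mean[tissue].to_numpy(float)
        if contamination is not None:
            src, dst, w = contamination
            if tissue == dst:
                profile = (1 - w) * profile + w * mean[src].to_numpy(float)
        for r in range(1, int(replicates[tissue]) + 1):
            sid = f"{tissue}_{suffix}{r}"
            noise = np.exp(rng.normal(0.0, noise_sd, len(profile))) if noise_sd > 0 else 1.0
            cols[sid] = profile * noise
            sheet_rows.append((sid, tissue, r))
    return pd.DataFrame(cols, index=mean.index), sheet_rows


def observe_platforms(truth: TruthLabels, params: SimulationParams | None = None) -> SyntheticBundle:
    """Observe the truth through both platforms, applying the planted corruptions.

    Platform A (CAGE-like) is returned both as a gene-level TPM matrix — what
    window-500 quantification of the emitted peak table yields, i.e. with
    multi-mapping and distal genes zeroed — and as the peak table itself,
    whose displaced distal peaks still carry the signal so that re-assignment
    with a larger window recovers those genes.
    """
    params = params or truth.params
    rng = np.random.default_rng([params.seed, 1])
    rep_a, rep_b = params.resolved_replicates()

    vals_a, rows_a = _sample_matrix(truth.mean_matrix, rep_a, params.noise_sd_a, rng, "cage", params.contamination)
    vals_b, rows_b = _sample_matrix(truth.mean_matrix, rep_b, params.noise_sd_b, rng, "rnaseq")

    labels = truth.labels
    polyA = labels.index[labels["gene_class"] == "polyA_minus"]
    mm = labels.index[labels["gene_class"] == "multimap_lost"]
    distal = labels.index[labels["gene_class"] == "distal_tss"]

    vals_b.loc[polyA] *= params.polyA_depletion

    # peak table carries the pre-window-loss signal; distal peaks keep theirs
    peak_expr = vals_a.copy()
    vals_a.loc[mm] = 0.0
    vals_a.loc[distal] = 0.0

    gene_ids = list(labels.index)
    mm_set = set(mm)
    spacing = params.gene_spacing_bp
    genes = []
    peak_rows = []
    kept_peaks = []
    for i, gid in enumerate(gene_ids):
        tss = 2 * spacing + spacing * i  # deep inside the synthetic chromosome
        genes.append(
            GeneModel(
                gene_id=gid,
                gene_name=gid,
                biotype="protein_coding",
                chrom=params.chrom,
                strand="+",
                tss_positions=frozenset({tss}),
            )
        )
        if gid in mm_set:
            continue  # multi-mapping tags were discarded: no peak at all
        rep = tss + int(labels.loc[gid, "distal_offset_bp"])
        peak_rows.append((params.chrom, rep - 1, rep + 20, f"p_{gid}", "+", rep))
        kept_peaks.append(gid)

    peaks_df = pd.DataFrame(
        peak_rows, columns=["chrom", "start", "end", "peak_id", "strand", "rep_pos"]
    ).set_index("peak_id")
    expr = peak_expr.loc[kept_peaks]
    expr.index = peaks_df.index
    peaks = PeakTable(peaks=peaks_df, expression=expr)

    sheet_df = pd.DataFrame(
        [(sid, t, "CAGE", r) for sid, t, r in rows_a] + [(sid, t, "RNASEQ", r) for sid, t, r in rows_b],
        columns=["sample_id", "tissue", "dataset_label", "replicate_index"],
    ).set_index("sample_id")

    return SyntheticBundle(
        mat_a=ExpressionMatrix(vals_a, unit="TPM", dataset_label="CAGE"),
        mat_b=ExpressionMatrix(vals_b, unit="FPKM", dataset_label="RNASEQ"),
        peaks=peaks,
        genes=genes,
        sheet=SampleSheet(sheet_df),
    )


def _gtf_lines(genes: Sequence[GeneModel]) -> list[str]:
    lines = []
    for g in genes:
        for j, tss in enumerate(sorted(g.tss_positions)):
            start, end = (tss, tss + 1500) if g.strand == "+" else (tss - 1500, tss)
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t{j}"; '
                f'gene_name "{g.gene_name}"; gene_biotype "protein_coding";'
            )
            if j == 0:
                gene_attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; gene_biotype "protein_coding";'
                lines.append(f"{g.chrom}\tsynthetic\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t{gene_attrs}")
            lines.append(f"{g.chrom}\tsynthetic\ttranscript\t{start}\t{end}\t.\t{g.strand}\t.\t{attrs}")
    return lines


def write_bundle(bundle: SyntheticBundle, truth: TruthLabels, out_dir: str | Path) -> dict[str, str]:
    """Write the bundle in the exact on-disk formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": out / "annotation.gtf",
        "peaks": out / "cage_peaks.tsv",
        "rnaseq": out / "rnaseq_fpkm.tsv",
        "cage_gene": out / "cage_gene_tpm.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth_labels.tsv",
    }
    with open(paths["gtf"], "w") as fh:
        fh.write("\n".join(_gtf_lines(bundle.genes)) + "\n")
    write_peak_table(bundle.peaks, paths["peaks"])
    write_expression_matrix(bundle.mat_b, paths["rnaseq"])
    write_expression_matrix(bundle.mat_a, paths["cage_gene"])
    write_sample_sheet(bundle.sheet, paths["samples"])
    truth.labels.to_csv(paths["truth"], sep="\t")
    return {k: str(v) for k, v in paths.items()}


def recovery_report(
    truth: TruthLabels,
    *,
    enrich_a,
    enrich_b,
    ubiquitous_a: set[str],
    ubiquitous_b: set[str],
    ubiquity_categories=None,
    x: float = 7.0,
) -> dict[str, float]:
    """Score pipeline outputs against the planted ground truth.

    Ubiquitous recovery is judged per platform against the genes whose *true
    per-platform profile* is ubiquitous: the planted ubiquitous genes plus, on
    the CAGE-like side, polyA(-) genes (full signal there), and on the
    RNA-Seq-like side, multi-mapping-lost and distal-TSS genes (full signal
    there).  Enriched recovery asks whether a planted gene qualifies at fold x
    with the planted tissue in either platform.  If ``ubiquity_categories`` (a
    CategoryAgreement) is given, planted discrepancy genes are additionally
    scored on landing in their predicted A-only / B-only category.
    """
    labels = truth.labels
    planted_ub = set(labels.index[labels["gene_class"] == "ubiquitous"])
    polyA = set(labels.index[labels["gene_class"] == "polyA_minus"])
    mm = set(labels.index[labels["gene_class"] == "multimap_lost"])
    distal = set(labels.index[labels["gene_class"] == "distal_tss"])
    expected_ub_a = planted_ub | polyA
    expected_ub_b = planted_ub | mm | distal

    def prf(called: set[str], expected: set[str]) -> tuple[float, float]:
        tp = len(called & expected)
        precision = tp / len(called) if called else 1.0
        recall = tp / len(expected) if expected else 1.0
        return precision, recall

    prec_a, rec_a = prf(ubiquitous_a, expected_ub_a)
    prec_b, rec_b = prf(ubiquitous_b, expected_ub_b)

    enriched = labels[labels["gene_class"] == "enriched"]
    qa, qb = enrich_a.qualifying(x), enrich_b.qualifying(x)
    rec_ea = rec_eb = rec_either = top_ok = 0
    for gid, row in enriched.iterrows():
        tissue = row["tissue"]
        in_a = gid in qa and enrich_a.top_tissue_of(gid) == tissue
        in_b = gid in qb and enrich_b.top_tissue_of(gid) == tissue
        rec_ea += in_a
        rec_eb += in_b
        rec_either += in_a or in_b
        top_ok += (enrich_a.top_tissue_of(gid) == tissue) or (enrich_b.top_tissue_of(gid) == tissue)
    n_e = len(enriched)
    planted_set = set(enriched.index)
    prec_ea = len(qa & planted_set) / len(qa) if qa else 1.0
    prec_eb = len(qb & planted_set) / len(qb) if qb else 1.0

    out = {
        "ubiquitous_precision_a": prec_a,
        "ubiquitous_recall_a": rec_a,
        "ubiquitous_precision_b": prec_b,
        "ubiquitous_recall_b": rec_b,
        "enriched_recall_a": rec_ea / n_e if n_e else 1.0,
        "enriched_recall_b": rec_eb / n_e if n_e else 1.0,
        "enriched_recall_either": rec_either / n_e if n_e else 1.0,
        "enriched_top_tissue_accuracy": top_ok / n_e if n_e else 1.0,
        "enriched_precision_a": prec_ea,
        "enriched_precision_b": prec_eb,
        "x": x,
    }

    if ubiquity_categories is not None:
        hits = misses = 0
        for g in polyA:
            hits += g in ubiquity_categories.a_only
            misses += g not in ubiquity_categories.a_only
        for g in mm | distal:
            hits += g in ubiquity_categories.b_only
            misses += g not in ubiquity_categories.b_only
        total = hits + misses
        out["discrepancy_class_accuracy"] = hits / total if total else 1.0
        out["n_discrepancy_genes"] = float(total)
    return out
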