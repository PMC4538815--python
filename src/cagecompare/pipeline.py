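"""Configuration-driven end-to-end runs: simulate, quantify, classify, compare.

``RunConfig`` freezes the published analysis parameters as defaults —
expression threshold 1.0, low-expression diagnostic 3.0, assignment window
500 bp, enrichment cutoffs x in {3, 5, 7, 10} with relaxed pairs
{(5,3), (7,3), (7,5), (10,5)}, ubiquity tolerance 0.95 and distance bins
(500, 1500] and (1500, 10000].  ``run_compare`` executes quantification ->
classification -> agreement -> correlation -> distance stages and writes a
deterministic report bundle; ``run_simulate`` emits a synthetic dataset in the
standard on-disk formats.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .cage_gene_quant import assign_peaks, bin_distal_genes, closest_distances, gene_level_expression
from .cross_platform import cluster_samples, exclude_enriched_and_recorrelate, expressed_universe, ratio_stats, spearman_all_vs_all
from .expression_classes import (
    EnrichmentCriteria,
    call_expressed,
    enrichment_agreement,
    enrichment_call,
    expressed_agreement_per_tissue,
    tissue_distribution,
    ubiquitous_set,
    ubiquity_agreement,
)
from .io_formats import (
    read_expression_matrix,
    read_gtf,
    read_peak_table,
    read_sample_sheet,
    write_report_tables,
)
from .synthetic_data import SimulationParams, generate_truth, observe_platforms, recovery_report, write_bundle

__all__ = ["RunConfig", "PipelineError", "run_compare", "run_simulate"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs, thresholds and cutoffs of a comparison run (defaults as published)."""

    gtf: str = ""
    peaks: str = ""
    rnaseq_matrix: str = ""
    sample_sheet: str = ""
    truth_labels: str = ""  # optional; enables the recovery report
    out_dir: str = "cagecompare_out"

    expression_threshold: float = 1.0
    low_expression_threshold: float = 3.0
    window_bp: int = 500
    strand_policy: str = "same_strand"
    fold_cutoffs: tuple[float, ...] = (3.0, 5.0, 7.0, 10.0)
    relaxed_pairs: tuple[tuple[float, float], ...] = ((5.0, 3.0), (7.0, 3.0), (7.0, 5.0), (10.0, 5.0))
    tolerance: float = 0.95
    aggregation: str = "mean"
    enrichment_floor: float = 0.1
    distance_bins: tuple[tuple[float, float], ...] = ((500.0, 1500.0), (1500.0, 10000.0))
    biotype_filter: str | None = "protein_coding"
    dataset_label_a: str = "CAGE"
    dataset_label_b: str = "RNASEQ"
    seed: int = 0

    def __post_init__(self) -> None:
        self.fold_cutoffs = tuple(float(x) for x in self.fold_cutoffs)
        self.relaxed_pairs = tuple((float(x), float(y)) for x, y in self.relaxed_pairs)
        self.distance_bins = tuple((float(lo), float(hi)) for lo, hi in self.distance_bins)
        for x, y in self.relaxed_pairs:
            if y >= x:
                raise ValueError(f"relaxed pair ({x}, {y}) invalid: y must be < x")
        if not 0 < self.tolerance <= 1:
            raise ValueError("tolerance must be in (0, 1]")
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "relaxed_pairs" in raw:
            raw["relaxed_pairs"] = tuple(tuple(p) for p in raw["relaxed_pairs"])
        if "distance_bins" in raw:
            raw["distance_bins"] = tuple(tuple(b) for b in raw["distance_bins"])
        if "fold_cutoffs" in raw:
            raw["fold_cutoffs"] = tuple(raw["fold_cutoffs"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:12]


def _cutoff_label(x: float, y: float | None = None) -> str:
    fmt = lambda v: f"{v:g}"
    return f"{fmt(x)}x" if y is None or y == x else f"{fmt(x)}x-{fmt(y)}x"


def run_compare(config: RunConfig) -> dict[str, Any]:
    """Run the full comparison; returns the result objects and writes the report.

    Stages: CAGE quantification -> expressed/ubiquitous/enriched classification
    -> cross-dataset agreement -> correlation & clustering -> TSS-distance
    diagnostics.  Any stage failure aborts with the stage name, and partial
    outputs are removed.
    """
    out_dir = Path(config.out_dir)
    results: dict[str, Any] = {}
    report: dict[str, Any] = {}
    stage = "read_inputs"
    try:
        gtf = read_gtf(config.gtf, biotype_filter=config.biotype_filter)
        peaks = read_peak_table(config.peaks)
        mat_b = read_expression_matrix(config.rnaseq_matrix, unit="FPKM", dataset_label=config.dataset_label_b)
        sheet = read_sample_sheet(config.sample_sheet)
        sheet_a = sheet.for_dataset(config.dataset_label_a)
        sheet_b = sheet.for_dataset(config.dataset_label_b)

        stage = "quantify_cage"
        assignment = assign_peaks(peaks, gtf.genes, window_bp=config.window_bp, strand_policy=config.strand_policy)
        mat_a = gene_level_expression(peaks, assignment, gtf.genes, dataset_label=config.dataset_label_a)
        # restrict both matrices to the shared annotated gene universe
        shared = mat_a.values.index.intersection(mat_b.values.index)
        mat_a = mat_a.subset_genes(shared)
        mat_b = mat_b.subset_genes(shared)

        stage = "classify"
        calls_a = call_expressed(mat_a, config.expression_threshold)
        calls_b = call_expressed(mat_b, config.expression_threshold)
        ubiq = ubiquity_agreement(calls_a, calls_b, tolerance=config.tolerance)
        criteria = EnrichmentCriteria(
            aggregation=config.aggregation,
            floor=config.enrichment_floor,
            expression_threshold=config.expression_threshold,
        )
        enrich_a = enrichment_call(mat_a, sheet_a, criteria)
        enrich_b = enrichment_call(mat_b, sheet_b, criteria)

        stage = "agreement"
        enr_agreements = {}
        tops_by_setting = {}
        for x in config.fold_cutoffs:
            agr = enrichment_agreement(enrich_a, enrich_b, x, x)
            enr_agreements[_cutoff_label(x)] = agr
            tops = [enrich_a.top_tissue_of(g) for g in agr.universe & enrich_a.qualifying(x)]
            tops += [enrich_b.top_tissue_of(g) for g in (agr.universe & enrich_b.qualifying(x)) - enrich_a.qualifying(x)]
            tops_by_setting[_cutoff_label(x)] = tops
        for x, y in config.relaxed_pairs:
            agr = enrichment_agreement(enrich_a, enrich_b, x, y)
            enr_agreements[_cutoff_label(x, y)] = agr
            tops = [enrich_a.top_tissue_of(g) for g in agr.universe & enrich_a.qualifying(x)]
            tops += [enrich_b.top_tissue_of(g) for g in (agr.universe & enrich_b.qualifying(x)) - enrich_a.qualifying(x)]
            tops_by_setting[_cutoff_label(x, y)] = tops
        dist = tissue_distribution(
            tops_by_setting,
            tissues=sheet.tissues,
            strict_settings=[_cutoff_label(x) for x in config.fold_cutoffs],
            relaxed_settings=[_cutoff_label(x, y) for x, y in config.relaxed_pairs],
        )
        per_tissue = expressed_agreement_per_tissue(calls_a, calls_b, sheet_a, sheet_b)

        stage = "correlation"
        universe = expressed_universe(mat_a, mat_b, config.expression_threshold)
        corr = spearman_all_vs_all(mat_a, mat_b, gene_universe=universe)
        corr_aa = spearman_all_vs_all(mat_a, mat_a, gene_universe=universe)
        dendro = cluster_samples(corr_aa.values)
        ratios = ratio_stats(mat_a, mat_b, sheet_a, sheet_b, aggregation=config.aggregation, genes=universe)

        stage = "distances"
        distances = closest_distances(peaks, gtf.genes, strand_policy=config.strand_policy)
        expressed_b = set(calls_b.calls.index[calls_b.calls.any(axis=1)])
        distal_bins = bin_distal_genes(distances, expressed_b, bins=config.distance_bins)

        stage = "report"
        category_rows = []
        for gid in sorted(ubiq.universe):
            cat = "common" if gid in ubiq.common else ("a_only" if gid in ubiq.a_only else "b_only")
            category_rows.append((gid, "ubiquitous", cat, "", ""))
        for label, agr in sorted(enr_agreements.items()):
            for gid in sorted(agr.universe):
                cat = (
                    "common" if gid in agr.common
                    else "a_only" if gid in agr.a_only
                    else "b_only" if gid in agr.b_only
                    else "discordant"
                )
                top = enrich_a.top_tissue_of(gid) or enrich_b.top_tissue_of(gid) or ""
                category_rows.append((gid, f"enriched_{label}", cat, top, label))
        categories = pd.DataFrame(
            category_rows, columns=["gene_id", "category", "agreement", "top_tissue", "cutoff"]
        ).set_index("gene_id")

        agreement_summary = {
            "ubiquitous": {**ubiq.counts, "percent_common": ubiq.percent_common},
            "enriched": {
                label: {**agr.counts, "percent_common": agr.percent_common}
                for label, agr in enr_agreements.items()
            },
            "distal_gene_bins": {f"({lo:g},{hi:g}]": n for (lo, hi), n in distal_bins.items()},
            "n_expressed_universe": len(universe),
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "version": __version__,
        }

        results = {
            "ubiquity": ubiq,
            "enrichment_agreements": enr_agreements,
            "enrich_a": enrich_a,
            "enrich_b": enrich_b,
            "calls_a": calls_a,
            "calls_b": calls_b,
            "mat_a": mat_a,
            "mat_b": mat_b,
            "correlation": corr,
            "dendrogram": dendro,
            "ratios": ratios,
            "distances": distances,
            "distal_bins": distal_bins,
            "tissue_distribution": dist,
            "per_tissue_agreement": per_tissue,
            "agreement_summary": agreement_summary,
        }

        if config.truth_labels:
            stage = "recovery"
            labels = pd.read_csv(config.truth_labels, sep="\t", index_col=0, keep_default_na=False)
            truth = _TruthShim(labels)
            recovery = recovery_report(
                truth,
                enrich_a=enrich_a,
                enrich_b=enrich_b,
                ubiquitous_a=ubiquitous_set(calls_a),
                ubiquitous_b=ubiquitous_set(calls_b),
                ubiquity_categories=ubiq,
                x=7.0,
            )
            results["recovery"] = recovery
            agreement_summary["recovery"] = recovery

        stage = "write_outputs"
        manifest = write_report_tables(
            {
                "agreement_summary": agreement_summary,
                "category_gene_lists": categories,
                "correlation_matrix": corr.values,
                "per_tissue_agreement": per_tissue,
                "tissue_distribution": dist.proportions,
                "tissue_distribution_tests": dist.tests,
                "ratio_per_gene": ratios.per_gene,
                "gene_distances": distances.gene_distance.to_frame(),
                "enrichment_calls_a": enrich_a.table,
                "enrichment_calls_b": enrich_b.table,
            },
            out_dir,
        )
        with open(out_dir / "dendrogram.newick", "w") as fh:
            fh.write(dendro.to_newick() + "\n")
        manifest["dendrogram"] = str(out_dir / "dendrogram.newick")
        results["manifest"] = manifest
    except Exception as exc:
        if out_dir.exists() and not results:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise PipelineError(stage, exc) from exc
    return results


class _TruthShim:
    """Adapter giving recovery_report the label frame it needs from a TSV."""

    def __init__(self, labels: pd.DataFrame):
        self.labels = labels


def run_simulate(params: SimulationParams, out_dir: str | Path) -> dict[str, str]:
    """Generate a synthetic two-platform bundle and write it to ``out_dir``."""
    truth = generate_truth(params)
    bundle = observe_platforms(truth, params)
    return write_bundle(bundle, truth, out_dir)
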