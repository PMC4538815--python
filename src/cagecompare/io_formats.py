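"""Readers, writers and in-memory containers for the pipeline's external formats.

Coordinate conventions are normalised once, at this boundary:

* GTF is 1-based, inclusive on both ends (Ensembl dialect).
* Peak tables are BED-like on disk — 0-based start, exclusive end — and carry a
  1-based representative position (``rep_pos``) internally.  All distance
  arithmetic downstream works on 1-based positions.

The transcription start site (TSS) of a transcript is its 5'-most base on its
own strand: the ``start`` coordinate for ``+`` transcripts and the ``end``
coordinate for ``-`` transcripts.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "GtfResult",
    "PeakTable",
    "ExpressionMatrix",
    "SampleSheet",
    "read_gtf",
    "read_peak_table",
    "write_peak_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_report_tables",
]

NONCODING_BIOTYPES = frozenset(
    {
        "lincRNA",
        "lncRNA",
        "miRNA",
        "misc_RNA",
        "rRNA",
        "snRNA",
        "snoRNA",
        "antisense",
        "sense_intronic",
        "sense_overlapping",
        "processed_transcript",
        "3prime_overlapping_ncrna",
        "ncRNA",
    }
)


def _biotype_class(raw: str) -> str:
    if raw == "protein_coding":
        return "protein_coding"
    if raw in NONCODING_BIOTYPES:
        return "noncoding"
    return "other"


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: identity, location and its set of transcript TSSes."""

    gene_id: str
    gene_name: str
    biotype: str  # protein_coding | noncoding | other
    chrom: str
    strand: str  # '+' or '-'
    tss_positions: frozenset[int]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.tss_positions:
            raise ValueError(f"gene {self.gene_id}: tss_positions must be non-empty")
        if any(p < 1 for p in self.tss_positions):
            raise ValueError(f"gene {self.gene_id}: TSS positions must be >= 1")


@dataclass
class GtfResult:
    """Genes parsed from a GTF plus a count of rejected transcript records."""

    genes: list[GeneModel]
    n_rejected: int = 0

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str | Path, biotype_filter: str | None = None) -> GtfResult:
    """Parse an Ensembl-style GTF into gene models with strand-aware TSS sets.

    A transcript's TSS is taken from ``transcript`` feature lines when present,
    otherwise reconstructed as the 5'-most exon boundary of that transcript.
    Transcripts without a usable strand are rejected and counted in
    ``GtfResult.n_rejected``.

    Parameters
    ----------
    path:
        GTF file path.
    biotype_filter:
        If given (e.g. ``"protein_coding"``), only genes of that biotype class
        are returned.
    """
    # per transcript: [chrom, strand, min_start, max_end, gene_id]
    transcripts: dict[str, list] = {}
    gene_meta: dict[str, dict] = {}
    n_rejected = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature not in ("gene", "transcript", "exon"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GTF line {lineno}: non-integer coordinates") from exc
            attrs = dict(_ATTR_RE.findall(attrs_s))
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}: malformed GTF line {lineno}: missing gene_id attribute")

            meta = gene_meta.setdefault(gene_id, {"gene_name": gene_id, "biotype_raw": "", "chrom": chrom, "strand": strand})
            if "gene_name" in attrs:
                meta["gene_name"] = attrs["gene_name"]
            raw_bt = attrs.get("gene_biotype") or attrs.get("gene_type")
            if raw_bt:
                meta["biotype_raw"] = raw_bt
            if feature == "gene":
                meta["chrom"], meta["strand"] = chrom, strand
                continue

            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            if strand not in ("+", "-"):
                n_rejected += 1
                warnings.warn(f"{path}: line {lineno}: transcript {tid} lacks a valid strand; record rejected")
                continue
            rec = transcripts.setdefault(tid, [chrom, strand, start, end, gene_id])
            rec[2] = min(rec[2], start)
            rec[3] = max(rec[3], end)

    tss_by_gene: dict[str, set[int]] = {}
    for chrom, strand, start, end, gene_id in transcripts.values():
        tss_by_gene.setdefault(gene_id, set()).add(start if strand == "+" else end)

    genes = []
    for gene_id, tss in sorted(tss_by_gene.items()):
        meta = gene_meta[gene_id]
        if meta["strand"] not in ("+", "-"):
            n_rejected += 1
            continue
        bt = _biotype_class(meta["biotype_raw"])
        if biotype_filter is not None and bt != biotype_filter:
            continue
        genes.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=meta["gene_name"],
                biotype=bt,
                chrom=meta["chrom"],
                strand=meta["strand"],
                tss_positions=frozenset(tss),
            )
        )
    return GtfResult(genes=genes, n_rejected=n_rejected)


_PEAK_COLS = ["chrom", "start", "end", "peak_id", "strand"]


@dataclass
class PeakTable:
    """5'-tag clusters: BED-derived coordinates plus per-sample TPM expression.

    ``peaks`` is indexed by peak_id with columns chrom, start (0-based), end
    (exclusive), strand, rep_pos (1-based).  ``expression`` is indexed by
    peak_id with one TPM column per sample.
    """

    peaks: pd.DataFrame
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.peaks
        if not p.index.is_unique:
            dups = p.index[p.index.duplicated()].tolist()
            raise ValueError(f"duplicate peak_id(s): {dups[:5]}")
        bad = p[p["start"] >= p["end"]]
        if len(bad):
            raise ValueError(f"start >= end for peak(s): {bad.index.tolist()[:5]}")
        bad = p[(p["rep_pos"] < p["start"] + 1) | (p["rep_pos"] > p["end"])]
        if len(bad):
            raise ValueError(f"rep_pos outside peak for peak(s): {bad.index.tolist()[:5]}")
        if not self.expression.index.equals(p.index):
            raise ValueError("expression rows must match peak table rows")
        if self.expression.isna().to_numpy().any():
            raise ValueError("missing expression cells are not allowed")
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("negative TPM values are not allowed")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    def __len__(self) -> int:
        return len(self.peaks)


def _default_rep_pos(start: pd.Series, end: pd.Series, strand: pd.Series) -> pd.Series:
    # 5'-most base of the peak on its own strand, as a 1-based position
    return pd.Series(np.where(strand == "-", end, start + 1), index=start.index, dtype=int)


def read_peak_table(path: str | Path) -> PeakTable:
    """Read a BED-like peak table with appended per-sample TPM columns.

    Expected header: ``chrom start end peak_id strand [rep_pos] <sample>...``.
    ``rep_pos`` (1-based representative position) defaults to the peak's
    5'-most base on its own strand when absent.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _PEAK_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"{path}: start >= end in row(s) for peak(s) {bad['peak_id'].tolist()[:5]}")
    if df["peak_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate peak_id(s): {df['peak_id'][df['peak_id'].duplicated()].tolist()[:5]}")

    has_rep = "rep_pos" in df.columns
    sample_cols = [c for c in df.columns if c not in _PEAK_COLS + ["rep_pos"]]
    expr = df[sample_cols].copy()
    for col in sample_cols:
        vals = pd.to_numeric(expr[col], errors="coerce")
        if vals.isna().any():
            row = int(np.where(vals.isna())[0][0])
            raise ValueError(f"{path}: non-numeric or missing expression in column {col!r}, row {row}")
        expr[col] = vals
    if (expr.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative TPM values are not allowed")

    peaks = df[_PEAK_COLS].copy().set_index("peak_id")
    if has_rep:
        peaks["rep_pos"] = df.set_index("peak_id")["rep_pos"].astype(int)
    else:
        peaks["rep_pos"] = _default_rep_pos(peaks["start"], peaks["end"], peaks["strand"])
    expr.index = peaks.index
    return PeakTable(peaks=peaks, expression=expr)


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    out = table.peaks.reset_index()[["chrom", "start", "end", "peak_id", "strand", "rep_pos"]]
    out = pd.concat([out, table.expression.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative abundances with a declared unit."""

    values: pd.DataFrame  # index: gene_id, columns: sample_id
    unit: str  # "TPM" | "FPKM"
    dataset_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in ("TPM", "FPKM"):
            raise ValueError(f"unit must be TPM or FPKM, got {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if not self.values.index.is_unique:
            raise ValueError("gene_ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample_ids must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], self.unit, self.dataset_label, dict(self.meta))


def read_expression_matrix(
    path: str | Path, unit: str, dataset_label: str = ""
) -> ExpressionMatrix:
    """Read a TSV of gene rows x sample columns into an :class:`ExpressionMatrix`.

    Duplicated gene_ids are collapsed by summation, with the number of collapsed
    rows recorded in ``meta["n_duplicate_genes_collapsed"]`` and warned about.
    Non-numeric cells are an error (never silently coerced to zero).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            gene = df.index[np.where(vals.isna())[0][0]]
            raise ValueError(f"{path}: non-numeric or missing value in column {col!r}, gene {gene!r}")
        df[col] = vals
    n_dups = int(df.index.duplicated().sum())
    if n_dups:
        warnings.warn(f"{path}: {n_dups} duplicated gene row(s) collapsed by sum")
        df = df.groupby(level=0, sort=False).sum()
    return ExpressionMatrix(df, unit=unit, dataset_label=dataset_label, meta={"n_duplicate_genes_collapsed": n_dups})


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class SampleSheet:
    """Maps samples to tissues, dataset labels and replicate indices."""

    samples: pd.DataFrame  # index: sample_id; columns: tissue, dataset_label, replicate_index

    def __post_init__(self) -> None:
        if not self.samples.index.is_unique:
            raise ValueError("sample_ids must be unique")
        required = {"tissue", "dataset_label", "replicate_index"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample sheet missing column(s): {sorted(missing)}")

    def tissue_of(self, sample_id: str) -> str:
        return str(self.samples.loc[sample_id, "tissue"])

    def for_dataset(self, dataset_label: str) -> "SampleSheet":
        return SampleSheet(self.samples[self.samples["dataset_label"] == dataset_label].copy())

    def tissue_map(self) -> dict[str, list[str]]:
        """tissue -> ordered list of its sample_ids."""
        out: dict[str, list[str]] = {}
        for sid, row in self.samples.iterrows():
            out.setdefault(str(row["tissue"]), []).append(str(sid))
        return out

    @property
    def tissues(self) -> list[str]:
        return sorted(self.samples["tissue"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str, "dataset_label": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: sample sheet must have a sample_id column")
    return SampleSheet(df.set_index("sample_id"))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.samples.to_csv(path, sep="\t", index_label="sample_id")


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report_tables(results: Mapping[str, object], out_dir: str | Path) -> dict[str, str]:
    """Write result objects deterministically; returns a name -> path manifest.

    DataFrames become TSVs (rows sorted by index), everything else JSON with
    sorted keys, so identical inputs give byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name in sorted(results):
        obj = results[name]
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.tsv"
            obj.sort_index().to_csv(path, sep="\t")
        else:
            path = out_dir / f"{name}.json"
            with open(path, "w") as fh:
                json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
                fh.write("\n")
        manifest[name] = str(path)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
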