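import numpy as np
import pandas as pd
import pytest

from cagecompare.io_formats import ExpressionMatrix, SampleSheet
from cagecompare.synthetic_data import SimulationParams, generate_truth, observe_platforms


@pytest.fixture
def rng():
    return np.random.default_rng(1729)


@pytest.fixture
def tiny_gtf(tmp_path):
    """Two genes on opposite strands, one with two transcripts sharing a 5' end."""
    text = "\n".join(
        [
            'chr1\ttest\tgene\t1000\t2000\t.\t+\t.\tgene_id "gA"; gene_name "ALPHA"; gene_biotype "protein_coding";',
            'chr1\ttest\ttranscript\t1000\t2000\t.\t+\t.\tgene_id "gA"; transcript_id "tA1"; gene_biotype "protein_coding";',
            'chr1\ttest\ttranscript\t1000\t1800\t.\t+\t.\tgene_id "gA"; transcript_id "tA2"; gene_biotype "protein_coding";',
            'chr1\ttest\tgene\t5000\t8000\t.\t-\t.\tgene_id "gB"; gene_name "BETA"; gene_biotype "lincRNA";',
            'chr1\ttest\ttranscript\t5000\t8000\t.\t-\t.\tgene_id "gB"; transcript_id "tB1"; gene_biotype "lincRNA";',
        ]
    )
    path = tmp_path / "tiny.gtf"
    path.write_text(text + "\n")
    return path


def make_matrix(values, genes, samples, unit="TPM", label="A"):
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, float), index=genes, columns=samples),
        unit=unit,
        dataset_label=label,
    )


def make_sheet(sample_tissues, dataset="A"):
    """sample_tissues: list of (sample_id, tissue)."""
    df = pd.DataFrame(
        [(s, t, dataset, i + 1) for i, (s, t) in enumerate(sample_tissues)],
        columns=["sample_id", "tissue", "dataset_label", "replicate_index"],
    ).set_index("sample_id")
    return SampleSheet(df)


@pytest.fixture(scope="session")
def small_bundle():
    """A modest noisy synthetic bundle shared by read-only tests."""
    params = SimulationParams(n_genes=300, seed=11)
    truth = generate_truth(params)
    return truth, observe_platforms(truth, params)


@pytest.fixture(scope="session")
def clean_bundle():
    """Zero-noise, zero-corruption bundle: both platforms equal the truth."""
    params = SimulationParams(
        n_genes=300,
        seed=5,
        noise_sd_a=0.0,
        noise_sd_b=0.0,
        polyA_minus_fraction=0.0,
        multimap_loss_fraction=0.0,
        distal_tss_fraction=0.0,
    )
    truth = generate_truth(params)
    return truth, observe_platforms(truth, params)
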