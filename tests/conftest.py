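"""Shared fixtures: toy annotations and a session-scoped synthetic run."""
from __future__ import annotations

import glob

import pandas as pd
import pytest

from pasflux.annotation_io import Gene, GenomeAnnotation, Transcript
from pasflux.pipeline import PipelineConfig, run
from pasflux.synthetic_data import SimConfig, simulate_dataset

TEST_SEED = 20260924


def make_gene(gene_id, chrom, strand, exon_sets, biotype="protein_coding", cds=None):
    """Build a Gene from per-transcript exon interval lists."""
    transcripts = [
        Transcript(id=f"{gene_id}.t{i}", gene_id=gene_id, chrom=chrom, strand=strand,
                   exons=list(exons), cds=list(cds[i]) if cds else [])
        for i, exons in enumerate(exon_sets)
    ]
    return Gene(id=gene_id, chrom=chrom, strand=strand, biotype=biotype, transcripts=transcripts)


def abundance_long(rows):
    """rows: (transcript_id, sample, tpm) -> long abundance frame."""
    df = pd.DataFrame(rows, columns=["transcript_id", "sample", "tpm"])
    df["est_counts"] = df["tpm"]
    return df


def two_by_two_design():
    return pd.DataFrame({
        "sample_id": ["control_1", "control_2", "mutant_1", "mutant_2"],
        "condition": ["control", "control", "mutant", "mutant"],
        "replicate": [1, 2, 1, 2],
    })


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=TEST_SEED, n_genes=120, n_shifted=24, reads_per_sample=30_000)


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    return simulate_dataset(small_config, str(out))


@pytest.fixture(scope="session")
def small_pipeline(small_dataset, tmp_path_factory):
    paths = small_dataset["paths"]
    out = tmp_path_factory.mktemp("pipeline_out")
    config = PipelineConfig(
        gtf=paths["gtf"], genome=paths["genome"], end_read_beds=paths["reads"],
        abundance=paths["abundance"], design=paths["design"], mirnas=paths["mirnas"],
        seed=TEST_SEED,
    )
    result = run(config, str(out))
    return {"config": config, "out_dir": str(out), "result": result,
            "dataset": small_dataset}


@pytest.fixture(scope="session")
def simple_annotation():
    """Two genes on opposite strands with two transcripts each."""
    plus = make_gene(
        "gplus", "chrT", "+",
        exon_sets=[[(100, 300), (500, 1001)], [(100, 300), (500, 1501)]],
        cds=[[(150, 300), (500, 700)], [(150, 300), (500, 700)]],
    )
    minus = make_gene(
        "gminus", "chrT", "-",
        exon_sets=[[(3000, 3501), (3800, 4000)], [(2500, 3501), (3800, 4000)]],
        cds=[[(3300, 3501), (3800, 3950)], [(3300, 3501), (3800, 3950)]],
    )
    return GenomeAnnotation([plus, minus])
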