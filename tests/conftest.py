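"""Shared fixtures: toy annotations and cached simulated samples."""

from __future__ import annotations

import io

import pytest

from nanofuse.panel import GeneModel, TargetPanel, read_gene_models
from nanofuse.simulate import FusionSpec, SimConfig, simulate_sample


def gtf_line(chrom, feature, start, end, strand, gene_id, transcript_id=None, gene_name=None):
    """1-based inclusive GTF line helper."""
    attrs = f'gene_id "{gene_id}";'
    if gene_name:
        attrs += f' gene_name "{gene_name}";'
    if transcript_id:
        attrs += f' transcript_id "{transcript_id}";'
    return f"{chrom}\ttest\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"


@pytest.fixture
def toy_gtf():
    """Gene G with two transcripts sharing exon [100,200) (0-based half-open)."""
    lines = [
        gtf_line("chr1", "exon", 101, 200, "+", "G", "T1"),
        gtf_line("chr1", "exon", 301, 400, "+", "G", "T1"),
        gtf_line("chr1", "exon", 101, 200, "+", "G", "T2"),
        gtf_line("chr1", "exon", 351, 450, "+", "G", "T2"),
    ]
    return io.StringIO("\n".join(lines) + "\n")


@pytest.fixture
def two_gene_panel():
    """Two disjoint genes on one chromosome, panel = both."""
    genes = [
        GeneModel("A", "A", "chr1", "+", [(1000, 1500), (2000, 2500)]),
        GeneModel("B", "B", "chr1", "+", [(10_000, 10_500)]),
    ]
    return TargetPanel.build(genes, panel_gene_names=None)


@pytest.fixture(scope="session")
def sim_sample(tmp_path_factory):
    """One modest simulated sample with a 20% fusion, reused across tests."""
    cfg = SimConfig(
        seed=11,
        n_genes=8,
        n_reads=2000,
        panel_gene_names=("ABL1", "JAK2", "CRLF2", "EPOR"),
        fusion_specs=[FusionSpec("ABL1", 2, "G1", 2, 0.2)],
    )
    outdir = tmp_path_factory.mktemp("sim_sample")
    result = simulate_sample(cfg, outdir=outdir)
    genes = read_gene_models(result.paths["gtf"])
    return cfg, result, genes
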