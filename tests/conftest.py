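"""Shared fixtures: packaged gene, synthetic reference, simulated cohort.

Everything is generated programmatically from fixed seeds; the expensive
default-scale cohort simulation is built once per session.
"""

from __future__ import annotations

import pytest

import splicescreen as ss
from splicescreen.gene_model import GeneModel, TranscriptModel
from splicescreen.intervals import GenomicInterval


@pytest.fixture(scope="session")
def agdsx() -> GeneModel:
    return ss.load_packaged_gene()


@pytest.fixture(scope="session")
def agdsx_cds():
    return ss.load_packaged_cds()


@pytest.fixture(scope="session")
def sim_config() -> ss.SimulationConfig:
    return ss.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def synthetic_reference(sim_config):
    return ss.make_reference(sim_config)


@pytest.fixture(scope="session")
def agdsx_sites(agdsx, synthetic_reference, agdsx_cds):
    return ss.sites_for_gene(agdsx, synthetic_reference, agdsx_cds)


@pytest.fixture(scope="session")
def cohort_fixture(sim_config, synthetic_reference, tmp_path_factory):
    """Default-scale simulated cohort, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("cohort")
    return ss.make_cohort_vcf(sim_config, synthetic_reference, outdir)


@pytest.fixture(scope="session")
def cohort_table(cohort_fixture):
    return cohort_fixture.table


def make_toy_gene(strand: str = "+") -> GeneModel:
    """Three-exon plus-strand toy gene with one skipping isoform."""
    chrom = "toy"
    if strand == "+":
        exons_a = [
            GenomicInterval(chrom, 101, 200, "+"),
            GenomicInterval(chrom, 301, 400, "+"),
            GenomicInterval(chrom, 501, 600, "+"),
        ]
        exons_b = [exons_a[0], exons_a[2]]
    else:
        exons_a = [
            GenomicInterval(chrom, 501, 600, "-"),
            GenomicInterval(chrom, 301, 400, "-"),
            GenomicInterval(chrom, 101, 200, "-"),
        ]
        exons_b = [exons_a[0], exons_a[2]]
    span = GenomicInterval(chrom, 1, 700, strand)
    return GeneModel(
        gene_id="toy",
        span=span,
        transcripts=(
            TranscriptModel(id="iso_all", exons=tuple(exons_a)),
            TranscriptModel(id="iso_skip", exons=tuple(exons_b)),
        ),
    )


@pytest.fixture
def toy_gene() -> GeneModel:
    return make_toy_gene("+")
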