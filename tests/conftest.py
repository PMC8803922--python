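import numpy as np
import pandas as pd
import pytest

from spliceburden.types import GeneModel, GenomicInterval, TranscriptModel
from spliceburden.synthetic import CohortConfig, simulate_cohort


def make_tx(tid, exons, strand="+", gene="G1", chrom="chr1", cds=None):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        cds=None if cds is None else GenomicInterval(chrom, cds[0], cds[1], strand),
    )


def make_gene(transcripts, gene="G1"):
    return GeneModel(gene, transcripts)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        seed=11, n_tumor=20, n_normal=10, n_genes=60, n_events=120,
        n_driver_genes=20, pathway_size=15,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_cohort(small_config)


@pytest.fixture
def cassette_gene():
    """Two-isoform gene differing only by one internal cassette exon."""
    t1 = make_tx("t1", [(100, 200), (300, 400), (500, 600)])
    t2 = make_tx("t2", [(100, 200), (500, 600)])
    return make_gene([t1, t2])


def beta_binomial_counts(rng, depth, psi, rho, size):
    """Independent overdispersed (inc, skip) draws used by simulation tests."""
    depths = rng.poisson(depth, size=size)
    if rho > 0:
        scale = (1 - rho) / rho
        p = rng.beta(psi * scale, (1 - psi) * scale, size=size)
    else:
        p = np.full(size, psi)
    inc = rng.binomial(depths, p)
    return inc, depths - inc
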