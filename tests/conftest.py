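import numpy as np
import pytest

from psicoupling import (
    SimScenario,
    apply_variability_filters,
    classify_events,
    compute_psi,
    simulate_dataset,
)
from psicoupling.gene_models import GeneModel, TranscriptModel


def make_gene(gene_id, strand, tx_exons, chrom="chr1", biotypes=None):
    """Helper: gene from {transcript_id: [(start, end), ...]}."""
    transcripts = tuple(
        TranscriptModel(
            transcript_id=tid,
            biotype=(biotypes or {}).get(tid, "protein_coding"),
            exons=tuple(exons),
        )
        for tid, exons in tx_exons.items()
    )
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, transcripts=transcripts
    )


A, B, C, D, E = (100, 200), (300, 400), (500, 600), (700, 800), (900, 1000)


@pytest.fixture
def simple_gene():
    """A-B-C vs A-C: one cassette exon B."""
    return make_gene("g1", "+", {"t1": [A, B, C], "t2": [A, C]})


@pytest.fixture
def collapse_gene():
    """A-B-C-D-E vs A-C-E: exons B and D are perfectly correlated."""
    return make_gene("g2", "+", {"t1": [A, B, C, D, E], "t2": [A, C, E]})


@pytest.fixture(scope="session")
def small_sim():
    """A small planted dataset shared by unit tests (fast to build)."""
    scn = SimScenario(
        n_uhp=15, n_dhp=15, n_type0=30, n_samples_per_tissue=60, n_donors=6,
        seed=11,
    )
    return simulate_dataset(scn)


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    """psi table, filter report and classifications for the small dataset."""
    table = compute_psi(small_sim.events, small_sim.abundance)
    filters = apply_variability_filters(table, small_sim.metadata)
    cls = classify_events(table, filters, small_sim.metadata)
    return table, filters, cls


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
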