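"""Shared fixtures: hand-built genomes and a small reusable simulation."""

import numpy as np
import pytest

from crispri_screen.genome import GeneAnnotation, GenomeRecord
from crispri_screen.simulate import SimulationConfig, simulate_screen


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_sim():
    """A reduced synthetic screen shared by read-only tests."""
    cfg = SimulationConfig(
        genome_length=20_000, n_genes=12, library_size=2500,
        n_bad_seeds=8, guides_per_bad_seed=30, n_offtarget_guides=30,
        rng_seed=5,
    )
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def small_fitness(small_sim):
    from crispri_screen.foldchange import compute_log2fc

    return compute_log2fc(small_sim.counts)


@pytest.fixture
def three_gene_genome():
    """A 600-nt genome with three annotated genes and one promoter.

    geneA [100,220) on '+', promoter [60,100); geneB [300,420) on '-';
    geneC [450,560) on '+'.  Sequence is deterministic pseudo-random.
    """
    r = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in r.integers(0, 4, size=600))
    genome = GenomeRecord("toy3", seq)
    anns = [
        GeneAnnotation("geneA", 100, 220, "+", "essential", "opA", promoter=(60, 100)),
        GeneAnnotation("geneB", 300, 420, "-", "neutral", "opB", promoter=(420, 460)),
        GeneAnnotation("geneC", 450, 560, "+", "fitness", "opC"),
    ]
    return genome, anns


def random_genome(rng, length, circular=False, gc_id="rand"):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    return GenomeRecord(gc_id, seq, circular=circular)


@pytest.fixture
def make_random_genome():
    return random_genome
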