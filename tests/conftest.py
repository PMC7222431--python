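import numpy as np
import pytest

from rrident.align import AlignParams
from rrident.benchmark import DEFAULT_BARCODE, DEFAULT_REVERSE_ADAPTER
from rrident.digest import ENZYMES, SimulationConfig, double_digest, select_amplifiable, simulate_reads, synth_genome
from rrident.readprep import demultiplex, prep_reads

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, length))


def simulate_assay(genome, seed=0, error_rate=0.0, replicates=6, window=(30, 300)):
    """Digest -> simulate -> demultiplex -> prep; returns collapsed tags.

    Built from the pipeline stages directly (not the packaged helper) so a
    defect in any single stage surfaces here.
    """
    frags = select_amplifiable(double_digest(genome, ENZYMES["PstI"], ENZYMES["HpaII"]), window)
    cfg = SimulationConfig(seed=seed, error_rate=error_rate, replicates=replicates, size_window=window)
    reads = simulate_reads(frags, cfg, DEFAULT_BARCODE, DEFAULT_REVERSE_ADAPTER)
    sample = demultiplex(reads, {DEFAULT_BARCODE: "s"})["s"]
    return prep_reads(sample, DEFAULT_REVERSE_ADAPTER)


@pytest.fixture(scope="session")
def genome_50kb():
    return synth_genome(50_000, seed=11, genome_id="g50k")


@pytest.fixture(scope="session")
def genome_100kb():
    return synth_genome(100_000, seed=17, genome_id="g100k")


@pytest.fixture
def permissive_params():
    """Thresholds relaxed so raw alignment behaviour is observable."""
    return AlignParams(word_size=8, min_bitscore=0.0, max_evalue=1e9, min_percent_identity=0.0, min_query_cover=0.0)
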