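"""Control-assay benchmark on a real genome.

The reference control for this assay design is the E. coli O157 (EDL 933)
genome, GenBank CP008957.1 / AE005174.2, 5,639,399 bp: in-silico PstI+HpaII
and PstI+MseI assays sequenced as 69 bp tags and aligned back to the same
genome are expected to yield on the order of 2,433 and 1,836 amplifiable
fragments and ~2.64% / ~2.34% genome coverage respectively (sensitive to
the size-selection window, which is a configuration choice here). The
genome is not bundled — supply a locally downloaded FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import AlignParams, align
from .digest import ENZYMES, Genome, SimulationConfig, double_digest, read_fasta, select_amplifiable, simulate_reads
from .identify import best_hit_per_query, genome_coverage
from .readprep import demultiplex, prep_reads

DEFAULT_BARCODE = "ACGTACGT"
DEFAULT_REVERSE_ADAPTER = "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAG"  # Illumina-style


def assay_tags(genome: Genome, seed: int = 0, error_rate: float = 0.0, replicates: int = 6,
               size_window: tuple[int, int] = (30, 300), secondary_enzyme: str = "HpaII"):
    """Run the wet-lab half of the assay in silico and return collapsed tags:
    digest, size-select, simulate reads, demultiplex, prepare."""
    frags = select_amplifiable(
        double_digest(genome, ENZYMES["PstI"], ENZYMES[secondary_enzyme]), size_window
    )
    cfg = SimulationConfig(seed=seed, error_rate=error_rate, replicates=replicates, size_window=size_window)
    reads = simulate_reads(frags, cfg, DEFAULT_BARCODE, DEFAULT_REVERSE_ADAPTER)
    sample = demultiplex(reads, {DEFAULT_BARCODE: "s"})["s"]
    return prep_reads(sample, DEFAULT_REVERSE_ADAPTER)


@dataclass(frozen=True)
class ControlAssayResult:
    enzyme_pair: tuple[str, str]
    n_fragments: int
    n_tags: int
    coverage_percent: float
    mean_percent_identity: float


def control_assay(
    genome: Genome,
    secondary_enzyme: str = "HpaII",
    size_window: tuple[int, int] = (30, 300),
    replicates: int = 6,
    seed: int = 0,
    error_rate: float = 0.0,
) -> ControlAssayResult:
    """Run one in-silico control assay: digest, simulate, prep, self-align.

    Returns the amplifiable fragment count, collapsed tag count, genome
    coverage of the tag alignments and their length-weighted mean percent
    identity against the source genome itself.
    """
    config = SimulationConfig(
        replicates=replicates, seed=seed, error_rate=error_rate, size_window=size_window
    )
    frags = select_amplifiable(
        double_digest(genome, ENZYMES["PstI"], ENZYMES[secondary_enzyme]), size_window
    )
    reads = simulate_reads(frags, config, DEFAULT_BARCODE, DEFAULT_REVERSE_ADAPTER)
    demuxed = demultiplex(reads, {DEFAULT_BARCODE: "control"})["control"]
    tags = prep_reads(demuxed, DEFAULT_REVERSE_ADAPTER)
    hits = best_hit_per_query(align(tags, genome, AlignParams()))
    total = sum(h.align_length for h in hits)
    mean_ident = sum(h.percent_identity * h.align_length for h in hits) / total if total else 0.0
    return ControlAssayResult(
        ("PstI", secondary_enzyme), len(frags), len(tags), genome_coverage(hits, len(genome)), mean_ident
    )


RECOVERY_RATES = (0.001, 0.005, 0.01, 0.02)


def recover_nsd(
    substitution_rate: float,
    seed: int = 0,
    n_genomes: int = 6,
    genome_length: int = 100_000,
) -> float:
    """Recover the NSD between a mutated isolate and its reference by
    running the full assay in silico.

    ``n_genomes`` independent synthetic references are each mutated at the
    given substitution rate; error-free assays are simulated from the
    mutants, prepared, and aligned back to the unmutated references; the
    NSD components are pooled before the distance transform. Pooling keeps
    the substitution count large enough for a stable estimate even at the
    lowest rate.
    """
    from .identify import NSDComponents, aggregate_components, compute_nsd
    from .digest import mutate_genome, synth_genome

    I = S = G = T = 0
    for k in range(n_genomes):
        base = seed + 100 * k
        ref = synth_genome(genome_length, seed=base, genome_id=f"ref{k}")
        mut, _ = mutate_genome(ref, substitution_rate, seed=base + 1)
        tags = assay_tags(mut, seed=base + 2)
        c = aggregate_components(align(tags, ref, AlignParams()))
        I, S, G, T = I + c.I, S + c.S, G + c.G, T + c.T
    return compute_nsd(NSDComponents(I, S, G, T))


def jukes_cantor(rate: float) -> float:
    """JC-corrected distance for a per-site substitution probability."""
    import math

    return -0.75 * math.log(1.0 - (4.0 / 3.0) * rate)


def parameter_recovery(seed: int = 0, rates: tuple[float, ...] = RECOVERY_RATES) -> dict:
    """Recovered-vs-true NSD across substitution rates.

    Each rate uses its own block of genome seeds (decorrelated arms) so the
    median ratio summarises independent experiments.
    """
    per_rate = {}
    ratios = []
    for ri, rate in enumerate(rates):
        nsd = recover_nsd(rate, seed=seed + 10_000 * ri)
        true = jukes_cantor(rate)
        per_rate[rate] = {"recovered_nsd": nsd, "true_nsd": true, "ratio": nsd / true}
        ratios.append(nsd / true)
    ratios.sort()
    n = len(ratios)
    median = (ratios[n // 2 - 1] + ratios[n // 2]) / 2 if n % 2 == 0 else ratios[n // 2]
    return {"per_rate": per_rate, "median_ratio": median}


def control_benchmark(genome_fasta: str, seed: int = 0) -> dict[str, ControlAssayResult]:
    """Both enzyme combinations on a genome FASTA (e.g. CP008957.1)."""
    genome = read_fasta(genome_fasta, topology="circular")[0]
    return {
        "PstI+HpaII": control_assay(genome, "HpaII", seed=seed),
        "PstI+MseI": control_assay(genome, "MseI", seed=seed),
    }
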