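"""In-silico restriction double digest and short-read assay simulation.

Models a DArTseq-style complexity-reduction assay: a genome is cut with a
pair of restriction enzymes, fragments carrying a *different* enzyme's site
at each end (the only class that receives both adapters and can form
sequencing clusters) are size-selected, and single-end reads of a fixed
cycle count are generated from the primary-enzyme end of each fragment.
Reads from fragments shorter than the usable cycle count run through into
the reverse adapter, exactly as on the instrument.

The same module provides the synthetic-genome generator used throughout the
test suite, so every downstream stage can be exercised without any external
sequence download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .readprep import ReadRecord

__all__ = [
    "RestrictionEnzyme",
    "Genome",
    "Fragment",
    "SimulationConfig",
    "ENZYMES",
    "GENOME_END",
    "find_sites",
    "double_digest",
    "select_amplifiable",
    "simulate_reads",
    "synth_genome",
    "mutate_genome",
    "read_fasta",
    "fragment_table",
]

log = logging.getLogger(__name__)

#: Sentinel end label for terminal fragments of a linear molecule.
GENOME_END = "genome_end"

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type II restriction enzyme with a palindromic recognition site.

    ``cut_offset`` is the 0-based position of top-strand cleavage within the
    recognition site: PstI CTGCA^G cuts after the fifth base (offset 5),
    HpaII C^CGG and MseI T^TAA after the first (offset 1).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition or set(self.recognition) - set(_BASES):
            raise ValueError(f"recognition site must be non-empty A/C/G/T: {self.recognition!r}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"cut_offset {self.cut_offset} outside recognition site")


#: The enzymes used by the assay this package models.
ENZYMES: dict[str, RestrictionEnzyme] = {
    "PstI": RestrictionEnzyme("PstI", "CTGCAG", 5),
    "HpaII": RestrictionEnzyme("HpaII", "CCGG", 1),
    "MseI": RestrictionEnzyme("MseI", "TTAA", 1),
}


@dataclass(frozen=True)
class Genome:
    """A replicon: one FASTA record, linear or circular."""

    id: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment in 0-based half-open genome coordinates.

    For a circular genome the origin-spanning fragment has ``wraps=True``
    and ``end > len(genome)``; ``end - start == len(sequence)`` always holds
    on the concatenated sequence.
    """

    genome_id: str
    start: int
    end: int
    left_enzyme: str
    right_enzyme: str
    sequence: str
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("fragment coordinates do not match sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the short-read simulation.

    Defaults mirror the assay being modeled: 77 sequencing cycles, six
    technical replicates per enzyme combination, and a 30-300 bp
    size-selection window for amplifiable fragments.
    """

    read_cycles: int = 77
    barcode_length: int = 8
    error_rate: float = 0.0
    replicates: int = 6
    size_window: tuple[int, int] = (30, 300)
    mean_phred: float = 33.0
    seed: int = 0
    read_from: str = "PstI"  # enzyme end the read starts at

    def __post_init__(self) -> None:
        if self.read_cycles <= self.barcode_length:
            raise ValueError("read_cycles must exceed barcode_length")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error rate must be in [0, 1)")
        if self.size_window[0] < 1 or self.size_window[0] > self.size_window[1]:
            raise ValueError(f"invalid size window {self.size_window}")


def find_sites(genome: Genome, enzyme: RestrictionEnzyme) -> list[int]:
    """Top-strand cut positions of ``enzyme`` on ``genome``, sorted ascending.

    All in-scope enzymes are palindromic, so a single-strand scan finds every
    cleavage. Ambiguity codes (N etc.) never match and therefore terminate a
    site. On circular genomes sites may span the origin; cut positions are
    reported mod genome length.
    """
    seq = genome.sequence.upper()
    recog = enzyme.recognition
    n = len(seq)
    if genome.topology == "circular" and n >= len(recog):
        scan = seq + seq[: len(recog) - 1]
    else:
        scan = seq
    cuts = set()
    pos = scan.find(recog)
    while pos != -1:
        cuts.add((pos + enzyme.cut_offset) % n if genome.topology == "circular" else pos + enzyme.cut_offset)
        pos = scan.find(recog, pos + 1)
    return sorted(cuts)


def double_digest(genome: Genome, enzA: RestrictionEnzyme, enzB: RestrictionEnzyme) -> list[Fragment]:
    """Digest ``genome`` with both enzymes and return the fragment tiling.

    Fragment ends are labeled with the enzyme that produced each cut;
    terminal fragments of a linear genome carry the :data:`GENOME_END`
    sentinel. The fragments tile the genome: their lengths sum to the
    genome length.
    """
    if enzA.name == enzB.name:
        raise ValueError("double digest requires two distinct enzymes")
    seq = genome.sequence.upper()
    n = len(seq)
    cuts: dict[int, str] = {}
    for enz in (enzA, enzB):
        for pos in find_sites(genome, enz):
            if pos in cuts:
                raise ValueError(f"enzymes {cuts[pos]} and {enz.name} cut at the same position {pos}")
            cuts[pos] = enz.name
    positions = sorted(cuts)

    frags: list[Fragment] = []
    if genome.topology == "linear":
        bounds = [(0, GENOME_END)] + [(p, cuts[p]) for p in positions] + [(n, GENOME_END)]
        for (s, left), (e, right) in zip(bounds, bounds[1:]):
            if e > s:
                frags.append(Fragment(genome.id, s, e, left, right, seq[s:e]))
    else:
        if not positions:
            return [Fragment(genome.id, 0, n, GENOME_END, GENOME_END, seq)]
        for i, s in enumerate(positions):
            if i + 1 < len(positions):
                e = positions[i + 1]
                frags.append(Fragment(genome.id, s, e, cuts[s], cuts[e], seq[s:e]))
            else:
                e = positions[0] + n  # origin-spanning fragment
                frags.append(
                    Fragment(genome.id, s, e, cuts[s], cuts[positions[0]], seq[s:] + seq[: positions[0]], wraps=True)
                )
    return frags


def select_amplifiable(fragments: list[Fragment], size_window: tuple[int, int] = (30, 300)) -> list[Fragment]:
    """Fragments able to form clusters: a different enzyme at each end.

    Asymmetric adapters mean only fragments whose two ends were cut by
    *different* enzymes receive a forward and a reverse adapter. Terminal
    (genome-end) fragments have no ligatable end and are dropped, as is
    anything outside the size-selection window. Input order is preserved.
    """
    lo, hi = size_window
    return [
        f
        for f in fragments
        if f.left_enzyme != f.right_enzyme
        and GENOME_END not in (f.left_enzyme, f.right_enzyme)
        and lo <= len(f) <= hi
    ]


def _synthesize_quality(rng: np.random.Generator, length: int, mean_phred: float) -> list[int]:
    q = np.rint(rng.normal(mean_phred, 2.0, size=length)).astype(int)
    return list(np.clip(q, 2, 41))


def simulate_reads(
    fragments: list[Fragment],
    config: SimulationConfig,
    barcode: str,
    reverse_adapter: str,
) -> list[ReadRecord]:
    """Simulate single-end reads from amplifiable fragments.

    Each read is ``barcode + fragment`` sequenced from the primary-enzyme
    end for ``read_cycles`` total cycles. Fragments shorter than the usable
    read length run through into ``reverse_adapter`` (the basis of the
    downstream adapter-trimming step). Substitution errors are applied i.i.d.
    at ``config.error_rate``; replicate ``r`` uses seed ``config.seed + r``
    so the whole simulation is reproducible from one integer.
    """
    if len(barcode) != config.barcode_length:
        raise ValueError(f"barcode length {len(barcode)} != configured {config.barcode_length}")
    if not fragments:
        log.warning("simulate_reads called with an empty fragment list")
        return []

    usable = config.read_cycles - config.barcode_length
    reads: list[ReadRecord] = []
    for r in range(config.replicates):
        rng = np.random.default_rng(config.seed + r)
        for frag in fragments:
            if frag.left_enzyme == config.read_from:
                template = frag.sequence
            elif frag.right_enzyme == config.read_from:
                template = revcomp(frag.sequence)
            else:
                continue  # no primary-enzyme end: not sequenced from this assay
            insert = template[:usable]
            if len(insert) < usable:
                insert += reverse_adapter[: usable - len(insert)]
            read_seq = (barcode + insert)[: config.read_cycles]
            if config.error_rate > 0.0:
                read_seq = _apply_substitutions(read_seq, config.error_rate, rng)
            qual = _synthesize_quality(rng, len(read_seq), config.mean_phred)
            rid = f"{frag.genome_id}|{frag.start}-{frag.end}|{frag.left_enzyme}-{frag.right_enzyme}|rep{r}"
            reads.append(ReadRecord(rid, read_seq, qual))
    return reads


def _apply_substitutions(sequence: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    out = list(sequence)
    for i in hit:
        base = out[i]
        if base not in _BASES:
            continue
        choices = [b for b in _BASES if b != base]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def synth_genome(length: int, gc_fraction: float = 0.5, seed: int = 0, *, topology: str = "circular", genome_id: str | None = None) -> Genome:
    """Random i.i.d. genome with the given GC fraction, reproducible by seed."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    seq = "".join(rng.choice(list(_BASES), size=length, p=p))
    return Genome(genome_id or f"synth_{length}bp_seed{seed}", seq, topology)


def mutate_genome(genome: Genome, substitution_rate: float, seed: int = 0) -> tuple[Genome, int]:
    """Apply i.i.d. substitutions (uniform over the 3 alternative bases).

    Returns the mutated genome and the realized substitution count; there is
    no indel model, so coordinates are preserved.
    """
    if not 0.0 <= substitution_rate < 1.0:
        raise ValueError("substitution rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = list(genome.sequence)
    hit = np.nonzero(rng.random(len(out)) < substitution_rate)[0]
    n_sub = 0
    for i in hit:
        base = out[i]
        if base not in _BASES:
            continue
        choices = [b for b in _BASES if b != base]
        out[i] = choices[rng.integers(3)]
        n_sub += 1
    return replace(genome, id=f"{genome.id}|mut{substitution_rate}", sequence="".join(out)), n_sub


def read_fasta(path, topology: str = "circular") -> list[Genome]:
    """Load every record of a (multi-)FASTA as a separate replicon."""
    genomes = [Genome(rec.id, str(rec.seq).upper(), topology) for rec in SeqIO.parse(str(path), "fasta")]
    if not genomes:
        raise ValueError(f"no FASTA records in {path}")
    return genomes


def write_fasta(genomes: list[Genome], path) -> None:
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes], str(path), "fasta")


def fragment_table(fragments: list[Fragment]):
    """Fragments as a DataFrame (genome_id, start, end, ends, length)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "genome_id": f.genome_id,
                "start": f.start,
                "end": f.end,
                "left_enzyme": f.left_enzyme,
                "right_enzyme": f.right_enzyme,
                "length": len(f),
            }
            for f in fragments
        ],
        columns=["genome_id", "start", "end", "left_enzyme", "right_enzyme", "length"],
    )
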