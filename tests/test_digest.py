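"""Restriction digest simulation: site finding, fragment tiling,
amplifiable-fragment selection and read simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna
from rrident.benchmark import DEFAULT_BARCODE, DEFAULT_REVERSE_ADAPTER
from rrident.digest import (
    ENZYMES,
    GENOME_END,
    Fragment,
    Genome,
    RestrictionEnzyme,
    SimulationConfig,
    double_digest,
    find_sites,
    mutate_genome,
    revcomp,
    select_amplifiable,
    simulate_reads,
    synth_genome,
)

PstI, HpaII, MseI = ENZYMES["PstI"], ENZYMES["HpaII"], ENZYMES["MseI"]

dna = st.text(alphabet="ACGT", min_size=1, max_size=3000)


def brute_force_cuts(seq: str, enzyme: RestrictionEnzyme, topology: str) -> list[int]:
    """Independent site scan: check every rotation/window explicitly."""
    n, k = len(seq), len(enzyme.recognition)
    cuts = set()
    if topology == "circular":
        doubled = seq + seq
        for i in range(n):
            if doubled[i : i + k] == enzyme.recognition:
                cuts.add((i + enzyme.cut_offset) % n)
    else:
        for i in range(n - k + 1):
            if seq[i : i + k] == enzyme.recognition:
                cuts.add(i + enzyme.cut_offset)
    return sorted(cuts)


class TestFindSites:
    def test_no_sites(self):
        assert find_sites(Genome("g", "AAAAAAA", "linear"), PstI) == []

    def test_single_pst_site(self):
        # site begins at index 2; top-strand cleavage CTGCA^G -> cut at 7
        assert find_sites(Genome("g", "AACTGCAGTT", "linear"), PstI) == [7]

    def test_tandem_hpa_sites(self):
        assert find_sites(Genome("g", "CCGGCCGG", "linear"), HpaII) == [1, 5]

    def test_circular_wraparound_site(self):
        # site spans the origin: GG...CC -> CCGG when wrapped
        g = Genome("g", "GGAAAAAAAACC", "circular")
        assert find_sites(g, HpaII) == [11]

    def test_ambiguity_codes_never_match(self):
        assert find_sites(Genome("g", "CTGCNG" * 3, "linear"), PstI) == []

    @settings(max_examples=150, derandomize=True)
    @given(seq=dna, enzyme=st.sampled_from(["PstI", "HpaII", "MseI"]), topology=st.sampled_from(["linear", "circular"]))
    def test_agrees_with_brute_force(self, seq, enzyme, topology):
        enz = ENZYMES[enzyme]
        assert find_sites(Genome("g", seq, topology), enz) == brute_force_cuts(seq, enz, topology)


class TestDoubleDigest:
    def test_no_sites_single_fragment(self):
        g = Genome("g", "ATATATAT", "linear")
        frags = double_digest(g, PstI, HpaII)
        assert len(frags) == 1
        assert (frags[0].left_enzyme, frags[0].right_enzyme) == (GENOME_END, GENOME_END)
        assert frags[0].sequence == g.sequence

    def test_linear_two_cuts(self):
        # PstI cut at 7 (site at 2), HpaII site at 10 -> cut at 11
        g = Genome("g", "AACTGCAGTTCCGGAA", "linear")
        frags = double_digest(g, PstI, HpaII)
        coords = [(f.start, f.end, f.left_enzyme, f.right_enzyme) for f in frags]
        assert coords == [
            (0, 7, GENOME_END, "PstI"),
            (7, 11, "PstI", "HpaII"),
            (11, 16, "HpaII", GENOME_END),
        ]

    def test_circular_one_site_each(self):
        g = Genome("g", "CTGCAG" + "A" * 20 + "CCGG" + "T" * 20, "circular")
        frags = double_digest(g, PstI, HpaII)
        assert len(frags) == 2
        for f in frags:
            assert {f.left_enzyme, f.right_enzyme} == {"PstI", "HpaII"}
        assert any(f.wraps for f in frags)

    def test_rejects_identical_enzymes(self):
        with pytest.raises(ValueError):
            double_digest(Genome("g", "ACGT"), PstI, PstI)

    @settings(max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 10_000), topology=st.sampled_from(["linear", "circular"]))
    def test_tiling_conservation(self, seed, topology):
        g = synth_genome(4000, seed=seed, topology=topology)
        frags = double_digest(g, PstI, HpaII)
        assert sum(len(f) for f in frags) == len(g)
        if topology == "circular":
            n_cuts = len(find_sites(g, PstI)) + len(find_sites(g, HpaII))
            assert len(frags) == max(n_cuts, 1)
        # fragments tile: consecutive, no gaps
        for a, b in zip(frags, frags[1:]):
            assert b.start == a.end % len(g) or b.start == a.end


class TestSelectAmplifiable:
    def _frag(self, left, right, length):
        return Fragment("g", 0, length, left, right, "A" * length)

    def test_same_enzyme_ends_excluded(self):
        assert select_amplifiable([self._frag("PstI", "PstI", 100)]) == []

    def test_mixed_ends_in_window_retained(self):
        f = self._frag("PstI", "HpaII", 100)
        assert select_amplifiable([f]) == [f]

    def test_size_selection(self):
        assert select_amplifiable([self._frag("PstI", "HpaII", 10)]) == []
        assert select_amplifiable([self._frag("PstI", "HpaII", 500)]) == []

    def test_genome_end_excluded(self):
        assert select_amplifiable([self._frag(GENOME_END, "HpaII", 100)]) == []

    def test_every_output_has_one_end_from_each_enzyme(self, genome_50kb):
        for f in select_amplifiable(double_digest(genome_50kb, PstI, HpaII)):
            assert {f.left_enzyme, f.right_enzyme} == {"PstI", "HpaII"}


class TestSimulateReads:
    cfg = SimulationConfig(seed=3, replicates=1)

    def _one_fragment(self, length, left="PstI", right="HpaII", seed=9):
        rng = np.random.default_rng(seed)
        return Fragment("g", 0, length, left, right, random_dna(rng, length))

    def test_long_fragment_read_is_fragment_prefix(self):
        frag = self._one_fragment(120)
        (read,) = simulate_reads([frag], self.cfg, DEFAULT_BARCODE, DEFAULT_REVERSE_ADAPTER)
        assert len(read.sequence) == 77
        assert read.sequence == DEFAULT_BARCODE + frag.sequence[:69]

    def test_short_fragment_reads_through_into_adapter(self):
        frag = self._one_fragment(40)
        (read,) = simulate_reads([frag], self.cfg, DEFAULT_BARCODE, DEFAULT_REVERSE_ADAPTER)
        assert read.sequence == DEFAULT_BARCODE + frag.sequence + DEFAULT_REVERSE_ADAPTER[:29]

    def test_reads_start_from_primary_enzyme_end(self):
        frag = self._one_fragment(120, left="HpaII", right="PstI")
        (read,) = simulate_reads([frag], self.cfg, DEFAULT_BARCODE, DEFAULT_REVERSE_ADAPTER)
        assert read.sequence == DEFAULT_BARCODE + revcomp(frag.sequence)[:69]

    def test_fixed_seed_is_deterministic(self):
        frags = [self._one_fragment(60, seed=s) for s in range(5)]
        cfg = SimulationConfig(seed=7, replicates=3, error_rate=0.01)
        a = simulate_reads(frags, cfg, DEFAULT_BARCODE, DEFAULT_REVERSE_ADAPTER)
        b = simulate_reads(frags, cfg, DEFAULT_BARCODE, DEFAULT_REVERSE_ADAPTER)
        assert a == b

    def test_empty_fragment_list(self):
        assert simulate_reads([], self.cfg, DEFAULT_BARCODE, DEFAULT_REVERSE_ADAPTER) == []

    def test_replicates_multiply_reads(self):
        frags = [self._one_fragment(60)]
        cfg = SimulationConfig(seed=1, replicates=6)
        assert len(simulate_reads(frags, cfg, DEFAULT_BARCODE, DEFAULT_REVERSE_ADAPTER)) == 6

    def test_error_free_reads_match_source(self, genome_50kb):
        frags = select_amplifiable(double_digest(genome_50kb, PstI, HpaII))
        reads = simulate_reads(frags, SimulationConfig(seed=1, replicates=1), DEFAULT_BARCODE, DEFAULT_REVERSE_ADAPTER)
        doubled = genome_50kb.sequence + genome_50kb.sequence
        rc = revcomp(doubled)
        for read in reads:
            insert = read.sequence[8:]
            # strip any adapter read-through before mapping back
            pos = insert.find(DEFAULT_REVERSE_ADAPTER[:10])
            if pos != -1:
                insert = insert[:pos]
            assert insert in doubled or insert in rc


class TestSyntheticGenomes:
    def test_synth_reproducible(self):
        assert synth_genome(500, seed=5).sequence == synth_genome(500, seed=5).sequence

    def test_gc_fraction_respected(self):
        g = synth_genome(100_000, gc_fraction=0.6, seed=2)
        gc = sum(g.sequence.count(b) for b in "GC") / len(g)
        assert abs(gc - 0.6) < 0.01

    def test_mutate_rate_zero_is_identity(self, genome_50kb):
        mut, n = mutate_genome(genome_50kb, 0.0, seed=1)
        assert n == 0 and mut.sequence == genome_50kb.sequence

    def test_mutation_count_within_binomial_bound(self):
        g = synth_genome(100_000, seed=4)
        _, n = mutate_genome(g, 0.01, seed=5)
        sd = (100_000 * 0.01 * 0.99) ** 0.5
        assert abs(n - 1000) <= 3 * sd

    def test_mutation_count_matches_hamming_distance(self, genome_50kb):
        mut, n = mutate_genome(genome_50kb, 0.02, seed=6)
        hamming = sum(a != b for a, b in zip(genome_50kb.sequence, mut.sequence))
        assert hamming == n


class TestValidation:
    def test_enzyme_invariants(self):
        with pytest.raises(ValueError):
            RestrictionEnzyme("bad", "CTGXAG", 2)
        with pytest.raises(ValueError):
            RestrictionEnzyme("bad", "CTGCAG", 7)

    def test_genome_invariants(self):
        with pytest.raises(ValueError):
            Genome("g", "")
        with pytest.raises(ValueError):
            Genome("g", "ACGT", topology="mobius")

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SimulationConfig(read_cycles=8, barcode_length=8)
        with pytest.raises(ValueError):
            SimulationConfig(error_rate=1.5)
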