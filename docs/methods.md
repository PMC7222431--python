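# Methods

## The assay being modeled

Complexity-reduced genotyping of bacterial isolates: genomic DNA is
digested with two restriction enzymes simultaneously — PstI (CTGCA^G)
paired with either HpaII (C^CGG) or MseI (T^TAA) — and adapters are
ligated such that only fragments with a *different* enzyme's site at each
end receive both the forward and reverse adapter and can form sequencing
clusters. The library is sequenced single-end for 77 cycles; after the
in-line barcode this leaves up to 69 bases of insert. Fragments shorter
than the usable read length are sequenced through into the reverse
adapter, which is later trimmed, so prepared sequence tags fall in the
30–69 bp range.

The simulator reproduces exactly this geometry. Cut offsets are the
standard cleavage chemistry for the three enzymes (PstI after base 5 of
its site, HpaII and MseI after base 1); the enzymes are named in the assay
protocol but cleavage positions are a property of the enzymes themselves.

## Identification model

Tags from one sample are aligned against a panel of candidate genomes
with BLASTn-style thresholds (word size 12, bitscore ≥ 50, e-value ≤
10⁻⁶, percent identity ≥ 80, query cover ≥ 80). Candidates are ranked by
votes: each tag votes for every genome on which it achieves its
panel-wide maximal bitscore (bitscores compared at the tabular precision
of one decimal). The top three candidates are then rescored with the
nucleotide sequence distance

NSD = −(3/4)·ln[1 − (4/3)·S/(I+S)]·(1 − G/T) + G/T

a Jukes–Cantor distance on the substitution fraction, damped by the
gap-opening fraction G/T and with G/T added back as a linear gap term.
I, S, G and T are summed over the retained alignments of the sample
against one genome. The candidate with the smallest NSD is the reported
match; NSD is undefined (saturated) when S/(I+S) ≥ 3/4, and a sample
whose candidates all saturate is reported unidentified.

Aggregation choices the distance definition leaves open, fixed here:

* **T** is summed alignment columns (including gap columns), **I** summed
  identities, **S** summed mismatches, **G** summed gap openings — the
  only aggregation expressible from standard 12-column tabular fields.
* Each tag contributes only its single best alignment on the candidate
  (highest bitscore, ties to the longer alignment). This prevents repeat
  regions from being counted several times. Aggregating all hits instead
  is available as a switch (`per_query_best=False`).
* The logarithm applies to the substitution bracket only; the (1 − G/T)
  factor multiplies the logarithmic term.
* Genome coverage is the union of subject intervals (strand-normalized,
  merged) over the genome length, so overlapping hits are not
  double-counted.

## Built-in aligner

The self-contained backend indexes the word-size k-mers of each query on
both strands, streams the subject once, clusters seed matches into loci,
and runs a full affine-gap Smith–Waterman on a padded window around each
locus (scoring match +1, mismatch −2, gap of length L costs 5 + 2L).
Window padding (32 bp) exceeds the longest gap that can appear in a
positive-scoring alignment of a ≤ 69 bp tag, so the windowed optimum
equals the full-matrix optimum whenever the optimal alignment contains
one exact word-size match — the same seeding assumption BLAST makes. The
test suite checks this equivalence against an independent affine-gap
local aligner (Bio.Align.PairwiseAligner) on hundreds of randomized
planted-homology instances.

Bit scores and e-values use the Karlin–Altschul transformation with
λ = 1.28 and K = 0.46, the published ungapped constants for the +1/−2
scheme (also applied by BLAST at these high gap costs); e-values use the
raw query × subject length product without edge corrections. These
statistics are an approximation to any particular BLASTn build — exact
bit-compatibility is available through the `blastn` backend, which shells
out to NCBI BLAST+ and parses its tabular output. Per subject locus only
the best local alignment is reported; locus resolution runs before
threshold filtering so that tightening any threshold can only remove
hits.

## Synthetic data

`synth_genome` draws i.i.d. bases at a configurable GC fraction (default
0.5) and `mutate_genome` applies i.i.d. substitutions uniform over the
three alternative bases, reporting the realized count. Defaults mirror
the study conditions of the assay: 77 cycles, 6 technical replicates per
enzyme combination, error-free reads unless an error rate is set, size
window 30–300 bp. One integer seed drives every stochastic draw;
replicate r uses seed + r.

What the generator does **not** emulate: PCR amplification bias and
duplicate structure, methylation sensitivity of HpaII, indel sequencing
errors (rare on this platform), quality-score correlation along the read,
and the repeat/compositional structure of real genomes. Passing tests
therefore demonstrate correctness of the pipeline arithmetic and the
statistical behaviour of the estimator under idealized sampling, not
robustness to real library artefacts.

## Parameter recovery protocol

The recovery experiment (`rrident.benchmark.parameter_recovery`) checks
that the pipeline's NSD estimate tracks the true divergence: for each
substitution rate in {0.001, 0.005, 0.01, 0.02}, six independent 100 kb
genomes are mutated at that rate, error-free assays are simulated from
the mutants and aligned back to the unmutated references, and the I/S/G/T
components are pooled before the distance transform. Pooling matters: a
single 100 kb genome yields only ~25–30 amplifiable PstI+HpaII fragments
(~1.5 kb aligned), far too few substitutions at rate 0.001 for a stable
ratio. Each rate uses its own seed block so the four arms are
independent, and the summary statistic is the median across rates of
recovered/true.

The estimator carries a small (< 10%) downward bias that is inherent to
local alignment: a substitution within ~3 bp of an alignment end is
cheaper to clip than to include under the +1/−2 scoring, so terminal
substitutions are systematically excluded from S. Any pipeline built on
local alignments, including the production BLASTn path, shares this
property; the 25% recovery tolerance absorbs it.

## Numerical and degenerate-input choices

* Ambiguity codes (N) never match a recognition site and score as
  mismatches in alignment; k-mers containing N are not seeded.
* A circular genome with no cut sites yields one whole-genome fragment;
  origin-spanning fragments carry a wrap flag and end > genome length so
  that end − start always equals the sequence length.
* Identical cut positions from both enzymes raise an error (impossible
  for the in-scope enzymes, whose sites cannot overlap at the same cut).
* fastQcol files are TSV with header `sequence  count  mean_quality`,
  mean qualities comma-separated at 2 decimals; counts below 1 are a
  parse error. Reads longer than 69 bp with no adapter found are
  truncated to 69 bp.
* Demultiplexing requires a mutually prefix-free barcode set and matches
  exactly; unmatched reads go to an `undetermined` bin.
* The PHRED filter threshold (mean read quality ≥ 25) and the
  adapter-trim seed (first 10 adapter bases, exact match) are
  configuration: the original pipeline's values are not recoverable, and
  with error-free or lightly-errored short reads the results are
  insensitive to both.
* Candidate ties at equal NSD break toward higher genome coverage, then
  lexicographic genome id; equal-best bitscore votes use exact equality
  after rounding to one decimal.
* Reads are generated from the PstI end of each fragment (the asymmetric
  adapter convention); the opposite orientation is selectable in
  `SimulationConfig`.

## Problem sizes

Tests and the acceptance script run entirely on synthetic material:
100 kb genomes for identification and recovery experiments (24 assay
simulations in the recovery protocol), ≤ 5 kb subjects for the
aligner-vs-oracle equivalence suite, and the packaged CSV tables for the
method-comparison arithmetic. These sizes give stable statistics for
every quantity asserted while keeping the whole suite fast.

## Known limitations

* The Karlin–Altschul constants are fixed for the single built-in scoring
  scheme; changing match/mismatch/gap costs would require new constants.
* The e-value lacks finite-size edge corrections, so very short subjects
  make it slightly conservative.
* The real-data identification tables bundled with the package (isolate
  summaries and the eight-isolate method comparison) are inputs for the
  comparison arithmetic, not outputs this package can regenerate: doing
  so would require the original read sets and the full RefSeq panel.
* The control benchmark against E. coli O157 (CP008957.1) requires a
  local copy of that genome and is therefore provided as a callable
  (`rrident.benchmark.control_benchmark`) rather than a packaged test.
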