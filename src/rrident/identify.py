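"""Candidate-genome ranking and best-match selection by nucleotide
sequence distance (NSD).

The pipeline stage this module implements: collapsed sequence tags from one
sample are aligned against a panel of reference genomes; candidate genomes
are ranked by the number of tags whose best (or equal-best) bitscore falls
on them; the top three candidates are then scored with the NSD — a
gap-adjusted Jukes-Cantor-style distance aggregated over every tag's best
alignment::

    NSD = -3/4 * ln(1 - 4/3 * S/(I+S)) * (1 - G/T) + G/T

where I, S, G and T are the identities, substitutions, gap openings and
total alignment columns summed over the retained alignments. The genome
with the lowest NSD is the best match; lower NSD means closer relatedness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .align import AlignmentHit, AlignParams, align
from .digest import Genome

__all__ = [
    "NSDComponents",
    "CandidateScore",
    "IdentificationResult",
    "PanelEntry",
    "NSDSaturationError",
    "compute_nsd",
    "aggregate_components",
    "best_hit_per_query",
    "rank_candidates",
    "genome_coverage",
    "merge_intervals",
    "identify_sample",
]


class NSDSaturationError(ValueError):
    """The substitution fraction reaches the Jukes-Cantor ceiling (3/4):
    the distance is undefined."""


@dataclass(frozen=True)
class NSDComponents:
    """Aggregated alignment quantities feeding the NSD.

    I: summed identical aligned bases; S: summed substitutions; G: summed
    gap openings; T: summed alignment columns, over all retained hits of a
    sample against one genome.
    """

    I: int
    S: int
    G: int
    T: int

    def __post_init__(self) -> None:
        if min(self.I, self.S, self.G, self.T) < 0:
            raise ValueError("NSD components must be non-negative")
        if self.T < self.I + self.S:
            raise ValueError("total columns T cannot be less than I + S")


def compute_nsd(c: NSDComponents) -> float:
    """Evaluate the NSD from aggregated components.

    Zero exactly when there are no substitutions and no gap openings.
    Raises :class:`NSDSaturationError` when S/(I+S) >= 3/4 (the
    Jukes-Cantor correction diverges) and ValueError when nothing aligned.
    """
    if c.T == 0 or c.I + c.S == 0:
        raise ValueError("no aligned bases: NSD undefined")
    p = c.S / (c.I + c.S)
    if p >= 0.75:
        raise NSDSaturationError(f"substitution fraction {p:.3f} >= 3/4: distance saturated")
    g = c.G / c.T
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p) * (1.0 - g) + g


def best_hit_per_query(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """One hit per query: highest bitscore, ties to the longer alignment.

    Restricting each tag to its single best alignment on a candidate stops
    repeat regions from being counted several times in the NSD components.
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.bitscore, h.align_length) > (cur.bitscore, cur.align_length):
            best[h.query_id] = h
    return list(best.values())


def aggregate_components(hits: list[AlignmentHit], per_query_best: bool = True) -> NSDComponents:
    """Sum I/S/G/T over hits (by default each query's best hit only)."""
    retained = best_hit_per_query(hits) if per_query_best else hits
    I = sum(h.identities for h in retained)
    S = sum(h.mismatches for h in retained)
    G = sum(h.gap_openings for h in retained)
    T = sum(h.align_length for h in retained)
    return NSDComponents(I, S, G, T)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    merged: list[list[int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def genome_coverage(hits: list[AlignmentHit], genome_length: int) -> float:
    """Percent of the genome covered by the union of hit subject intervals.

    Overlapping hits are merged before summing, so coverage never exceeds
    the summed hit lengths and never exceeds 100%.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    covered = sum(hi - lo + 1 for lo, hi in merge_intervals([h.subject_interval for h in hits]))
    return 100.0 * covered / genome_length


def rank_candidates(hits_by_genome: dict[str, list[AlignmentHit]], top_n: int = 3) -> list[tuple[str, int]]:
    """Rank panel genomes by best-or-equal-best bitscore votes.

    For each query the maximal bitscore across the whole panel is found
    (bitscores compared at tabular precision, 1 decimal); every genome
    achieving it receives one vote from that query. Genomes are ordered by
    descending vote count, ties broken by summed bitscore then genome id,
    and the top ``top_n`` are returned as ``(genome_id, votes)``.
    """
    best_by_query: dict[str, float] = {}
    per_genome_query_best: dict[str, dict[str, float]] = {}
    sum_bits: dict[str, float] = {}
    for gid, hits in hits_by_genome.items():
        qbest: dict[str, float] = {}
        for h in hits:
            b = round(h.bitscore, 1)
            if b > qbest.get(h.query_id, -1.0):
                qbest[h.query_id] = b
            sum_bits[gid] = sum_bits.get(gid, 0.0) + h.bitscore
        per_genome_query_best[gid] = qbest
        for qid, b in qbest.items():
            if b > best_by_query.get(qid, -1.0):
                best_by_query[qid] = b
    if not best_by_query:
        return []
    votes: dict[str, int] = {}
    for gid, qbest in per_genome_query_best.items():
        if qbest:  # genomes with any retained hit participate in the ranking
            votes[gid] = sum(1 for qid, b in qbest.items() if b == best_by_query[qid])
    ranked = sorted(votes, key=lambda g: (-votes[g], -sum_bits.get(g, 0.0), g))
    return [(g, votes[g]) for g in ranked[:top_n]]


@dataclass(frozen=True)
class PanelEntry:
    """One reference genome of the candidate panel."""

    genome: Genome
    replicon: str = "chromosome"  # or "plasmid"


@dataclass(frozen=True)
class CandidateScore:
    genome_id: str
    best_hit_count: int
    avg_percent_identity: float
    nsd: float | None  # None when the distance saturated
    coverage_percent: float
    n_aligned: int
    n_unaligned: int
    components: NSDComponents | None = None

    def to_dict(self) -> dict:
        d = {
            "genome_id": self.genome_id,
            "best_hit_count": self.best_hit_count,
            "avg_percent_identity": self.avg_percent_identity,
            "nsd": self.nsd,
            "coverage_percent": self.coverage_percent,
            "n_aligned": self.n_aligned,
            "n_unaligned": self.n_unaligned,
        }
        if self.components is not None:
            d["components"] = {"I": self.components.I, "S": self.components.S,
                               "G": self.components.G, "T": self.components.T}
        return d


@dataclass(frozen=True)
class IdentificationResult:
    """Ranked candidates for one sample plus report tallies.

    Candidates are sorted by ascending NSD (saturated distances last), ties
    by higher coverage then genome id. ``tallies`` counts queries whose best
    hit lands on a chromosome, on a plasmid, or nowhere; the identity
    histogram uses 1%-wide bins with hits below 95% flagged separately.
    """

    sample_id: str
    status: str  # "identified" | "unidentified"
    candidates: tuple[CandidateScore, ...]
    tallies: dict[str, int] = field(default_factory=dict)
    identity_histogram: dict[str, int] = field(default_factory=dict)

    @property
    def best_match(self) -> CandidateScore | None:
        return self.candidates[0] if self.candidates else None

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "status": self.status,
            "candidates": [c.to_dict() for c in self.candidates],
            "tallies": self.tallies,
            "identity_histogram": self.identity_histogram,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def _score_candidate(
    gid: str,
    hits: list[AlignmentHit],
    genome_length: int,
    total_queries: int,
    votes: int,
    per_query_best: bool,
) -> CandidateScore:
    retained = best_hit_per_query(hits) if per_query_best else hits
    n_aligned = len({h.query_id for h in hits})
    total_len = sum(h.align_length for h in retained)
    avg_ident = (
        sum(h.percent_identity * h.align_length for h in retained) / total_len if total_len else 0.0
    )
    comps = aggregate_components(hits, per_query_best)
    try:
        nsd = compute_nsd(comps)
    except (NSDSaturationError, ValueError):
        nsd = None
    return CandidateScore(
        genome_id=gid,
        best_hit_count=votes,
        avg_percent_identity=round(avg_ident, 4),
        nsd=nsd,
        coverage_percent=genome_coverage(hits, genome_length),
        n_aligned=n_aligned,
        n_unaligned=total_queries - n_aligned,
        components=comps,
    )


def identity_histogram(hits: list[AlignmentHit], flag_below: float = 95.0) -> dict[str, int]:
    """1%-wide identity bins over hits; bins below ``flag_below`` carry a
    ``low:`` prefix (the report's red class)."""
    bins: dict[str, int] = {}
    for h in hits:
        lo = min(math.floor(h.percent_identity), 99)
        key = f"{lo}-{lo + 1}"
        if h.percent_identity < flag_below:
            key = "low:" + key
        bins[key] = bins.get(key, 0) + 1
    return dict(sorted(bins.items()))


def identify_sample(
    collapsed_reads,
    panel: list[PanelEntry],
    params: AlignParams | None = None,
    backend: str = "builtin",
    per_query_best: bool = True,
    sample_id: str = "sample",
) -> IdentificationResult:
    """Two-stage identification of one sample against a genome panel.

    Stage 1 aligns every tag against every panel genome and ranks candidates
    by best-or-equal-best bitscore votes. Stage 2 realigns the tags against
    the top three candidates, aggregates each tag's best alignment into the
    NSD components, and orders candidates by ascending NSD. A sample with no
    retained alignments, or whose candidates all saturate the distance, is
    reported as unidentified.
    """
    if not collapsed_reads:
        raise ValueError("identify_sample requires a non-empty read set")
    params = params or AlignParams()
    queries = {f"tag{i:05d}": c.sequence for i, c in enumerate(collapsed_reads)}

    stage1 = {e.genome.id: align(queries, e.genome, params, backend=backend) for e in panel}
    ranking = rank_candidates(stage1, top_n=3)
    if not ranking:
        return IdentificationResult(sample_id, "unidentified", (), {"chromosome_hit": 0, "plasmid_hit": 0, "no_hit": len(queries)}, {})
    votes = dict(ranking)
    by_id = {e.genome.id: e for e in panel}

    scores = []
    stage2: dict[str, list[AlignmentHit]] = {}
    for gid, _ in ranking:
        entry = by_id[gid]
        stage2[gid] = align(queries, entry.genome, params, backend=backend)  # stage-2 realignment
        scores.append(_score_candidate(gid, stage2[gid], len(entry.genome), len(queries), votes[gid], per_query_best))
    scores.sort(key=lambda c: (c.nsd is None, c.nsd if c.nsd is not None else 0.0, -c.coverage_percent, c.genome_id))

    if all(c.nsd is None for c in scores):
        status = "unidentified"
    else:
        status = "identified"

    best_gid = scores[0].genome_id
    retained = best_hit_per_query(stage2[best_gid])
    aligned_queries = {h.query_id for h in retained}
    replicon = by_id[best_gid].replicon
    tallies = {
        "chromosome_hit": len(aligned_queries) if replicon == "chromosome" else 0,
        "plasmid_hit": len(aligned_queries) if replicon == "plasmid" else 0,
        "no_hit": len(queries) - len(aligned_queries),
    }
    return IdentificationResult(sample_id, status, tuple(scores), tallies, identity_histogram(retained))


def coverage_bed(hits: list[AlignmentHit], genome_id: str) -> str:
    """Merged hit intervals as BED (0-based half-open) for track export."""
    lines = [
        f"{genome_id}\t{lo - 1}\t{hi}" for lo, hi in merge_intervals([h.subject_interval for h in hits])
    ]
    return "\n".join(lines) + ("\n" if lines else "")
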