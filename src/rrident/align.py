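"""Local alignment of collapsed sequence tags against candidate genomes.

Two interchangeable backends produce the same 12-column BLAST-tabular hit
model:

* ``builtin`` — a self-contained seeded aligner: exact word-size k-mer
  seeding on both strands, then banded affine-gap Smith-Waterman around
  each seed cluster. Scoring is match +1 / mismatch -2 / gap open 5 /
  gap extend 2 (a gap of length L costs 5 + 2L), with bit scores and
  e-values from the Karlin-Altschul transformation using the published
  constants for this scheme (lambda = 1.28, K = 0.46). It needs no
  external tools and is exact with respect to a full Smith-Waterman on
  the scoring scheme whenever the optimal alignment contains one exact
  word-size match.
* ``blastn`` — an adapter that shells out to NCBI BLAST+ ``blastn`` and
  parses its tabular output, for bit-compatibility with production runs.

Default thresholds are those of the identification pipeline: word size 12,
bitscore 50, e-value 1e-6, 80% identity, 80% query cover.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .readprep import CollapsedRead

__all__ = [
    "AlignmentHit",
    "AlignParams",
    "AlignBackendError",
    "align",
    "smith_waterman",
    "LocalAlignment",
    "parse_tabular",
    "write_tabular",
    "bitscore",
    "evalue",
]

MATCH = 1
MISMATCH = -2
GAP_OPEN = 5  # cost of a length-L gap: GAP_OPEN + GAP_EXTEND * L
GAP_EXTEND = 2
LAMBDA = 1.28
KA_K = 0.46

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


class AlignBackendError(RuntimeError):
    """External alignment tool failed; carries the tool's diagnostics."""


@dataclass(frozen=True)
class AlignParams:
    """Hit-filtering thresholds shared by both backends."""

    word_size: int = 12
    min_bitscore: float = 50.0
    max_evalue: float = 1e-6
    min_percent_identity: float = 80.0
    min_query_cover: float = 80.0

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if min(self.min_bitscore, self.min_percent_identity, self.min_query_cover) < 0 or self.max_evalue < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment in the 12-column BLAST tabular convention.

    Coordinates are 1-based inclusive; ``s_start > s_end`` marks a
    minus-strand hit.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    @property
    def identities(self) -> int:
        return round(self.percent_identity * self.align_length / 100.0)

    @property
    def subject_interval(self) -> tuple[int, int]:
        """Strand-normalized (low, high) subject coordinates, 1-based inclusive."""
        return (min(self.s_start, self.s_end), max(self.s_start, self.s_end))


def bitscore(raw_score: float) -> float:
    return (LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def evalue(raw_score: float, query_len: int, subject_len: int) -> float:
    return query_len * subject_len * 2.0 ** (-bitscore(raw_score))


# ---------------------------------------------------------------------------
# Affine-gap Smith-Waterman (the extension core, also usable standalone)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalAlignment:
    """Optimal local alignment of one query/subject pair.

    Coordinates are 0-based half-open on the inputs as given.
    """

    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identities: int
    mismatches: int
    gap_openings: int
    align_length: int


def smith_waterman(query: str, subject: str) -> LocalAlignment | None:
    """Optimal local alignment under the module scoring scheme.

    Full O(len(query) x len(subject)) affine-gap dynamic programme with
    traceback; used by :func:`align` on small windows around seed clusters
    and directly testable against an independent aligner. Ties are broken
    toward the lowest (i, j) end cell and, in the traceback, toward
    diagonal moves. Returns None when no positive-scoring alignment exists.
    """
    m, n = len(query), len(subject)
    if m == 0 or n == 0:
        return None
    neg = -(10**9)
    open_cost = GAP_OPEN + GAP_EXTEND
    # H: best local score ending at (i, j); E: ends in gap-in-query; F: gap-in-subject
    prev_h = [0] * (n + 1)
    prev_f = [neg] * (n + 1)
    # pointer codes packed per cell: 0 stop, 1 diag, 2 from E, 3 from F
    ptr_h = [[0] * (n + 1) for _ in range(m + 1)]
    ptr_e = [[0] * (n + 1) for _ in range(m + 1)]  # 1: opened here, 0: extended
    ptr_f = [[0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        qc = query[i - 1]
        cur_h = [0] * (n + 1)
        cur_f = [neg] * (n + 1)
        e = neg
        row_ph, row_pe, row_pf = ptr_h[i], ptr_e[i], ptr_f[i]
        for j in range(1, n + 1):
            # E: gap in query (consumes subject base)
            e_open = cur_h[j - 1] - open_cost
            e_ext = e - GAP_EXTEND
            if e_open >= e_ext:
                e, row_pe[j] = e_open, 1
            else:
                e, row_pe[j] = e_ext, 0
            # F: gap in subject (consumes query base)
            f_open = prev_h[j] - open_cost
            f_ext = prev_f[j] - GAP_EXTEND
            if f_open >= f_ext:
                f, row_pf[j] = f_open, 1
            else:
                f, row_pf[j] = f_ext, 0
            cur_f[j] = f
            diag = prev_h[j - 1] + (MATCH if qc == subject[j - 1] else MISMATCH)
            h, p = 0, 0
            if diag > h:
                h, p = diag, 1
            if e > h:
                h, p = e, 2
            if f > h:
                h, p = f, 3
            cur_h[j] = h
            row_ph[j] = p
            if h > best:
                best, bi, bj = h, i, j
        prev_h, prev_f = cur_h, cur_f
    if best <= 0:
        return None

    # Traceback from the best cell.
    i, j, state = bi, bj, "H"
    identities = mismatches = gaps = align_len = 0
    while i > 0 and j > 0:
        if state == "H":
            p = ptr_h[i][j]
            if p == 0:
                break
            if p == 1:
                align_len += 1
                if query[i - 1] == subject[j - 1]:
                    identities += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            align_len += 1
            opened = ptr_e[i][j] == 1
            j -= 1
            if opened:
                gaps += 1
                state = "H"
        else:  # F
            align_len += 1
            opened = ptr_f[i][j] == 1
            i -= 1
            if opened:
                gaps += 1
                state = "H"
    return LocalAlignment(best, i, bi, j, bj, identities, mismatches, gaps, align_len)


# ---------------------------------------------------------------------------
# Seeded search
# ---------------------------------------------------------------------------

_PAD = 32  # window margin around a seed cluster; covers any gap worth opening


def _normalize_queries(queries) -> list[tuple[str, str]]:
    if isinstance(queries, Mapping):
        return [(str(k), v.upper()) for k, v in queries.items()]
    out = []
    for i, q in enumerate(queries):
        if isinstance(q, CollapsedRead):
            out.append((f"tag{i:05d}", q.sequence.upper()))
        elif isinstance(q, tuple):
            out.append((str(q[0]), q[1].upper()))
        else:
            raise TypeError(f"unsupported query type: {type(q)!r}")
    return out


def _seed_clusters(seeds: list[tuple[int, int]], qlen: int) -> list[tuple[int, int]]:
    """Group seeds (subject_pos, query_pos) into loci; return windows (lo, hi)."""
    seeds.sort()
    clusters: list[list[tuple[int, int]]] = []
    for s, q in seeds:
        if clusters and s - clusters[-1][-1][0] <= qlen + _PAD:
            clusters[-1].append((s, q))
        else:
            clusters.append([(s, q)])
    windows = []
    for cl in clusters:
        diags = [s - q for s, q in cl]
        lo = min(diags) - _PAD
        hi = max(diags) + qlen + _PAD
        windows.append((max(lo, 0), hi))
    return windows


def _hit_from_window(
    qid: str,
    oriented: str,
    qlen: int,
    strand: int,
    subject_seq: str,
    win_lo: int,
    win_hi: int,
    subject_id: str,
    subject_len: int,
) -> AlignmentHit | None:
    aln = smith_waterman(oriented, subject_seq[win_lo:win_hi])
    if aln is None:
        return None
    bits = bitscore(aln.score)
    ev = evalue(aln.score, qlen, subject_len)
    pident = 100.0 * aln.identities / aln.align_length
    s0 = win_lo + aln.s_start + 1  # to 1-based inclusive
    s1 = win_lo + aln.s_end
    if strand > 0:
        q0, q1 = aln.q_start + 1, aln.q_end
        ss, se = s0, s1
    else:
        q0, q1 = qlen - aln.q_end + 1, qlen - aln.q_start
        ss, se = s1, s0  # minus strand: s_start > s_end
    return AlignmentHit(
        qid, subject_id, round(pident, 2), aln.align_length, aln.mismatches,
        aln.gap_openings, q0, q1, ss, se, ev, round(bits, 1),
    )


def _align_builtin(queries: list[tuple[str, str]], subject_id: str, subject_seq: str, params: AlignParams) -> list[AlignmentHit]:
    w = params.word_size
    n = len(subject_seq)
    if n < w:
        return []
    # Index query k-mers on both orientations, then stream the subject once.
    index: dict[str, list[tuple[int, int, int]]] = defaultdict(list)  # kmer -> (query idx, strand, qpos)
    oriented_seqs: dict[tuple[int, int], str] = {}
    for qi, (_, qseq) in enumerate(queries):
        for strand, seq in ((1, qseq), (-1, _revcomp(qseq))):
            oriented_seqs[(qi, strand)] = seq
            for p in range(len(seq) - w + 1):
                kmer = seq[p : p + w]
                if "N" not in kmer:
                    index[kmer].append((qi, strand, p))

    seeds: dict[tuple[int, int], list[tuple[int, int]]] = defaultdict(list)
    for s in range(n - w + 1):
        entry = index.get(subject_seq[s : s + w])
        if entry:
            for qi, strand, qp in entry:
                seeds[(qi, strand)].append((s, qp))

    hits_by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    qlens: dict[str, int] = dict()
    for (qi, strand), seed_list in seeds.items():
        qid, qseq = queries[qi]
        qlens[qid] = len(qseq)
        for win_lo, win_hi in _seed_clusters(seed_list, len(qseq)):
            hit = _hit_from_window(
                qid, oriented_seqs[(qi, strand)], len(qseq), strand, subject_seq,
                win_lo, min(win_hi, n), subject_id, n,
            )
            if hit is not None:
                hits_by_query[qid].append(hit)

    # One best alignment per subject locus: drop hits whose subject interval
    # substantially overlaps a better one (repeats remain separate loci).
    # Locus resolution runs on the unfiltered alignments so the threshold
    # filters below are strictly monotone: tightening never adds a hit.
    out: list[AlignmentHit] = []
    for qid, _ in queries:
        kept: list[AlignmentHit] = []
        for hit in sorted(hits_by_query.get(qid, ()), key=lambda h: (-h.bitscore, h.subject_interval)):
            lo, hi = hit.subject_interval
            redundant = False
            for k in kept:
                klo, khi = k.subject_interval
                ov = min(hi, khi) - max(lo, klo) + 1
                if ov > 0.5 * min(hi - lo + 1, khi - klo + 1):
                    redundant = True
                    break
            if not redundant:
                kept.append(hit)
        for hit in kept:
            qcov = 100.0 * (hit.q_end - hit.q_start + 1) / qlens[hit.query_id]
            if (
                hit.bitscore >= params.min_bitscore
                and hit.evalue <= params.max_evalue
                and hit.percent_identity >= params.min_percent_identity
                and qcov >= params.min_query_cover
            ):
                out.append(hit)
    return out


# ---------------------------------------------------------------------------
# External blastn backend
# ---------------------------------------------------------------------------


def _align_blastn(queries: list[tuple[str, str]], subject_id: str, subject_seq: str, params: AlignParams) -> list[AlignmentHit]:
    if shutil.which("blastn") is None:
        raise AlignBackendError("blastn executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "queries.fa"
        spath = Path(tmp) / "subject.fa"
        qpath.write_text("".join(f">{qid}\n{seq}\n" for qid, seq in queries))
        spath.write_text(f">{subject_id}\n{subject_seq}\n")
        cmd = [
            "blastn", "-query", str(qpath), "-subject", str(spath),
            "-word_size", str(params.word_size),
            "-evalue", str(params.max_evalue),
            "-perc_identity", str(params.min_percent_identity),
            "-qcov_hsp_perc", str(params.min_query_cover),
            "-dust", "no", "-outfmt", "6",
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise AlignBackendError(f"blastn failed (exit {proc.returncode}): {proc.stderr.strip()}")
        hits = _parse_tabular_lines(proc.stdout.splitlines(), "blastn output")
    return [h for h in hits if h.bitscore >= params.min_bitscore]


def align(queries, subject, params: AlignParams | None = None, backend: str = "builtin") -> list[AlignmentHit]:
    """Align query tags against one subject genome.

    ``queries`` may be a mapping ``{id: sequence}``, a list of ``(id,
    sequence)`` pairs, or a list of :class:`~rrident.readprep.CollapsedRead`
    (ids are then generated as ``tag00000``...). ``subject`` is anything
    with ``id`` and ``sequence`` attributes (e.g. a Genome) or an
    ``(id, sequence)`` pair. Hits satisfy every threshold in ``params`` and
    are sorted by query id then descending bitscore.
    """
    params = params or AlignParams()
    qs = _normalize_queries(queries)
    if hasattr(subject, "sequence"):
        sid, sseq = subject.id, subject.sequence.upper()
    else:
        sid, sseq = subject[0], subject[1].upper()
    if backend == "builtin":
        hits = _align_builtin(qs, sid, sseq, params)
    elif backend == "blastn":
        hits = _align_blastn(qs, sid, sseq, params)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    order = {qid: i for i, (qid, _) in enumerate(qs)}
    hits.sort(key=lambda h: (order.get(h.query_id, 0), -h.bitscore))
    return hits


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def _parse_tabular_lines(lines: Iterable[str], source: str) -> list[AlignmentHit]:
    hits = []
    for ln, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 12:
            raise ValueError(f"{source}:{ln}: expected 12 tab-separated columns, got {len(parts)}")
        hits.append(
            AlignmentHit(
                parts[0], parts[1], float(parts[2]), int(parts[3]), int(parts[4]),
                int(parts[5]), int(parts[6]), int(parts[7]), int(parts[8]),
                int(parts[9]), float(parts[10]), float(parts[11]),
            )
        )
    return hits


def parse_tabular(path) -> list[AlignmentHit]:
    """Read 12-column BLAST tabular hits; '#' comment lines are skipped."""
    return _parse_tabular_lines(Path(path).read_text().splitlines(), str(path))


def tabular_lines(hits: list[AlignmentHit]) -> list[str]:
    return [
        "\t".join(
            [
                h.query_id, h.subject_id, f"{h.percent_identity:.2f}", str(h.align_length),
                str(h.mismatches), str(h.gap_openings), str(h.q_start), str(h.q_end),
                str(h.s_start), str(h.s_end), f"{h.evalue:.2e}", f"{h.bitscore:.1f}",
            ]
        )
        for h in hits
    ]


def write_tabular(hits: list[AlignmentHit], path) -> None:
    lines = tabular_lines(hits)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
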