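"""FASTQ preparation: quality filtering, demultiplexing, adapter trimming
and collapsing of identical reads into fastQcol records.

A fastQcol record holds each unique sequence together with its read count
and the per-base mean PHRED quality over the reads that were merged into
it. The on-disk dialect is a TSV with columns ``sequence``, ``count`` and
``mean_quality`` (comma-separated per-base means, 2 decimals).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReadRecord",
    "CollapsedRead",
    "read_fastq",
    "write_fastq",
    "quality_filter",
    "demultiplex",
    "trim_reverse_adapter",
    "collapse",
    "read_fastqcol",
    "write_fastqcol",
    "prep_reads",
    "UNDETERMINED",
]

#: Demultiplexing bin for reads matching no barcode.
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ReadRecord:
    """One FASTQ read: id, sequence and per-base PHRED qualities."""

    id: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "quality", tuple(self.quality))
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id}: sequence and quality lengths differ")

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.quality)) if self.quality else 0.0


@dataclass(frozen=True)
class CollapsedRead:
    """One fastQcol record: a unique sequence, its read count, and the
    arithmetic mean PHRED at each base over the merged reads."""

    sequence: str
    count: int
    mean_quality: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_quality", tuple(float(q) for q in self.mean_quality))
        if self.count < 1:
            raise ValueError("collapsed read count must be >= 1")
        if len(self.sequence) != len(self.mean_quality):
            raise ValueError("sequence and mean_quality lengths differ")


def read_fastq(path) -> list[ReadRecord]:
    return [
        ReadRecord(rec.id, str(rec.seq).upper(), tuple(rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: list[ReadRecord], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def quality_filter(reads: list[ReadRecord], min_mean_phred: float = 25.0) -> tuple[list[ReadRecord], int]:
    """Keep reads whose mean PHRED is at least the threshold.

    Returns (kept reads, number discarded).
    """
    kept = [r for r in reads if r.mean_quality >= min_mean_phred]
    return kept, len(reads) - len(kept)


def demultiplex(reads: list[ReadRecord], barcode_map: dict[str, str]) -> dict[str, list[ReadRecord]]:
    """Assign reads to samples by exact barcode prefix, stripping the barcode.

    Barcodes may differ in length but must be mutually prefix-free so the
    assignment is unambiguous. Unmatched reads land in the
    :data:`UNDETERMINED` bin with their sequence untouched.
    """
    barcodes = sorted(barcode_map)
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            if b.startswith(a) or a.startswith(b):
                raise ValueError(f"barcode set not prefix-free: {a!r} / {b!r}")

    out: dict[str, list[ReadRecord]] = {sample: [] for sample in barcode_map.values()}
    out[UNDETERMINED] = []
    for read in reads:
        for bc, sample in barcode_map.items():
            if read.sequence.startswith(bc):
                n = len(bc)
                out[sample].append(ReadRecord(read.id, read.sequence[n:], read.quality[n:]))
                break
        else:
            out[UNDETERMINED].append(read)
    return out


def trim_reverse_adapter(
    read: ReadRecord,
    adapter: str,
    min_len: int = 30,
    max_len: int = 69,
    seed_len: int = 10,
) -> ReadRecord | None:
    """Trim reverse-adapter read-through; return None when the trimmed read
    is shorter than ``min_len``.

    Reads from fragments shorter than ``max_len`` continue into the reverse
    adapter; its first ``seed_len`` bases are located by exact match and
    everything from that position on is removed. Reads with no adapter are
    truncated to ``max_len``.
    """
    seed = adapter[:seed_len]
    pos = read.sequence.find(seed) if seed else -1
    cut = pos if pos != -1 else len(read.sequence)
    cut = min(cut, max_len)
    if cut < min_len:
        return None
    return ReadRecord(read.id, read.sequence[:cut], read.quality[:cut])


def collapse(reads: list[ReadRecord]) -> list[CollapsedRead]:
    """Collapse identical sequences into fastQcol records.

    Counts conserve the number of input reads; per-base quality is the
    arithmetic mean over merged reads. Output is sorted by descending count,
    then lexicographically by sequence.
    """
    groups: dict[str, list[ReadRecord]] = defaultdict(list)
    for r in reads:
        groups[r.sequence].append(r)
    out = [
        CollapsedRead(
            seq,
            len(members),
            tuple(np.mean([m.quality for m in members], axis=0)),
        )
        for seq, members in groups.items()
    ]
    out.sort(key=lambda c: (-c.count, c.sequence))
    return out


_FASTQCOL_HEADER = "sequence\tcount\tmean_quality"


def write_fastqcol(records: list[CollapsedRead], path) -> None:
    lines = [_FASTQCOL_HEADER]
    for rec in records:
        quals = ",".join(f"{q:.2f}" for q in rec.mean_quality)
        lines.append(f"{rec.sequence}\t{rec.count}\t{quals}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fastqcol(path) -> list[CollapsedRead]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _FASTQCOL_HEADER:
        raise ValueError(f"{path}: missing fastQcol header line")
    records = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields, got {len(parts)}")
        seq, count_s, quals_s = parts
        try:
            count = int(count_s)
            quals = tuple(float(q) for q in quals_s.split(","))
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: {exc}") from None
        if count < 1:
            raise ValueError(f"{path}:{ln}: count must be >= 1, got {count}")
        records.append(CollapsedRead(seq, count, quals))
    return records


def prep_reads(
    reads: list[ReadRecord],
    adapter: str,
    min_mean_phred: float = 25.0,
    min_len: int = 30,
    max_len: int = 69,
    seed_len: int = 10,
) -> list[CollapsedRead]:
    """Single-sample preparation pipeline: quality filter, adapter trim,
    collapse. Assumes the barcode has already been removed."""
    kept, _ = quality_filter(reads, min_mean_phred)
    trimmed = [t for r in kept if (t := trim_reverse_adapter(r, adapter, min_len, max_len, seed_len)) is not None]
    return collapse(trimmed)
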