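"""Poly(A)-tail read selection, trimming, and 3'-end mapping.

Reads carrying an untemplated poly(A) tail mark a cleavage site: the trimmed
remainder aligns so that its 3' terminus is the transcript's last transcribed
base. Selection keeps a read iff its maximal terminal run of A is >= 23 nt
and the remainder after removing the run is >= 10 nt; the strict-run policy
(no mismatches) is the default, with an optional single-interruption mode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .annotation import revcomp

DEFAULT_MIN_TAIL = 23
DEFAULT_MIN_REMAINDER = 10

_TAIL_RE = re.compile(r"[Aa]+$")


@dataclass(frozen=True)
class PolyARead:
    read_id: str
    trimmed_sequence: str
    tail_length: int


@dataclass(frozen=True)
class EndAlignment:
    """A read's 3'-most transcribed position.

    ``end3`` follows the half-open convention: one past the last base on '+',
    the first (lowest) coordinate of the alignment on '-'.
    """

    read_id: str
    contig: str
    strand: str
    end3: int


@dataclass
class RejectionLog:
    counts: dict[str, int] = field(default_factory=dict)
    records: list[tuple[str, str]] = field(default_factory=list)

    def add(self, read_id: str, reason: str) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + 1
        self.records.append((read_id, reason))

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _terminal_tail(seq: str, allow_one_interruption: bool) -> tuple[int, int]:
    """Return (n_removed, n_adenosines) for the terminal A run of ``seq``."""
    m = _TAIL_RE.search(seq)
    if m is None:
        return 0, 0
    run = len(seq) - m.start()
    if not allow_one_interruption:
        return run, run
    head = seq[: m.start()]
    m2 = _TAIL_RE.search(head[:-1]) if head else None
    if head and m2 is not None and m2.end() == len(head) - 1:
        run2 = len(head) - 1 - m2.start()
        return run + 1 + run2, run + run2
    return run, run


def extract_polya_reads(
    records: Iterable[tuple[str, str]],
    min_tail: int = DEFAULT_MIN_TAIL,
    min_remainder: int = DEFAULT_MIN_REMAINDER,
    allow_one_interruption: bool = False,
) -> tuple[list[PolyARead], RejectionLog]:
    """Select and trim polyA-tailed reads from ``(read_id, sequence)`` pairs.

    A read is kept iff its terminal A run holds >= ``min_tail`` adenosines and
    the remainder after removing the run is >= ``min_remainder`` nt.
    """
    kept: list[PolyARead] = []
    log = RejectionLog()
    for read_id, seq in records:
        if not seq:
            raise ValueError(f"empty sequence for read {read_id!r}")
        removed, n_a = _terminal_tail(seq, allow_one_interruption)
        if n_a < min_tail:
            log.add(read_id, "tail_too_short")
            continue
        remainder = seq[: len(seq) - removed]
        if len(remainder) < min_remainder:
            log.add(read_id, "remainder_too_short")
            continue
        kept.append(PolyARead(read_id, remainder.upper(), n_a))
    return kept, log


def iter_fastq(path: str) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file; malformed records are fatal."""
    it = SeqIO.parse(path, "fastq")
    index = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from exc
        yield rec.id, str(rec.seq)
        index += 1


def write_trimmed_fastq(reads: Iterable[PolyARead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.trimmed_sequence}\n+\n{'I' * len(r.trimmed_sequence)}\n")


# ---------------------------------------------------------------------------
# Exact-match mapping
# ---------------------------------------------------------------------------

class GenomeIndex:
    """K-mer anchored exact-match index over the forward strands of a genome.

    Every genomic occurrence of a query of length >= k is anchored by its
    first k-mer, so candidate verification enumerates all perfect hits.
    Queries shorter than k fall back to a linear scan.
    """

    def __init__(self, genome: dict[str, str], k: int = 16):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        index: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in self.genome.items():
            for pos in range(len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append((contig, pos))
        self._index = index

    def _find_forward(self, query: str) -> list[tuple[str, int]]:
        n = len(query)
        if n >= self.k:
            hits = []
            for contig, pos in self._index.get(query[: self.k], ()):
                if self.genome[contig][pos : pos + n] == query:
                    hits.append((contig, pos))
            return hits
        hits = []
        for contig, seq in self.genome.items():
            start = seq.find(query)
            while start != -1:
                hits.append((contig, start))
                start = seq.find(query, start + 1)
        return hits

    def find_all(self, query: str) -> list[tuple[str, str, int, int]]:
        """All perfect hits of ``query`` as (contig, strand, start, end)."""
        query = query.upper()
        out = [(c, "+", p, p + len(query)) for c, p in self._find_forward(query)]
        rc = revcomp(query)
        out += [(c, "-", p, p + len(query)) for c, p in self._find_forward(rc)]
        return out


def map_trimmed_reads(
    reads: Iterable[PolyARead],
    genome: dict[str, str] | GenomeIndex,
) -> tuple[list[EndAlignment], dict[str, int]]:
    """Map trimmed reads by unique perfect match; multi-mappers/no-hits dropped.

    ``end3`` is the hit end on '+' and the hit start on '-' (the genomic
    position of the read's 3'-most transcribed base, half-open convention).
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    alignments: list[EndAlignment] = []
    stats = {"mapped": 0, "multimapped": 0, "unmapped": 0}
    for read in reads:
        hits = index.find_all(read.trimmed_sequence)
        if len(hits) == 1:
            contig, strand, start, end = hits[0]
            end3 = end if strand == "+" else start
            alignments.append(EndAlignment(read.read_id, contig, strand, end3))
            stats["mapped"] += 1
        elif len(hits) == 0:
            stats["unmapped"] += 1
        else:
            stats["multimapped"] += 1
    return alignments, stats


# ---------------------------------------------------------------------------
# BED import / export (lets users substitute a real aligner)
# ---------------------------------------------------------------------------

BED_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


def import_alignments(bed: str | pd.DataFrame) -> list[EndAlignment]:
    """Read strand-aware 3' termini from a BED6 table."""
    if isinstance(bed, pd.DataFrame):
        df = bed.copy()
        df.columns = BED_COLUMNS[: len(df.columns)]
    else:
        df = pd.read_csv(bed, sep="\t", header=None, names=BED_COLUMNS, comment="#")
    alignments = []
    for row in df.itertuples(index=False):
        strand = str(row.strand)
        if strand not in ("+", "-"):
            raise ValueError(f"missing or invalid strand for record {row.name!r}: {strand!r}")
        end3 = int(row.end) if strand == "+" else int(row.start)
        alignments.append(EndAlignment(str(row.name), str(row.contig), strand, end3))
    return alignments


def alignments_to_bed(
    alignments: Iterable[EndAlignment], read_lengths: dict[str, int] | None = None
) -> pd.DataFrame:
    """Export alignments as BED6; intervals are reconstructed from end3.

    Without ``read_lengths`` a 1 nt interval at the 3' terminus is written,
    which round-trips through :func:`import_alignments` unchanged.
    """
    rows = []
    for a in alignments:
        length = (read_lengths or {}).get(a.read_id, 1)
        if a.strand == "+":
            start, end = a.end3 - length, a.end3
        else:
            start, end = a.end3, a.end3 + length
        rows.append((a.contig, start, end, a.read_id, 0, a.strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def alignments_to_frame(
    alignments: Iterable[EndAlignment], dataset: str | None = None
) -> pd.DataFrame:
    df = pd.DataFrame(
        [(a.read_id, a.contig, a.strand, a.end3) for a in alignments],
        columns=["read_id", "contig", "strand", "end3"],
    )
    if dataset is not None:
        df["dataset"] = dataset
    return df
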