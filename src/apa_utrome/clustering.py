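"""Poly(A)-cluster building, filtering, gene attachment and cross-dataset merge.

The cluster caller turns mapped read 3' ends into genomic poly(A) clusters:

1. each 3' end is expanded to a +-5 nt fragment,
2. overlapping-or-bookended fragments on one contig+strand merge into clusters,
3. clusters whose downstream genomic context is A-rich (>=65% A within 20 nt)
   are flagged as internal-priming artifacts,
4. surviving clusters attach to the nearest same-strand gene whose 3'UTR
   window (stop codon to furthest annotated end + 100 nt) contains the
   cluster's representative site,
5. clusters from different datasets whose representative sites lie within
   <=5 nt merge transitively, and
6. clusters holding <5% of a 3'UTR's pooled reads are flagged as low usage.

Flagged clusters are retained for bookkeeping but excluded downstream.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, revcomp
from .readprep import EndAlignment

logger = logging.getLogger(__name__)

DEFAULT_FRAGMENT_FLANK = 5
DEFAULT_IP_A_FRACTION = 0.65
DEFAULT_IP_WINDOW = 20
DEFAULT_ATTACH_MAX_DOWNSTREAM = 100
DEFAULT_CROSS_MERGE_DISTANCE = 5
DEFAULT_MIN_USAGE = 0.05

FRAGMENT_COLUMNS = ["contig", "strand", "start", "end", "end3", "dataset"]


@dataclass
class PolyACluster:
    contig: str
    strand: str
    start: int
    end: int
    counts: dict[str, int]  # dataset -> read count
    end3_counts: Counter  # pooled end3 -> read count, for the representative
    representative_site: int
    gene_id: str | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def surviving(self) -> bool:
        return not self.flags


def _representative(end3_counts: Counter, strand: str) -> int:
    """Read-weighted modal end3; ties resolved to the most distal (3'-most)."""
    sign = 1 if strand == "+" else -1
    return max(end3_counts.items(), key=lambda kv: (kv[1], sign * kv[0]))[0]


def fragments_from_alignments(
    alignments: Iterable[EndAlignment] | pd.DataFrame,
    dataset: str = "default",
    contig_lengths: dict[str, int] | None = None,
    flank: int = DEFAULT_FRAGMENT_FLANK,
) -> pd.DataFrame:
    """One fragment per alignment: [end3-flank, end3+flank+1) clipped to contig."""
    if isinstance(alignments, pd.DataFrame):
        df = alignments.copy()
        if "dataset" not in df.columns:
            df["dataset"] = dataset
    else:
        df = pd.DataFrame(
            [(a.contig, a.strand, a.end3) for a in alignments],
            columns=["contig", "strand", "end3"],
        )
        df["dataset"] = dataset
    if df.empty:
        return pd.DataFrame(columns=FRAGMENT_COLUMNS)
    df["start"] = (df["end3"] - flank).clip(lower=0)
    df["end"] = df["end3"] + flank + 1
    if contig_lengths:
        limits = df["contig"].map(contig_lengths)
        df["end"] = np.minimum(df["end"], limits)
    return df[FRAGMENT_COLUMNS].reset_index(drop=True)


def merge_fragments(fragments: pd.DataFrame) -> list[PolyACluster]:
    """Merge overlapping-or-bookended fragments per contig+strand (gap 0)."""
    clusters: list[PolyACluster] = []
    if fragments.empty:
        return clusters
    for (contig, strand), group in fragments.groupby(["contig", "strand"], sort=True):
        g = group.sort_values(["start", "end"], kind="mergesort")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        end3s = g["end3"].to_numpy()
        datasets = g["dataset"].to_numpy()
        cur_start, cur_end = int(starts[0]), int(ends[0])
        members: list[int] = [0]
        for i in range(1, len(starts)):
            if starts[i] <= cur_end:  # overlap or bookended
                cur_end = max(cur_end, int(ends[i]))
                members.append(i)
            else:
                clusters.append(
                    _make_cluster(contig, strand, cur_start, cur_end, end3s, datasets, members)
                )
                cur_start, cur_end = int(starts[i]), int(ends[i])
                members = [i]
        clusters.append(
            _make_cluster(contig, strand, cur_start, cur_end, end3s, datasets, members)
        )
    return clusters


def _make_cluster(contig, strand, start, end, end3s, datasets, members) -> PolyACluster:
    counts: dict[str, int] = {}
    e3 = Counter()
    for i in members:
        counts[datasets[i]] = counts.get(datasets[i], 0) + 1
        e3[int(end3s[i])] += 1
    return PolyACluster(
        contig=contig,
        strand=strand,
        start=int(start),
        end=int(end),
        counts=counts,
        end3_counts=e3,
        representative_site=_representative(e3, strand),
    )


def filter_internal_priming(
    clusters: list[PolyACluster],
    genome: dict[str, str],
    a_fraction: float = DEFAULT_IP_A_FRACTION,
    window: int = DEFAULT_IP_WINDOW,
) -> list[PolyACluster]:
    """Flag clusters whose downstream genomic window is adenosine-rich.

    The window is the ``window`` nt immediately downstream (in transcription
    direction) of the cluster's 3' end; A content is measured on the
    transcribed strand. Truncated windows at contig edges are evaluated over
    the available bases.
    """
    for c in clusters:
        seq = genome[c.contig]
        if c.strand == "+":
            win = seq[c.end : c.end + window]
            n_a = win.upper().count("A")
        else:
            win = seq[max(0, c.start - window) : c.start]
            n_a = win.upper().count("T")  # A on the transcribed (minus) strand
        if win and n_a / len(win) >= a_fraction:
            c.flags.add("internal_priming")
    return clusters


@dataclass
class _GeneWindows:
    genes: list[GeneModel]
    lo: np.ndarray
    hi: np.ndarray
    max_width: int


def build_gene_windows(
    genes: Iterable[GeneModel], max_downstream: int = DEFAULT_ATTACH_MAX_DOWNSTREAM
) -> dict[tuple[str, str], _GeneWindows]:
    """Attachment windows per (contig, strand).

    A site is eligible for a gene iff it lies strictly past the stop codon and
    no more than ``max_downstream`` nt past the furthest annotated 3'UTR end.
    """
    grouped: dict[tuple[str, str], list[tuple[int, int, GeneModel]]] = {}
    for g in genes:
        if g.furthest_site is None:
            logger.warning("gene %s lacks an annotated 3'UTR end; ineligible", g.gene_id)
            continue
        if g.strand == "+":
            lo, hi = g.stop_end + 1, g.furthest_site + max_downstream
        else:
            lo, hi = g.furthest_site - max_downstream, g.stop_start - 1
        grouped.setdefault((g.contig, g.strand), []).append((lo, hi, g))
    out = {}
    for key, entries in grouped.items():
        entries.sort(key=lambda t: (t[0], t[1], t[2].gene_id))
        lo = np.array([e[0] for e in entries])
        hi = np.array([e[1] for e in entries])
        width = int((hi - lo).max()) + 1 if len(entries) else 0
        out[key] = _GeneWindows([e[2] for e in entries], lo, hi, width)
    return out


def attach_site(
    site: int, contig: str, strand: str, windows: dict[tuple[str, str], _GeneWindows]
) -> GeneModel | None:
    """Gene a cleavage site attaches to, or None.

    Among eligible same-strand genes the winner has the nearest furthest-UTR
    end; ties fall to the nearer stop codon, then to gene_id.
    """
    w = windows.get((contig, strand))
    if w is None:
        return None
    idx = int(np.searchsorted(w.lo, site, side="right"))
    best = None
    i = idx - 1
    while i >= 0 and w.lo[i] > site - w.max_width:
        if w.lo[i] <= site <= w.hi[i]:
            g = w.genes[i]
            key = (abs(site - g.furthest_site), abs(site - g.utr_anchor), g.gene_id)
            if best is None or key < best[0]:
                best = (key, g)
        i -= 1
    return best[1] if best else None


def attach_to_gene(
    clusters: list[PolyACluster],
    genes: Iterable[GeneModel],
    max_downstream: int = DEFAULT_ATTACH_MAX_DOWNSTREAM,
) -> list[PolyACluster]:
    """Attach surviving clusters to genes by their representative site."""
    windows = build_gene_windows(genes, max_downstream)
    for c in clusters:
        if not c.surviving:
            continue
        g = attach_site(c.representative_site, c.contig, c.strand, windows)
        c.gene_id = g.gene_id if g else None
    return clusters


def merge_across_datasets(
    clusters: Sequence[PolyACluster],
    max_distance: int = DEFAULT_CROSS_MERGE_DISTANCE,
) -> list[PolyACluster]:
    """Single-linkage merge of clusters whose representative sites are close.

    Clusters on the same contig, strand and gene whose representative sites
    lie within ``max_distance`` nt merge transitively; per-dataset counts are
    preserved and the representative site is recomputed as the read-weighted
    mode of the pooled end3s. Flagged clusters pass through unmerged.
    """
    merged: list[PolyACluster] = [c for c in clusters if not c.surviving]
    groups: dict[tuple, list[PolyACluster]] = {}
    for c in clusters:
        if c.surviving:
            groups.setdefault((c.contig, c.strand, c.gene_id), []).append(c)
    for _key, members in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1], str(kv[0][2]))):
        members.sort(key=lambda c: c.representative_site)
        chain: list[PolyACluster] = [members[0]]
        for c in members[1:]:
            if c.representative_site - chain[-1].representative_site <= max_distance:
                chain.append(c)
            else:
                merged.append(_combine(chain))
                chain = [c]
        merged.append(_combine(chain))
    return merged


def _combine(chain: list[PolyACluster]) -> PolyACluster:
    if len(chain) == 1:
        return chain[0]
    counts: dict[str, int] = {}
    e3: Counter = Counter()
    for c in chain:
        for ds, n in c.counts.items():
            counts[ds] = counts.get(ds, 0) + n
        e3.update(c.end3_counts)
    first = chain[0]
    return PolyACluster(
        contig=first.contig,
        strand=first.strand,
        start=min(c.start for c in chain),
        end=max(c.end for c in chain),
        counts=counts,
        end3_counts=e3,
        representative_site=_representative(e3, first.strand),
        gene_id=first.gene_id,
        flags=set(),
    )


def filter_low_usage(
    clusters: list[PolyACluster], min_usage: float = DEFAULT_MIN_USAGE
) -> list[PolyACluster]:
    """Flag clusters holding <``min_usage`` of a gene's pooled reads."""
    by_gene: dict[str, list[PolyACluster]] = {}
    for c in clusters:
        if c.surviving and c.gene_id is not None:
            by_gene.setdefault(c.gene_id, []).append(c)
    for members in by_gene.values():
        total = sum(c.total_reads for c in members)
        if total == 0:
            continue
        for c in members:
            if c.total_reads / total < min_usage:
                c.flags.add("low_usage")
    return clusters


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def clusters_to_frame(clusters: Iterable[PolyACluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        rows.append(
            {
                "contig": c.contig,
                "start": c.start,
                "end": c.end,
                "name": c.gene_id or ".",
                "score": c.total_reads,
                "strand": c.strand,
                "representative_site": c.representative_site,
                "counts": ",".join(f"{k}:{v}" for k, v in sorted(c.counts.items())),
                "flags": ",".join(sorted(c.flags)) or ".",
            }
        )
    return pd.DataFrame(rows)


def clusters_to_gff3(clusters: Iterable[PolyACluster]) -> str:
    lines = ["##gff-version 3"]
    for i, c in enumerate(clusters):
        if not c.surviving:
            continue
        attrs = f"ID=pac{i};representative_site={c.representative_site};reads={c.total_reads}"
        if c.gene_id:
            attrs += f";gene_id={c.gene_id}"
        lines.append(
            "\t".join(
                [c.contig, "apa_utrome", "polyA_site", str(c.start + 1), str(c.end),
                 str(c.total_reads), c.strand, ".", attrs]
            )
        )
    return "\n".join(lines) + "\n"
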