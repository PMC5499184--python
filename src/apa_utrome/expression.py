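"""Gene expression from 3'-end alignments: counts, FPKM, breadth, overlaps.

Expression is quantified per dataset (tissue.replicate) by attaching read 3'
ends to genes with the same rule the cluster caller uses, converting counts
to FPKM, and calling a gene expressed in a tissue when its replicate-summary
FPKM is >= 1 (genes below the threshold are ignored). Expression breadth
(tissue-restricted / intermediate / commonly transcribed) is classified from
the number of tissues in which a gene is expressed.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .clustering import DEFAULT_ATTACH_MAX_DOWNSTREAM, attach_site, build_gene_windows

DEFAULT_FPKM_THRESHOLD = 1.0

BREADTH_CLASSES = ("tissue_restricted", "intermediate", "commonly_transcribed")


def count_reads_per_gene(
    alignments: pd.DataFrame,
    genes: Sequence[GeneModel],
    max_downstream: int = DEFAULT_ATTACH_MAX_DOWNSTREAM,
) -> tuple[pd.DataFrame, pd.Series]:
    """Integer read counts per gene per dataset, plus unattached tallies.

    ``alignments`` needs columns contig, strand, end3, dataset. Attachment
    uses the same stop-codon-to-furthest-UTR-end+100nt rule as the cluster
    caller, applied per unique 3'-end position.
    """
    datasets = sorted(alignments["dataset"].unique()) if len(alignments) else []
    gene_ids = [g.gene_id for g in genes]
    counts = pd.DataFrame(0, index=gene_ids, columns=datasets, dtype=int)
    unattached = pd.Series(0, index=datasets, dtype=int)
    if not len(alignments):
        return counts, unattached
    windows = build_gene_windows(genes, max_downstream)
    sites = alignments[["contig", "strand", "end3"]].drop_duplicates()
    site_gene = {
        (r.contig, r.strand, r.end3): attach_site(int(r.end3), r.contig, r.strand, windows)
        for r in sites.itertuples(index=False)
    }
    for row in alignments.itertuples(index=False):
        g = site_gene[(row.contig, row.strand, row.end3)]
        if g is None:
            unattached[row.dataset] += 1
        else:
            counts.at[g.gene_id, row.dataset] += 1
    return counts, unattached


def fpkm(
    counts: pd.DataFrame,
    gene_lengths_kb: Mapping[str, float] | pd.Series,
    library_sizes: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = count / (gene length in kb x mapped reads in millions)."""
    lengths = pd.Series(gene_lengths_kb).reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for all genes")
    if library_sizes is None:
        sizes = counts.sum(axis=0).astype(float)
    else:
        sizes = pd.Series(library_sizes).reindex(counts.columns).astype(float)
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lengths, axis=0).div(sizes / 1e6, axis=1)


def call_expressed(
    fpkm_table: pd.DataFrame,
    dataset_tissues: Mapping[str, str],
    mode: str = "median_replicates",
    threshold: float = DEFAULT_FPKM_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize replicate FPKMs per tissue and call expressed genes.

    ``median_replicates`` takes the median across a tissue's replicates (with
    two replicates this is their mean); ``per_run`` takes the replicate mean.
    A gene is expressed in a tissue iff the summary FPKM is >= ``threshold``.
    Returns (summary_fpkm genes x tissues, boolean expressed table).
    """
    if mode not in ("median_replicates", "per_run"):
        raise ValueError(f"unknown mode {mode!r}")
    tissues = sorted(set(dataset_tissues.values()))
    summary = pd.DataFrame(index=fpkm_table.index, columns=tissues, dtype=float)
    for t in tissues:
        cols = [d for d in fpkm_table.columns if dataset_tissues[d] == t]
        if not cols:
            raise ValueError(f"tissue {t!r} has no replicate columns")
        block = fpkm_table[cols].to_numpy(dtype=float)
        summary[t] = np.median(block, axis=1) if mode == "median_replicates" else block.mean(axis=1)
    expressed = summary >= threshold
    return summary, expressed


def classify_breadth(
    expressed: pd.DataFrame,
    restricted_max: int = 1,
    common_min: int | None = None,
) -> pd.DataFrame:
    """Expression-breadth class per gene from tissue counts.

    ``tissue_restricted``: expressed in <= ``restricted_max`` tissues;
    ``commonly_transcribed``: in >= ``common_min`` tissues (default: all);
    ``intermediate`` otherwise. Cutoffs are recorded in ``DataFrame.attrs``.
    """
    n_tissues = expressed.shape[1]
    if common_min is None:
        common_min = n_tissues
    if not restricted_max < common_min:
        raise ValueError("restricted_max must be below common_min")
    n_expr = expressed.sum(axis=1).astype(int)
    cls = pd.Series("intermediate", index=expressed.index)
    cls[n_expr <= restricted_max] = "tissue_restricted"
    cls[n_expr >= common_min] = "commonly_transcribed"
    out = pd.DataFrame({"n_tissues_expressed": n_expr, "breadth_class": cls})
    out.attrs["restricted_max"] = restricted_max
    out.attrs["common_min"] = common_min
    return out


def overlap_sets(
    expressed: pd.DataFrame, tissue_grouping: Mapping[str, Sequence[str]]
) -> dict[frozenset, int]:
    """Venn-style region counts over tissue groups.

    ``tissue_grouping`` must partition the tissue panel. A gene belongs to a
    group when it is expressed in at least one member tissue; the returned
    dict maps each non-empty combination of groups to the number of genes
    expressed in exactly those groups.
    """
    all_members = [t for ts in tissue_grouping.values() for t in ts]
    if len(set(all_members)) != len(all_members):
        raise ValueError("tissue groups overlap")
    if set(all_members) != set(expressed.columns):
        raise ValueError("tissue grouping does not partition the tissue panel")
    regions: dict[frozenset, int] = {}
    for _gene, row in expressed.iterrows():
        groups = frozenset(
            g for g, ts in tissue_grouping.items() if any(row[t] for t in ts)
        )
        if groups:
            regions[groups] = regions.get(groups, 0) + 1
    return regions
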