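"""miRNA target overlay: target fates under APA, loss fractions, family ranks.

Target sites live in 3'UTR-relative coordinates (0-based, half-open,
measured from the first base after the stop codon). A site is retained by an
isoform when the isoform's 3'UTR fully contains the seed span; a site whose
span crosses the cleavage site is treated as non-functional (lost) for that
isoform. Per tissue, a target is lost when the gene is expressed there but
every detected isoform ends at or before the seed span.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import revcomp
from .utrome import UTRIsoform

logger = logging.getLogger(__name__)

TARGET_COLUMNS = ["mirna_id", "family_id", "gene_id", "utr_start", "utr_end", "source"]
SEED_LENGTH = 7  # positions 2-8 of the miRNA


def load_target_table(
    table: str | pd.DataFrame,
    longest_utr: Mapping[str, int],
    family_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Validate a target table against the longest detected 3'UTR per gene.

    Expects columns mirna (or mirna_id), gene (or gene_id), start, end, with
    an optional family column. Sites falling past the gene's longest UTR (or
    on unknown genes) are dropped with a warning count; duplicate
    (mirna, gene, start) rows are deduplicated. Returns (table, n_dropped).
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t")
    df = df.rename(
        columns={"mirna": "mirna_id", "gene": "gene_id", "start": "utr_start", "end": "utr_end",
                 "family": "family_id"}
    )
    for col in ("mirna_id", "gene_id", "utr_start", "utr_end"):
        if col not in df.columns:
            raise ValueError(f"target table lacks column {col!r}")
    if "family_id" not in df.columns:
        df["family_id"] = df["mirna_id"]
    if family_map is not None:
        df["family_id"] = df["mirna_id"].map(lambda m: family_map.get(m, m))
    if "source" not in df.columns:
        df["source"] = "table"
    df = df.drop_duplicates(subset=["mirna_id", "gene_id", "utr_start"])
    limits = df["gene_id"].map(lambda g: longest_utr.get(g, -1))
    in_utr = (df["utr_start"] >= 0) & (df["utr_end"] <= limits)
    n_dropped = int((~in_utr).sum())
    if n_dropped:
        logger.warning("dropped %d target sites outside the longest detected 3'UTR", n_dropped)
    return df[in_utr][TARGET_COLUMNS].reset_index(drop=True), n_dropped


def infer_families(mirna_sequences: Mapping[str, str]) -> dict[str, str]:
    """Group miRNAs sharing identical seed (positions 2-8) into families."""
    seeds: dict[str, str] = {}
    families = {}
    for name in sorted(mirna_sequences):
        seed = mirna_sequences[name][1 : 1 + SEED_LENGTH].upper().replace("T", "U")
        families[name] = seeds.setdefault(seed, name)
    return families


def seed_scan(
    mirna_sequences: Mapping[str, str],
    utr_sequences: Mapping[str, str],
    family_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """7mer-m8 seed matching: reverse complements of miRNA positions 2-8.

    Returns one row per match with 3'UTR-relative half-open coordinates.
    """
    if family_map is None:
        family_map = infer_families(mirna_sequences)
    rows = []
    for name in sorted(mirna_sequences):
        seq = mirna_sequences[name].upper().replace("U", "T")
        if len(seq) < 8:
            raise ValueError(f"miRNA {name} shorter than 8 nt")
        site = revcomp(seq[1 : 1 + SEED_LENGTH])  # target-site sequence, DNA
        for gene in sorted(utr_sequences):
            utr = utr_sequences[gene].upper().replace("U", "T")
            start = utr.find(site)
            while start != -1:
                rows.append((name, family_map.get(name, name), gene,
                             start, start + SEED_LENGTH, "seed_scan"))
                start = utr.find(site, start + 1)
    return pd.DataFrame(rows, columns=TARGET_COLUMNS)


FATE_RETAINED = "retained"
FATE_LOST = "lost"
FATE_NOT_EXPRESSED = "gene_not_expressed"


def assign_target_fates(
    targets: pd.DataFrame,
    isoforms: Sequence[UTRIsoform],
    expressed: pd.DataFrame,
) -> pd.DataFrame:
    """Per-tissue fate of every target site.

    retained: some isoform detected in the tissue covers the full seed span;
    lost: the gene is expressed in the tissue but every detected isoform ends
    at or before the span; gene_not_expressed otherwise.
    """
    tissues = list(expressed.columns)
    longest_detected: dict[tuple[str, str], int] = {}
    for iso in isoforms:
        for t in tissues:
            if iso.detected.get(t, False):
                key = (iso.gene_id, t)
                longest_detected[key] = max(longest_detected.get(key, 0), iso.utr_length)
    rows = []
    for idx, tgt in targets.iterrows():
        gene = tgt["gene_id"]
        for t in tissues:
            if gene not in expressed.index or not bool(expressed.at[gene, t]):
                status = FATE_NOT_EXPRESSED
            elif longest_detected.get((gene, t), 0) >= int(tgt["utr_end"]):
                status = FATE_RETAINED
            else:
                status = FATE_LOST
            rows.append((idx, tgt["mirna_id"], tgt["family_id"], gene, t, status))
    return pd.DataFrame(
        rows, columns=["target_index", "mirna_id", "family_id", "gene_id", "tissue", "status"]
    )


def target_loss_fraction(fates: pd.DataFrame, scope: str = "overall"):
    """Fraction lost among retained+lost fates (unexpressed genes excluded)."""
    if scope == "overall":
        lost = int((fates["status"] == FATE_LOST).sum())
        retained = int((fates["status"] == FATE_RETAINED).sum())
        if lost + retained == 0:
            return float("nan")
        return lost / (lost + retained)
    if scope == "per_tissue":
        return {
            t: target_loss_fraction(sub, "overall") for t, sub in fates.groupby("tissue")
        }
    raise ValueError(f"unknown scope {scope!r}")


def family_enrichment_rank(
    targets: pd.DataFrame,
    expressed: pd.DataFrame,
    fates: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Per-tissue family rankings by expressed-target and lost-target counts.

    Families are ranked by descending count with alphabetical tie-break; a
    rank-change table across tissues is included for the expressed ranking.
    """
    tissues = list(expressed.columns)
    frames = {}
    for kind, mask_status in (("expressed", (FATE_RETAINED, FATE_LOST)), ("lost", (FATE_LOST,))):
        rows = []
        for t in tissues:
            sub = fates[(fates["tissue"] == t) & (fates["status"].isin(mask_status))]
            counts = sub.groupby("family_id").size().sort_index()
            ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            for rank, (family, n) in enumerate(ranked, start=1):
                rows.append((t, family, int(n), rank))
        frames[kind] = pd.DataFrame(rows, columns=["tissue", "family_id", "count", "rank"])
    ranks = frames["expressed"].pivot(index="family_id", columns="tissue", values="rank")
    ranks["rank_range"] = ranks.max(axis=1) - ranks.min(axis=1)
    frames["rank_change"] = ranks
    return frames


def target_presence_by_breadth(
    targets: pd.DataFrame, breadth: pd.DataFrame
) -> dict[str, float]:
    """Per breadth class, the fraction of genes carrying >=1 target site."""
    with_target = set(targets["gene_id"])
    out = {}
    for cls, sub in breadth.groupby("breadth_class"):
        if len(sub) == 0:
            raise ValueError(f"empty breadth class {cls!r}")
        out[cls] = sum(1 for g in sub.index if g in with_target) / len(sub)
    if not out:
        raise ValueError("no breadth classes supplied")
    return out
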