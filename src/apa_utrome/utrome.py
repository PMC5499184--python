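"""Per-tissue 3'UTR isoform catalogs: usage, APA rates, switches, PAS classes.

Each surviving, gene-attached poly(A) cluster defines one 3'UTR isoform whose
length runs from the first base after the stop codon through the last
transcribed base. Per-tissue usage is the tissue's read share among the
gene's surviving clusters; an isoform is "detected" in a tissue when it has
at least one read there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, revcomp
from .clustering import PolyACluster

CANONICAL_PAS = "AAUAAA"
CANONICAL_PAS_DNA = "AATAAA"
DEFAULT_PAS_WINDOW = 40

# all 18 single-substitution variants of the canonical hexamer (DNA alphabet)
PAS_VARIANTS_DNA = tuple(
    CANONICAL_PAS_DNA[:i] + b + CANONICAL_PAS_DNA[i + 1 :]
    for i in range(6)
    for b in "ACGT"
    if b != CANONICAL_PAS_DNA[i]
)


@dataclass
class UTRIsoform:
    gene_id: str
    cleavage_site: int
    utr_length: int
    usage: dict[str, float]  # tissue -> fraction among detected isoforms
    detected: dict[str, bool]
    tissue_counts: dict[str, int]
    pas_class: str = "unclassified"

    @property
    def detected_anywhere(self) -> bool:
        return any(self.detected.values())


def call_isoforms(
    clusters: Sequence[PolyACluster],
    genes: Iterable[GeneModel],
    dataset_tissues: Mapping[str, str],
    min_detect_reads: int = 1,
) -> list[UTRIsoform]:
    """One isoform per surviving gene-attached cluster, with per-tissue usage."""
    gene_map = {g.gene_id: g for g in genes}
    tissues = sorted(set(dataset_tissues.values()))
    by_gene: dict[str, list[PolyACluster]] = {}
    for c in clusters:
        if c.surviving and c.gene_id is not None:
            by_gene.setdefault(c.gene_id, []).append(c)
    isoforms: list[UTRIsoform] = []
    for gene_id in sorted(by_gene):
        gene = gene_map[gene_id]
        members = sorted(by_gene[gene_id], key=lambda c: gene.utr_length_of(c.representative_site))
        counts = np.zeros((len(members), len(tissues)), dtype=int)
        for i, c in enumerate(members):
            for ds, n in c.counts.items():
                counts[i, tissues.index(dataset_tissues[ds])] += n
        totals = counts.sum(axis=0)
        for i, c in enumerate(members):
            usage = {}
            detected = {}
            tcounts = {}
            for j, t in enumerate(tissues):
                tcounts[t] = int(counts[i, j])
                detected[t] = counts[i, j] >= min_detect_reads
                usage[t] = float(counts[i, j] / totals[j]) if totals[j] > 0 else 0.0
            isoforms.append(
                UTRIsoform(
                    gene_id=gene_id,
                    cleavage_site=c.representative_site,
                    utr_length=gene.utr_length_of(c.representative_site),
                    usage=usage,
                    detected=detected,
                    tissue_counts=tcounts,
                )
            )
    return isoforms


def classify_pas(
    contig: str,
    strand: str,
    cleavage_site: int,
    genome: dict[str, str],
    window: int = DEFAULT_PAS_WINDOW,
) -> str:
    """PAS class of a cleavage site from its upstream sequence window.

    Scans the ``window`` nt upstream of the site on the transcribed strand:
    canonical if AAUAAA occurs anywhere, otherwise the closest-to-site
    single-substitution variant, otherwise none.
    """
    seq = genome[contig]
    if strand == "+":
        win = seq[max(0, cleavage_site - window) : cleavage_site].upper()
    else:
        win = revcomp(seq[cleavage_site : cleavage_site + window]).upper()
    if CANONICAL_PAS_DNA in win:
        return "canonical"
    variants = set(PAS_VARIANTS_DNA)
    for start in range(len(win) - 6, -1, -1):  # closest to the site first
        hexamer = win[start : start + 6]
        if hexamer in variants:
            return "variant:" + hexamer.replace("T", "U")
    return "none"


def classify_isoforms(
    isoforms: Iterable[UTRIsoform],
    genes: Iterable[GeneModel],
    genome: dict[str, str],
    window: int = DEFAULT_PAS_WINDOW,
) -> None:
    gene_map = {g.gene_id: g for g in genes}
    for iso in isoforms:
        g = gene_map[iso.gene_id]
        iso.pas_class = classify_pas(g.contig, g.strand, iso.cleavage_site, genome, window)


def apa_rate(isoforms: Sequence[UTRIsoform]) -> dict:
    """Fractions of genes using >=2 3'UTR isoforms, per tissue and overall.

    ``per_tissue``: among genes detected in the tissue, the fraction with
    >=2 isoforms detected there. ``mean_across_tissues`` averages those.
    ``anywhere``: fraction of cataloged genes with >=2 isoforms detected in
    at least one tissue each.
    """
    if not isoforms:
        raise ValueError("empty isoform catalog")
    tissues = sorted(isoforms[0].detected)
    by_gene: dict[str, list[UTRIsoform]] = {}
    for iso in isoforms:
        by_gene.setdefault(iso.gene_id, []).append(iso)
    per_tissue = {}
    for t in tissues:
        detected_genes = 0
        multi = 0
        for members in by_gene.values():
            n = sum(1 for iso in members if iso.detected[t])
            if n >= 1:
                detected_genes += 1
                if n >= 2:
                    multi += 1
        per_tissue[t] = multi / detected_genes if detected_genes else float("nan")
    anywhere = sum(
        1
        for members in by_gene.values()
        if sum(1 for iso in members if iso.detected_anywhere) >= 2
    ) / len(by_gene)
    valid = [v for v in per_tissue.values() if not np.isnan(v)]
    return {
        "per_tissue": per_tissue,
        "mean_across_tissues": float(np.mean(valid)) if valid else float("nan"),
        "anywhere": anywhere,
    }


def switch_matrix(isoforms: Sequence[UTRIsoform]) -> pd.DataFrame:
    """Proximal/distal preference matrix for genes with exactly two isoforms.

    Cell values: 'proximal' or 'distal' by majority usage (exact ties fall to
    'distal'), 'n/a' where the gene is undetected in the tissue.
    """
    tissues = sorted(isoforms[0].detected) if isoforms else []
    by_gene: dict[str, list[UTRIsoform]] = {}
    for iso in isoforms:
        by_gene.setdefault(iso.gene_id, []).append(iso)
    rows = {}
    for gene_id in sorted(by_gene):
        members = by_gene[gene_id]
        if len(members) != 2:
            continue
        proximal, distal = sorted(members, key=lambda i: i.utr_length)
        row = {}
        for t in tissues:
            if not (proximal.detected[t] or distal.detected[t]):
                row[t] = "n/a"
            elif proximal.usage[t] > 0.5:
                row[t] = "proximal"
            else:
                row[t] = "distal"
        rows[gene_id] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=tissues)


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Lower weighted median: smallest value whose cumulative weight reaches
    half the total."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    total = w.sum()
    if total <= 0:
        raise ValueError("non-positive total weight")
    cum = np.cumsum(w)
    return float(v[int(np.searchsorted(cum, total / 2.0))])


def length_stats(
    isoforms: Sequence[UTRIsoform],
    weighting: str = "per_isoform",
    bins: int | Sequence[float] = 10,
) -> dict[str, dict]:
    """Per-tissue median 3'UTR length and histogram over detected isoforms."""
    if weighting not in ("per_isoform", "usage_weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    tissues = sorted(isoforms[0].detected) if isoforms else []
    out = {}
    for t in tissues:
        lengths = [iso.utr_length for iso in isoforms if iso.detected[t]]
        if not lengths:
            raise ValueError(f"no detected isoforms in tissue {t!r}")
        if weighting == "per_isoform":
            median = float(np.median(lengths))
            weights = np.ones(len(lengths))
        else:
            weights = [iso.usage[t] for iso in isoforms if iso.detected[t]]
            median = weighted_median(lengths, weights)
        hist, edges = np.histogram(lengths, bins=bins, weights=np.asarray(weights, dtype=float))
        out[t] = {"median": median, "histogram": (hist.tolist(), edges.tolist())}
    return out


def breadth_length_comparison(
    isoforms: Sequence[UTRIsoform],
    breadth_classes: Mapping[str, str],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Longest-detected-isoform length distributions per expression-breadth class.

    Reports per-class mean/median and the commonly_transcribed minus
    tissue_restricted difference of means with a seeded bootstrap CI.
    """
    longest: dict[str, int] = {}
    for iso in isoforms:
        if iso.detected_anywhere:
            longest[iso.gene_id] = max(longest.get(iso.gene_id, 0), iso.utr_length)
    per_class: dict[str, list[int]] = {}
    for gene_id, length in longest.items():
        cls = breadth_classes.get(gene_id)
        if cls is not None:
            per_class.setdefault(cls, []).append(length)
    summary = {
        cls: {
            "n": len(v),
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "lengths": sorted(v),
        }
        for cls, v in per_class.items()
    }
    result = {"per_class": summary}
    common = per_class.get("commonly_transcribed", [])
    restricted = per_class.get("tissue_restricted", [])
    if common and restricted:
        diff = float(np.mean(common) - np.mean(restricted))
        rng = np.random.default_rng(seed)
        common_arr = np.asarray(common, dtype=float)
        restr_arr = np.asarray(restricted, dtype=float)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = rng.choice(common_arr, len(common_arr)).mean() - rng.choice(
                restr_arr, len(restr_arr)
            ).mean()
        result["mean_difference"] = diff
        result["ci95"] = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return result


def isoforms_to_frame(isoforms: Sequence[UTRIsoform]) -> pd.DataFrame:
    tissues = sorted(isoforms[0].detected) if isoforms else []
    rows = []
    for iso in isoforms:
        row = {
            "gene_id": iso.gene_id,
            "cleavage_site": iso.cleavage_site,
            "utr_length": iso.utr_length,
            "pas_class": iso.pas_class,
        }
        for t in tissues:
            row[f"usage.{t}"] = iso.usage[t]
            row[f"detected.{t}"] = iso.detected[t]
        rows.append(row)
    return pd.DataFrame(rows)


def isoforms_to_gff3(isoforms: Sequence[UTRIsoform], genes: Iterable[GeneModel]) -> str:
    gene_map = {g.gene_id: g for g in genes}
    lines = ["##gff-version 3"]
    for i, iso in enumerate(isoforms):
        g = gene_map[iso.gene_id]
        if g.strand == "+":
            start, end = g.utr_anchor, iso.cleavage_site
        else:
            start, end = iso.cleavage_site, g.utr_anchor
        usage = ",".join(f"{t}:{iso.usage[t]:.4f}" for t in sorted(iso.usage))
        lines.append(
            "\t".join(
                [
                    g.contig, "apa_utrome", "three_prime_UTR", str(start + 1), str(end), ".",
                    g.strand, ".",
                    f"ID=utr{i};Parent={iso.gene_id};pas_class={iso.pas_class};usage={usage}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
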