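"""Synthetic genome, 3'-end read and miRNA-target generator with ground truth.

The simulator emulates the statistical structure a tissue-specific APA
analysis assumes: genes carry 1-3 cleavage sites, each preceded 10-30 nt
upstream by a PAS hexamer (canonical AAUAAA for a configurable fraction,
single-substitution variants otherwise); per-tissue isoform usage mixtures;
polyA-tailed reads (tails >= 23 nt) ending exactly at cleavage sites;
A-rich genomic decoys that produce internal-priming reads; short-tailed
contaminant reads; and seed-match miRNA target sites embedded in the UTR
sequence, biased toward distal 3'UTR extensions.

Sequence-level guarantees the generator enforces so that ground truth is
exactly recoverable (see docs/methods.md): the base immediately 5' of every
true cleavage site is non-A, the 30 nt downstream of every true site hold at
most 12 adenosines on the transcribed strand, and the 40 nt PAS search
window upstream of each site contains no PAS-like hexamer other than the
planted one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, revcomp
from .utrome import CANONICAL_PAS_DNA

BASES = "ACGT"
NON_A = "CGT"

# Embedded 7-nt target-site sequences per miRNA family (low A content so
# they can never form PAS-like hexamers or A-rich windows).
DEFAULT_FAMILY_SITES: dict[str, str] = {
    "miR-2": "CTGCTCC",
    "miR-58.1": "GTCGATC",
    "let-7": "CTGCCTC",
    "miR-50": "GTGTCGC",
    "lin-4": "CTCAGGG",
    "miR-1": "GTCCATG",
}

_MIRNA_FILLER = "CGUACGUACGUACG"  # 3' filler to pad simulated miRNAs to 22 nt


def family_mirna_sequences(families: Sequence[str]) -> dict[str, str]:
    """Simulated 22-nt miRNA sequences whose 7mer-m8 seed matches the
    embedded family site."""
    out = {}
    for fam in families:
        site = DEFAULT_FAMILY_SITES[fam]
        seed = revcomp(site).replace("T", "U")
        out[fam] = "U" + seed + _MIRNA_FILLER
    return out


@dataclass
class SimConfig:
    """Study conditions for the synthetic APA experiment.

    Defaults describe a desk-scale eight-tissue panel: ~50 3'-end reads per
    gene per dataset, 40% of genes with 2-3 cleavage sites, canonical PAS at
    39%, pure-A internal-priming decoys at a 10% read rate, and predicted
    miRNA targets at high density with a strong distal bias.
    """

    n_genes: int = 100
    n_tissues: int = 8
    n_replicates_per_tissue: int = 2
    isoforms_per_gene: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1}
    )
    apa_gene_fraction: float = 0.4
    utr_length_range: tuple[int, int] = (80, 800)
    proximal_length_spread: int = 40
    isoform_gap_range: tuple[int, int] = (250, 350)
    cds_length: int = 150
    tail_length_range: tuple[int, int] = (23, 60)
    contaminant_rate: float = 0.05
    contaminant_tail_range: tuple[int, int] = (5, 22)
    internal_priming_rate: float = 0.1
    decoy_a_content: float = 1.0
    n_decoys: int = 20
    decoy_length: int = 30
    reads_per_gene_mean: float = 50.0
    read_length_range: tuple[int, int] = (30, 50)
    seed: int = 0
    target_density: float = 10.0  # expected targets per kb of longest 3'UTR
    distal_target_bias: float = 0.95
    canonical_pas_fraction: float = 0.39
    pas_distance_range: tuple[int, int] = (10, 30)
    min_isoform_usage: float = 0.1
    usage_dirichlet_alpha: float = 3.0
    common_gene_fraction: float = 0.3
    restricted_gene_fraction: float = 0.3
    gene_expression_sigma: float = 0.8
    common_length_bonus: int = 100
    planted_loss_fraction: float | None = None
    target_presence_by_class: Mapping[str, float] | None = None
    mirna_families: tuple[str, ...] = tuple(DEFAULT_FAMILY_SITES)
    contig_count: int = 2
    contig_length: int = 100_000
    intergenic_gap_range: tuple[int, int] = (150, 400)
    tail_error_rate: float = 0.0

    def validate(self) -> None:
        proportions = {
            "apa_gene_fraction": self.apa_gene_fraction,
            "contaminant_rate": self.contaminant_rate,
            "internal_priming_rate": self.internal_priming_rate,
            "distal_target_bias": self.distal_target_bias,
            "canonical_pas_fraction": self.canonical_pas_fraction,
            "common_gene_fraction": self.common_gene_fraction,
            "restricted_gene_fraction": self.restricted_gene_fraction,
            "tail_error_rate": self.tail_error_rate,
        }
        for name, value in proportions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.planted_loss_fraction is not None and not 0 <= self.planted_loss_fraction <= 1:
            raise ValueError("planted_loss_fraction must be in [0, 1]")
        if self.common_gene_fraction + self.restricted_gene_fraction > 1:
            raise ValueError("breadth-class fractions exceed 1")
        if self.utr_length_range[0] < 30:
            raise ValueError("minimum 3'UTR length must be >= 30 nt")
        if self.utr_length_range[0] > self.utr_length_range[1]:
            raise ValueError("bad utr_length_range")
        if not 0.65 <= self.decoy_a_content <= 1.0:
            raise ValueError("decoy_a_content must be >= 0.65")
        if self.tail_length_range[0] < 23:
            raise ValueError("true-read tails must support >= 23 nt")
        if self.contaminant_tail_range[1] >= 23:
            raise ValueError("contaminant tails must stay below 23 nt")
        if not all(f in DEFAULT_FAMILY_SITES for f in self.mirna_families):
            unknown = [f for f in self.mirna_families if f not in DEFAULT_FAMILY_SITES]
            raise ValueError(f"unknown miRNA families {unknown}")
        if self.min_isoform_usage * 3 > 1:
            raise ValueError("min_isoform_usage too large for 3-isoform genes")

    @property
    def tissues(self) -> list[str]:
        return [f"t{i + 1:02d}" for i in range(self.n_tissues)]

    @property
    def datasets(self) -> list[tuple[str, str]]:
        return [
            (t, f"rep{r + 1}")
            for t in self.tissues
            for r in range(self.n_replicates_per_tissue)
        ]


@dataclass
class GeneTruth:
    gene_id: str
    breadth_class: str
    expressed_tissues: tuple[str, ...]
    expression_factor: float
    utr_lengths: tuple[int, ...]
    pas_hexamers: tuple[str, ...]  # RNA alphabet, per site
    pas_classes: tuple[str, ...]  # canonical / variant
    contig: str = ""
    strand: str = "+"
    cleavage_sites: tuple[int, ...] = ()
    transcript_length: int = 0
    usage: dict[str, tuple[float, ...]] = field(default_factory=dict)
    anchor_tissue: str | None = None

    @property
    def n_isoforms(self) -> int:
        return len(self.utr_lengths)

    @property
    def is_apa(self) -> bool:
        return self.n_isoforms >= 2


@dataclass(frozen=True)
class Decoy:
    contig: str
    strand: str
    end3: int  # trimmed-read 3'-end coordinate implied by priming at the run
    length: int


@dataclass
class GroundTruth:
    genes: dict[str, GeneTruth]
    targets: pd.DataFrame
    decoys: list[Decoy]
    mirna_sequences: dict[str, str]
    config: SimConfig
    mean_transcript_length: float

    def usage_table(self) -> pd.DataFrame:
        rows = []
        for g in self.genes.values():
            for tissue, fractions in sorted(g.usage.items()):
                for idx, frac in enumerate(fractions):
                    rows.append((g.gene_id, tissue, idx, g.utr_lengths[idx], frac))
        return pd.DataFrame(
            rows, columns=["gene_id", "tissue", "isoform_index", "utr_length", "usage"]
        )

    def sites_bed(self) -> pd.DataFrame:
        rows = []
        for g in self.genes.values():
            for idx, site in enumerate(g.cleavage_sites):
                start, end = (site - 1, site) if g.strand == "+" else (site, site + 1)
                rows.append((g.contig, start, end, f"{g.gene_id}.site{idx}", 0, g.strand))
        return pd.DataFrame(rows, columns=["contig", "start", "end", "name", "score", "strand"])

    def breadth_table(self) -> pd.DataFrame:
        rows = [
            (g.gene_id, g.breadth_class, len(g.expressed_tissues),
             ",".join(g.expressed_tissues))
            for g in self.genes.values()
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "breadth_class", "n_tissues_expressed", "tissues"]
        )


# ---------------------------------------------------------------------------
# Target placement zones
# ---------------------------------------------------------------------------

_SITE_GUARD_UP = 46  # keeps targets out of the PAS search window + its hexamer
_SITE_GUARD_DOWN = 30  # keeps targets out of the scrubbed downstream window


def _forbidden_spans(utr_lengths: Sequence[int]) -> list[tuple[int, int]]:
    spans = [(0, 10)]
    for L in utr_lengths:
        spans.append((L - _SITE_GUARD_UP, L + _SITE_GUARD_DOWN))
    return spans


def _allowed_starts(lo: int, hi: int, forbidden: list[tuple[int, int]], span: int = 7) -> list[int]:
    return [
        s
        for s in range(lo, hi + 1)
        if all(s + span <= f0 or s >= f1 for f0, f1 in forbidden)
    ]


def target_zones(utr_lengths: Sequence[int]) -> tuple[list[int], list[int]]:
    """(proximal, distal) allowed target start offsets for one gene."""
    forbidden = _forbidden_spans(utr_lengths)
    l1, lmax = utr_lengths[0], utr_lengths[-1]
    proximal = _allowed_starts(10, l1 - 7, forbidden)
    distal = _allowed_starts(l1, lmax - 7, forbidden) if len(utr_lengths) > 1 else []
    return proximal, distal


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

_PAS_LIKE = {CANONICAL_PAS_DNA}
for _i in range(6):
    for _b in BASES:
        if _b != CANONICAL_PAS_DNA[_i]:
            _PAS_LIKE.add(CANONICAL_PAS_DNA[:_i] + _b + CANONICAL_PAS_DNA[_i + 1 :])


def _random_bases(rng: np.random.Generator, n: int) -> list[str]:
    return [BASES[i] for i in rng.integers(0, 4, size=n)]


def _scrub_a_content(seq: list[str], start: int, end: int, rng, max_a: int = 12) -> None:
    """Cap adenosine count in seq[start:end] at ``max_a`` (in place)."""
    idx = [i for i in range(start, min(end, len(seq))) if seq[i] == "A"]
    excess = len(idx) - max_a
    if excess > 0:
        for i in rng.permutation(len(idx))[:excess]:
            seq[idx[i]] = NON_A[rng.integers(0, 3)]


def _scrub_pas_window(
    seq: list[str], win_start: int, win_end: int, planted_start: int, rng
) -> None:
    """Remove PAS-like hexamers from seq[win_start:win_end] except the
    planted one. Mutations only move hexamers away from the canonical
    sequence and never introduce adenosines, so no new PAS can appear."""
    planted_span = range(planted_start, planted_start + 6)
    for s in range(win_start, win_end - 5):
        if s == planted_start:
            continue
        hexamer = "".join(seq[s : s + 6])
        if hexamer not in _PAS_LIKE:
            continue
        mismatches = sum(1 for j in range(6) if seq[s + j] != CANONICAL_PAS_DNA[j])
        for j in range(6):
            if mismatches >= 2:
                break
            p = s + j
            if p in planted_span or seq[p] != CANONICAL_PAS_DNA[j]:
                continue
            seq[p] = "C" if CANONICAL_PAS_DNA[j] != "C" else "G"
            mismatches += 1


@dataclass
class _GenePlan:
    truth: GeneTruth
    sequence: list[str]  # transcript + 30 nt terminator, transcribed strand
    pas_starts: tuple[int, ...]  # transcript coords of planted hexamers
    target_rows: list[dict]


def _plan_gene(
    gene_id: str,
    breadth: str,
    is_apa: bool,
    has_targets: bool | None,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> _GenePlan:
    tissues = cfg.tissues
    if breadth == "tissue_restricted":
        expressed = tuple(rng.choice(tissues, size=1, replace=False))
    elif breadth == "commonly_transcribed":
        expressed = tuple(tissues)
    else:
        k = int(rng.integers(2, cfg.n_tissues)) if cfg.n_tissues > 2 else 1
        expressed = tuple(sorted(rng.choice(tissues, size=k, replace=False)))
    sigma = cfg.gene_expression_sigma
    factor = float(rng.lognormal(-sigma * sigma / 2.0, sigma)) if sigma > 0 else 1.0

    # isoform count and UTR lengths
    if is_apa:
        weights = np.array(
            [cfg.isoforms_per_gene.get(2, 0.0), cfg.isoforms_per_gene.get(3, 0.0)], float
        )
        k_iso = 2 if weights.sum() <= 0 else int(rng.choice([2, 3], p=weights / weights.sum()))
    else:
        k_iso = 1
    utr_min, utr_max = cfg.utr_length_range
    gap_min, gap_max = cfg.isoform_gap_range
    budget = utr_max - gap_min * (k_iso - 1)
    if budget < utr_min:
        raise ValueError("utr_length_range too narrow for the isoform gap range")
    l1 = int(rng.integers(utr_min, min(utr_min + cfg.proximal_length_spread, budget) + 1))
    lengths = [l1]
    for i in range(1, k_iso):
        remaining = k_iso - 1 - i
        cap = utr_max - lengths[-1] - gap_min * remaining
        gap = int(rng.integers(gap_min, min(gap_max, cap) + 1))
        lengths.append(lengths[-1] + gap)
    if breadth == "commonly_transcribed" and cfg.common_length_bonus:
        lengths[-1] += cfg.common_length_bonus

    # PAS per site
    pas_hexamers, pas_classes, pas_starts = [], [], []
    d_lo, d_hi = cfg.pas_distance_range
    for L in lengths:
        if rng.random() < cfg.canonical_pas_fraction:
            hexamer = CANONICAL_PAS_DNA
            pas_classes.append("canonical")
        else:
            pos = int(rng.integers(0, 6))
            alt = [b for b in BASES if b != CANONICAL_PAS_DNA[pos]]
            hexamer = (
                CANONICAL_PAS_DNA[:pos]
                + alt[int(rng.integers(0, 3))]
                + CANONICAL_PAS_DNA[pos + 1 :]
            )
            pas_classes.append("variant:" + hexamer.replace("T", "U"))
        d = int(rng.integers(d_lo, d_hi + 1))
        pas_hexamers.append(hexamer.replace("T", "U"))
        pas_starts.append(cfg.cds_length + L - d - 6)

    # transcript + terminator sequence
    total = cfg.cds_length + lengths[-1]
    seq = _random_bases(rng, total + _SITE_GUARD_DOWN)
    seq[cfg.cds_length - 3 : cfg.cds_length] = list("TAA")
    for start, hexamer in zip(pas_starts, pas_hexamers):
        seq[start : start + 6] = list(hexamer.replace("U", "T"))

    # targets (placed before scrubbing; zones avoid all scrubbed windows)
    proximal_zone, distal_zone = target_zones(lengths)
    target_rows = _place_targets(
        gene_id, lengths, has_targets, proximal_zone, distal_zone, cfg, rng
    )
    used: list[tuple[int, int]] = []
    for row in target_rows:
        s = row["utr_start"]
        seq[cfg.cds_length + s : cfg.cds_length + s + 7] = list(
            DEFAULT_FAMILY_SITES[row["family_id"]]
        )
        used.append((s, s + 7))

    # recoverability guarantees
    for L in lengths:
        pos = cfg.cds_length + L - 1
        if seq[pos] == "A":
            seq[pos] = NON_A[rng.integers(0, 3)]
        _scrub_a_content(seq, cfg.cds_length + L, cfg.cds_length + L + _SITE_GUARD_DOWN, rng)
    for L, planted in zip(lengths, pas_starts):
        _scrub_pas_window(seq, cfg.cds_length + L - 40, cfg.cds_length + L, planted, rng)

    truth = GeneTruth(
        gene_id=gene_id,
        breadth_class=breadth,
        expressed_tissues=expressed,
        expression_factor=factor,
        utr_lengths=tuple(lengths),
        pas_hexamers=tuple(pas_hexamers),
        pas_classes=tuple(pas_classes),
        transcript_length=total,
    )
    return _GenePlan(truth, seq, tuple(pas_starts), target_rows)


def _place_targets(
    gene_id: str,
    lengths: Sequence[int],
    has_targets: bool | None,
    proximal_zone: list[int],
    distal_zone: list[int],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[dict]:
    lmax_kb = lengths[-1] / 1000.0
    if has_targets is not None:
        n = 1 + int(rng.poisson(cfg.target_density * lmax_kb)) if has_targets else 0
    else:
        n = int(rng.poisson(cfg.target_density * lmax_kb))
    families = list(cfg.mirna_families)
    weights = np.arange(len(families), 0, -1, dtype=float)
    weights /= weights.sum()
    rows: list[dict] = []
    used: list[tuple[int, int]] = []
    for i in range(n):
        want_distal = bool(distal_zone) and rng.random() < cfg.distal_target_bias
        zone = distal_zone if want_distal else proximal_zone or distal_zone
        if not zone:
            continue
        placed = None
        for _try in range(30):
            s = int(zone[rng.integers(0, len(zone))])
            if all(s + 7 <= a or s >= b for a, b in used):
                placed = s
                break
        if placed is None:
            continue
        used.append((placed, placed + 7))
        family = str(rng.choice(families, p=weights))
        rows.append(
            {
                "target_id": f"{gene_id}.tg{i}",
                "mirna_id": family,
                "family_id": family,
                "gene_id": gene_id,
                "utr_start": placed,
                "utr_end": placed + 7,
                "distal": placed >= lengths[0],
                "source": "table",
            }
        )
    return rows


def _exact_count_subset(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask selecting round(fraction*n) random members.

    Planted fractions are structural (exact counts), so the conditions a run
    states are the conditions it gets, up to rounding.
    """
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[: round(fraction * n)]] = True
    return mask


def _assign_gene_conditions(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, list[bool | None]]:
    n = cfg.n_genes
    n_restricted = round(cfg.restricted_gene_fraction * n)
    n_common = round(cfg.common_gene_fraction * n)
    perm = rng.permutation(n)
    breadth = ["intermediate"] * n
    for i in perm[:n_restricted]:
        breadth[i] = "tissue_restricted"
    for i in perm[n_restricted : n_restricted + n_common]:
        breadth[i] = "commonly_transcribed"
    apa = _exact_count_subset(n, cfg.apa_gene_fraction, rng)
    has_targets: list[bool | None] = [None] * n
    if cfg.target_presence_by_class is not None:
        for cls, p in sorted(cfg.target_presence_by_class.items()):
            members = [i for i in range(n) if breadth[i] == cls]
            chosen = _exact_count_subset(len(members), p, rng)
            for j, i in enumerate(members):
                has_targets[i] = bool(chosen[j])
    return breadth, apa, has_targets


def generate_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[GeneModel], GroundTruth]:
    """Build the synthetic genome, gene annotation and full ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    breadth, apa, has_targets = _assign_gene_conditions(config, rng)
    plans = [
        _plan_gene(f"g{i + 1:04d}", breadth[i], bool(apa[i]), has_targets[i], config, rng)
        for i in range(config.n_genes)
    ]

    # layout genes and decoys across contigs
    contig_names = [f"chr{i + 1}" for i in range(config.contig_count)]
    contigs: dict[str, list[str]] = {c: [] for c in contig_names}
    cursors = {c: 0 for c in contig_names}

    def _pad(contig: str, n: int) -> None:
        contigs[contig].append("".join(_random_bases(rng, n)))
        cursors[contig] += n

    for c in contig_names:
        _pad(c, 100)

    genes: list[GeneModel] = []
    gap_lo, gap_hi = config.intergenic_gap_range
    decoy_specs = [("decoy", i) for i in range(config.n_decoys)]
    items: list[tuple[str, int]] = [("gene", i) for i in range(len(plans))]
    # interleave decoys between genes deterministically
    merged_items: list[tuple[str, int]] = []
    stride = max(1, len(items) // max(1, len(decoy_specs)))
    di = 0
    for j, it in enumerate(items):
        merged_items.append(it)
        if di < len(decoy_specs) and (j + 1) % stride == 0:
            merged_items.append(decoy_specs[di])
            di += 1
    merged_items.extend(decoy_specs[di:])

    decoys: list[Decoy] = []
    for j, (kind, idx) in enumerate(merged_items):
        contig = contig_names[j % len(contig_names)]
        _pad(contig, int(rng.integers(gap_lo, gap_hi + 1)))
        start = cursors[contig]
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "gene":
            plan = plans[idx]
            full = "".join(plan.sequence)
            footprint = len(full)
            tlen = plan.truth.transcript_length
            if strand == "+":
                tx_start = start
                stop_start = start + config.cds_length - 3
                anchor = start + config.cds_length
                sites = tuple(anchor + L for L in plan.truth.utr_lengths)
                contigs[contig].append(full)
            else:
                tx_start = start + footprint - tlen
                anchor = start + footprint - config.cds_length
                stop_start = anchor
                sites = tuple(anchor - L for L in plan.truth.utr_lengths)
                contigs[contig].append(revcomp(full))
            plan.truth.contig = contig
            plan.truth.strand = strand
            plan.truth.cleavage_sites = sites
            if strand == "+":
                genes.append(
                    GeneModel(
                        gene_id=plan.truth.gene_id,
                        contig=contig,
                        strand="+",
                        stop_start=stop_start,
                        stop_end=stop_start + 3,
                        furthest_site=sites[-1],
                        tx_start=tx_start,
                        tx_end=tx_start + tlen,
                    )
                )
            else:
                genes.append(
                    GeneModel(
                        gene_id=plan.truth.gene_id,
                        contig=contig,
                        strand="-",
                        stop_start=stop_start,
                        stop_end=stop_start + 3,
                        furthest_site=sites[-1],
                        tx_start=tx_start,
                        tx_end=start + footprint,
                    )
                )
            cursors[contig] += footprint
        else:
            prefix = _random_bases(rng, 60)
            run = [
                ("A" if rng.random() < config.decoy_a_content else NON_A[rng.integers(0, 3)])
                for _ in range(config.decoy_length)
            ]
            if strand == "+":
                if prefix[-1] == "A":
                    prefix[-1] = NON_A[rng.integers(0, 3)]
                contigs[contig].append("".join(prefix) + "".join(run))
                end3 = start + 60
            else:
                if prefix[-1] == "A":
                    prefix[-1] = NON_A[rng.integers(0, 3)]
                # minus-strand decoy: T-run then rev-comp'd prefix on the contig
                contigs[contig].append(
                    "".join("T" if b == "A" else ("A" if b == "T" else b) for b in run)[::-1]
                    + revcomp("".join(prefix))
                )
                end3 = start + config.decoy_length
            decoys.append(Decoy(contig, strand, end3, config.decoy_length))
            cursors[contig] += 60 + config.decoy_length
        if cursors[contig] > config.contig_length - 100:
            raise ValueError(
                "contig_length too small for the requested genes/decoys; increase it"
            )

    for c in contig_names:
        _pad(c, config.contig_length - cursors[c])
    genome = {c: "".join(parts) for c, parts in contigs.items()}

    truth = GroundTruth(
        genes={p.truth.gene_id: p.truth for p in plans},
        targets=_targets_frame([row for p in plans for row in p.target_rows]),
        decoys=decoys,
        mirna_sequences=family_mirna_sequences(config.mirna_families),
        config=config,
        mean_transcript_length=float(
            np.mean([p.truth.transcript_length for p in plans])
        ),
    )
    _plant_usage(truth, rng)
    return genome, genes, truth


def _targets_frame(rows: list[dict]) -> pd.DataFrame:
    columns = [
        "target_id", "mirna_id", "family_id", "gene_id", "utr_start", "utr_end",
        "distal", "source",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns]


def _plant_usage(truth: GroundTruth, rng: np.random.Generator) -> None:
    """Assign per-tissue isoform usage; optionally plant a target-loss rate.

    With ``planted_loss_fraction`` set, each APA gene keeps one anchor tissue
    with mixed usage while every other expressed tissue uses only the
    proximal site with probability p = loss / phi, where phi is the share of
    target x expressed-tissue pairs that sit distal on APA genes with a
    non-anchor tissue - computed from the generator's own realized target
    placement, so the expected pooled loss equals the requested value.
    """
    cfg = truth.config
    p_short = 0.0
    if cfg.planted_loss_fraction is not None and len(truth.targets):
        n_expr = {g.gene_id: len(g.expressed_tissues) for g in truth.genes.values()}
        den = num = 0.0
        for row in truth.targets.itertuples(index=False):
            n = n_expr[row.gene_id]
            den += n
            if row.distal and truth.genes[row.gene_id].is_apa:
                num += n - 1
        phi = num / den if den else 0.0
        if phi <= 0 or cfg.planted_loss_fraction / phi > 0.98:
            raise ValueError(
                f"requested loss fraction {cfg.planted_loss_fraction} is not attainable "
                f"under the realized target placement (distal pair share {phi:.3f})"
            )
        p_short = cfg.planted_loss_fraction / phi

    min_u = cfg.min_isoform_usage
    alpha = cfg.usage_dirichlet_alpha
    for g in truth.genes.values():
        k = g.n_isoforms

        def _mixed(distal_dominant: bool = False) -> tuple[float, ...]:
            if k == 1:
                return (1.0,)
            raw = rng.dirichlet([alpha] * k)
            if distal_dominant:
                # tissues running the long-3'UTR program use the distal
                # site predominantly: largest share goes to the distal site
                raw = np.sort(raw)
            return tuple(min_u + (1 - k * min_u) * raw)

        short_only = (1.0,) + (0.0,) * (k - 1)
        usage: dict[str, tuple[float, ...]] = {}
        if cfg.planted_loss_fraction is not None and g.is_apa and p_short > 0:
            anchor = str(rng.choice(list(g.expressed_tissues)))
            g.anchor_tissue = anchor
            for t in g.expressed_tissues:
                if t != anchor and rng.random() < p_short:
                    usage[t] = short_only
                else:
                    usage[t] = _mixed(distal_dominant=True)
        else:
            for t in g.expressed_tissues:
                usage[t] = _mixed()
        g.usage = usage


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _transcript_sequence(gene: GeneModel, truth: GeneTruth, genome: dict[str, str]) -> str:
    seq = genome[gene.contig]
    tlen = truth.transcript_length
    if gene.strand == "+":
        return seq[gene.tx_start : gene.tx_start + tlen]
    return revcomp(seq[gene.tx_end - tlen : gene.tx_end])


def simulate_reads(
    genome: dict[str, str],
    annotation: Sequence[GeneModel],
    truth: GroundTruth,
    tissue: str,
    replicate: str,
    seed: int,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate one dataset (tissue x replicate) of polyA-tailed reads.

    Returns (reads, truth_table): reads as (read_id, sequence) pairs and a
    table recording every read's origin (true-site, internal-priming decoy,
    or short-tail contaminant) and intended 3'-end coordinate.
    """
    cfg = truth.config
    if tissue not in cfg.tissues:
        raise ValueError(f"unknown tissue {tissue!r}")
    rng = np.random.default_rng(seed)
    gene_map = {g.gene_id: g for g in annotation}
    rl_lo, rl_hi = cfg.read_length_range
    tail_lo, tail_hi = cfg.tail_length_range

    reads: list[tuple[str, str]] = []
    truth_rows: list[tuple] = []

    def _emit(seq: str, origin: str, gene_id: str, iso: int, contig: str, strand: str, end3: int):
        rid = f"{tissue}_{replicate}_{len(reads):07d}"
        reads.append((rid, seq))
        truth_rows.append((rid, origin, gene_id, iso, contig, strand, end3))

    for gene_id in sorted(truth.genes):
        gt = truth.genes[gene_id]
        if tissue not in gt.expressed_tissues:
            continue
        gene = gene_map[gene_id]
        first_site_len = cfg.cds_length + gt.utr_lengths[0]
        if first_site_len < rl_hi:
            raise ValueError(
                f"gene {gene_id}: usable prefix {first_site_len} nt shorter than the "
                f"maximum trimmed-read length {rl_hi}"
            )
        tseq = _transcript_sequence(gene, gt, genome)
        lam = (
            cfg.reads_per_gene_mean
            * gt.expression_factor
            * gt.transcript_length
            / truth.mean_transcript_length
        )
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        usage = np.asarray(gt.usage[tissue])
        iso_idx = rng.choice(gt.n_isoforms, size=n, p=usage)
        lengths = rng.integers(rl_lo, rl_hi + 1, size=n)
        tails = rng.integers(tail_lo, tail_hi + 1, size=n)
        for i in range(n):
            iso = int(iso_idx[i])
            end_t = cfg.cds_length + gt.utr_lengths[iso]
            body = tseq[end_t - int(lengths[i]) : end_t]
            tail = "A" * int(tails[i])
            if cfg.tail_error_rate > 0:
                tail = "".join(
                    BASES[rng.integers(0, 4)] if rng.random() < cfg.tail_error_rate else "A"
                    for _ in tail
                )
            _emit(
                body + tail, "true", gene_id, iso, gt.contig, gt.strand,
                gt.cleavage_sites[iso],
            )

    n_true = len(reads)
    # internal-priming reads at decoys
    if cfg.internal_priming_rate > 0 and truth.decoys and n_true:
        rate = cfg.internal_priming_rate
        n_decoy_reads = int(rng.poisson(n_true * rate / (1.0 - rate)))
        for _ in range(n_decoy_reads):
            d = truth.decoys[int(rng.integers(0, len(truth.decoys)))]
            rl = int(rng.integers(rl_lo, rl_hi + 1))
            seq = genome[d.contig]
            if d.strand == "+":
                prefix = seq[d.end3 - rl : d.end3]
                run = seq[d.end3 : d.end3 + d.length]
            else:
                prefix = revcomp(seq[d.end3 : d.end3 + rl])
                run = revcomp(seq[d.end3 - d.length : d.end3])
            a_run = 0
            while a_run < len(run) and run[a_run] == "A":
                a_run += 1
            templated = min(int(rng.integers(10, d.length + 1)), a_run)
            untemplated = int(rng.integers(13, 26))
            _emit(
                prefix + "A" * (templated + untemplated), "decoy", "", -1,
                d.contig, d.strand, d.end3,
            )

    # short-tail contaminants
    if cfg.contaminant_rate > 0 and n_true:
        rate = cfg.contaminant_rate
        n_cont = int(rng.poisson(n_true * rate / (1.0 - rate)))
        contig_names = sorted(genome)
        for _ in range(n_cont):
            for _try in range(50):
                contig = contig_names[int(rng.integers(0, len(contig_names)))]
                seq = genome[contig]
                strand = "+" if rng.random() < 0.5 else "-"
                rl = int(rng.integers(rl_lo, rl_hi + 1))
                p = int(rng.integers(rl, len(seq) - rl))
                if strand == "+" and seq[p - 1] != "A":
                    body = seq[p - rl : p]
                    break
                if strand == "-" and seq[p] != "T":
                    body = revcomp(seq[p : p + rl])
                    break
            else:
                continue
            tail = "A" * int(
                rng.integers(cfg.contaminant_tail_range[0], cfg.contaminant_tail_range[1] + 1)
            )
            _emit(body + tail, "contaminant", "", -1, contig, strand, p)

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth_df = pd.DataFrame(
        [truth_rows[i] for i in order],
        columns=["read_id", "origin", "gene_id", "isoform_index", "contig", "strand", "end3"],
    )
    return reads, truth_df


def write_fastq(reads: Iterable[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Standalone target-table generation (no sequence embedding)
# ---------------------------------------------------------------------------

def generate_target_table(
    annotation: Sequence[GeneModel],
    truth: GroundTruth,
    config: SimConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample a fresh miRNA target table over the annotated 3'UTRs.

    Placement follows the same zoning rules as the embedded ground-truth
    targets (uniform within zones, a ``distal_target_bias`` fraction forced
    strictly downstream of the proximal cleavage site) but is independent of
    the genome sequence, emulating an externally supplied prediction table.
    """
    rng = np.random.default_rng(config.seed + 1_000_003 if seed is None else seed)
    gene_ids = sorted(truth.genes)
    has_targets: dict[str, bool | None] = {g: None for g in gene_ids}
    if config.target_presence_by_class is not None:
        for cls, p in sorted(config.target_presence_by_class.items()):
            members = [g for g in gene_ids if truth.genes[g].breadth_class == cls]
            chosen = _exact_count_subset(len(members), p, rng)
            for j, g in enumerate(members):
                has_targets[g] = bool(chosen[j])
    rows: list[dict] = []
    for gene_id in gene_ids:
        gt = truth.genes[gene_id]
        proximal, distal = target_zones(gt.utr_lengths)
        rows.extend(
            _place_targets(gene_id, gt.utr_lengths, has_targets[gene_id], proximal, distal,
                           config, rng)
        )
    return _targets_frame(rows)
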