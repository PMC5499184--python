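"""End-to-end driver: simulate -> readprep -> cluster -> utrome -> expr -> mirna.

A single :class:`PipelineConfig` holds every stage threshold (all defaults
follow the analysis conventions: tail >= 23 A, remainder >= 10 nt, +-5 nt
fragments, >=65% A in 20 nt for internal priming, <=100 nt gene attachment,
<=5 nt cross-dataset merge, <5% usage, FPKM >= 1). ``run_pipeline`` returns
a JSON-serializable report and, when ground truth is available, a
truth-versus-recovered comparison.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import clustering, expression, mirna, readprep, synthetic_data, utrome
from .annotation import GeneModel, write_fasta, write_gff3
from .synthetic_data import GroundTruth, SimConfig

logger = logging.getLogger(__name__)

CONFIG_VERSION = 1


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    min_tail: int = readprep.DEFAULT_MIN_TAIL
    min_remainder: int = readprep.DEFAULT_MIN_REMAINDER
    fragment_flank: int = clustering.DEFAULT_FRAGMENT_FLANK
    ip_a_fraction: float = clustering.DEFAULT_IP_A_FRACTION
    ip_window: int = clustering.DEFAULT_IP_WINDOW
    attach_max_downstream: int = clustering.DEFAULT_ATTACH_MAX_DOWNSTREAM
    cross_merge_distance: int = clustering.DEFAULT_CROSS_MERGE_DISTANCE
    min_usage: float = clustering.DEFAULT_MIN_USAGE
    fpkm_threshold: float = expression.DEFAULT_FPKM_THRESHOLD
    pas_window: int = utrome.DEFAULT_PAS_WINDOW

    def validate(self) -> None:
        if self.min_tail < 1 or self.min_remainder < 1:
            raise ValueError("tail and remainder thresholds must be positive")
        if not 0 < self.ip_a_fraction <= 1:
            raise ValueError("ip_a_fraction must be in (0, 1]")
        if not 0 <= self.min_usage < 1:
            raise ValueError("min_usage must be in [0, 1)")
        if min(self.fragment_flank, self.ip_window, self.attach_max_downstream,
               self.cross_merge_distance, self.pas_window) < 0:
            raise ValueError("window parameters must be non-negative")
        self.sim.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["isoforms_per_gene"] = {
            str(k): v for k, v in d["sim"]["isoforms_per_gene"].items()
        }
        d["version"] = CONFIG_VERSION
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        d.pop("version", None)
        sim_d = dict(d.pop("sim", {}))
        if "isoforms_per_gene" in sim_d:
            sim_d["isoforms_per_gene"] = {
                int(k): float(v) for k, v in sim_d["isoforms_per_gene"].items()
            }
        for key in ("utr_length_range", "isoform_gap_range", "tail_length_range",
                    "contaminant_tail_range", "read_length_range", "pas_distance_range",
                    "intergenic_gap_range", "mirna_families"):
            if key in sim_d and isinstance(sim_d[key], list):
                sim_d[key] = tuple(sim_d[key])
        return cls(sim=SimConfig(**sim_d), **d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _dataset_seed(seed: int, index: int) -> int:
    return (seed * 100_003 + 7_919 * index + 1) % (2**31 - 1)


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> dict:
    """Run the full synthetic-data APA pipeline and return the report."""
    config.validate()
    sim = replace(config.sim, seed=config.seed)
    genome, genes, truth = synthetic_data.generate_genome(sim)
    contig_lengths = {c: len(s) for c, s in genome.items()}
    index = readprep.GenomeIndex(genome)
    dataset_tissues = {f"{t}.{r}": t for t, r in sim.datasets}

    read_stats: dict[str, dict] = {}
    aln_frames: list[pd.DataFrame] = []
    clusters: list[clustering.PolyACluster] = []
    for i, (tissue, rep) in enumerate(sim.datasets):
        ds = f"{tissue}.{rep}"
        reads, _read_truth = synthetic_data.simulate_reads(
            genome, genes, truth, tissue, rep, seed=_dataset_seed(config.seed, i)
        )
        kept, rejections = readprep.extract_polya_reads(
            reads, config.min_tail, config.min_remainder
        )
        alignments, map_stats = readprep.map_trimmed_reads(kept, index)
        read_stats[ds] = {
            "total": len(reads),
            "kept": len(kept),
            "rejected": dict(sorted(rejections.counts.items())),
            **map_stats,
        }
        frame = readprep.alignments_to_frame(alignments, ds)
        aln_frames.append(frame)
        frags = clustering.fragments_from_alignments(
            frame, ds, contig_lengths, config.fragment_flank
        )
        ds_clusters = clustering.merge_fragments(frags)
        clustering.filter_internal_priming(
            ds_clusters, genome, config.ip_a_fraction, config.ip_window
        )
        clustering.attach_to_gene(ds_clusters, genes, config.attach_max_downstream)
        clusters.extend(ds_clusters)

    n_built = len(clusters)
    n_ip = sum(1 for c in clusters if "internal_priming" in c.flags)
    n_attached = sum(1 for c in clusters if c.surviving and c.gene_id)
    merged = clustering.merge_across_datasets(clusters, config.cross_merge_distance)
    clustering.filter_low_usage(merged, config.min_usage)
    n_low = sum(1 for c in merged if "low_usage" in c.flags)
    surviving = [c for c in merged if c.surviving and c.gene_id]

    isoforms = utrome.call_isoforms(merged, genes, dataset_tissues)
    utrome.classify_isoforms(isoforms, genes, genome, config.pas_window)
    apa = utrome.apa_rate(isoforms)
    switches = utrome.switch_matrix(isoforms)
    lengths = utrome.length_stats(isoforms)

    alignments_df = pd.concat(aln_frames, ignore_index=True)
    counts, unattached = expression.count_reads_per_gene(
        alignments_df, genes, config.attach_max_downstream
    )
    lengths_kb = {g.gene_id: (g.tx_end - g.tx_start) / 1000.0 for g in genes}
    library_sizes = counts.sum(axis=0) + unattached
    fpkm_df = expression.fpkm(counts, lengths_kb, library_sizes)
    summary_fpkm, expressed = expression.call_expressed(
        fpkm_df, dataset_tissues, threshold=config.fpkm_threshold
    )
    breadth = expression.classify_breadth(expressed)

    longest_detected: dict[str, int] = {}
    for iso in isoforms:
        if iso.detected_anywhere:
            longest_detected[iso.gene_id] = max(
                longest_detected.get(iso.gene_id, 0), iso.utr_length
            )
    targets, n_dropped = mirna.load_target_table(truth.targets, longest_detected)
    fates = mirna.assign_target_fates(targets, isoforms, expressed)
    loss_overall = mirna.target_loss_fraction(fates)
    loss_per_tissue = mirna.target_loss_fraction(fates, "per_tissue")
    presence = mirna.target_presence_by_breadth(targets, breadth)
    ranks = mirna.family_enrichment_rank(targets, expressed, fates)

    pas_counts = {"canonical": 0, "variant": 0, "none": 0}
    for iso in isoforms:
        key = iso.pas_class.split(":")[0]
        pas_counts[key] = pas_counts.get(key, 0) + 1
    n_iso = len(isoforms)

    switch_tally = {"proximal": 0, "distal": 0, "n/a": 0}
    for col in switches.columns:
        for v in switches[col]:
            switch_tally[v] += 1

    report = {
        "config": config.to_dict(),
        "reads": read_stats,
        "clusters": {
            "built": n_built,
            "internal_priming_flagged": n_ip,
            "gene_attached": n_attached,
            "after_cross_merge": len(merged),
            "low_usage_flagged": n_low,
            "surviving": len(surviving),
        },
        "apa": {
            "per_tissue": apa["per_tissue"],
            "mean_across_tissues": apa["mean_across_tissues"],
            "anywhere": apa["anywhere"],
        },
        "switch_matrix": {"genes": int(len(switches)), "cells": switch_tally},
        "utr_length_median_by_tissue": {t: s["median"] for t, s in lengths.items()},
        "pas": {
            **pas_counts,
            "canonical_fraction": pas_counts["canonical"] / n_iso if n_iso else float("nan"),
            "noncanonical_fraction": (
                (pas_counts["variant"] + pas_counts["none"]) / n_iso if n_iso else float("nan")
            ),
        },
        "expression": {
            "expressed_genes_by_tissue": {
                t: int(expressed[t].sum()) for t in expressed.columns
            },
            "breadth_counts": breadth["breadth_class"].value_counts().to_dict(),
        },
        "mirna": {
            "n_targets": int(len(targets)),
            "n_targets_dropped": int(n_dropped),
            "loss_fraction_overall": loss_overall,
            "loss_fraction_per_tissue": loss_per_tissue,
            "presence_by_breadth": presence,
            "top_families_expressed": ranks["expressed"][ranks["expressed"]["rank"] <= 3]
            .groupby("tissue")["family_id"]
            .apply(list)
            .to_dict(),
        },
        "truth_recovery": _truth_recovery(truth, merged, isoforms, breadth, loss_overall),
    }

    if outdir is not None:
        _write_outputs(outdir, genome, genes, truth, merged, isoforms, switches,
                       fpkm_df, breadth, targets, fates, report)
    return report


def _truth_recovery(
    truth: GroundTruth,
    clusters: list,
    isoforms: list,
    breadth: pd.DataFrame,
    loss_overall: float,
    tol: int = 2,
) -> dict:
    """Truth-versus-recovered comparison for the synthetic run."""
    recovered_sites: dict[str, list[int]] = {}
    for c in clusters:
        if c.surviving and c.gene_id:
            recovered_sites.setdefault(c.gene_id, []).append(c.representative_site)
    n_sites = n_matched = 0
    n_genes = n_count_match = 0
    for g in truth.genes.values():
        if not g.expressed_tissues:
            continue
        rec = recovered_sites.get(g.gene_id, [])
        n_genes += 1
        if len(rec) == g.n_isoforms:
            n_count_match += 1
        for site in g.cleavage_sites:
            n_sites += 1
            if rec and min(abs(r - site) for r in rec) <= tol:
                n_matched += 1
    rec_total = rec_matched = 0
    true_sites = {
        (g.contig, g.strand, s) for g in truth.genes.values() for s in g.cleavage_sites
    }
    flagged_true = 0
    for c in clusters:
        if "internal_priming" in c.flags:
            if any(
                c.contig == ct and c.strand == st and abs(c.representative_site - s) <= tol
                for ct, st, s in true_sites
            ):
                flagged_true += 1
        if c.surviving and c.gene_id:
            rec_total += 1
            g = truth.genes.get(c.gene_id)
            if g and min(abs(c.representative_site - s) for s in g.cleavage_sites) <= tol:
                rec_matched += 1
    decoy_positions = {(d.contig, d.strand, d.end3) for d in truth.decoys}
    decoy_seen = decoy_flagged = 0
    for c in clusters:
        key = (c.contig, c.strand, c.representative_site)
        if key in decoy_positions:
            decoy_seen += 1
            if "internal_priming" in c.flags:
                decoy_flagged += 1
    truth_breadth = {g.gene_id: g.breadth_class for g in truth.genes.values()}
    breadth_match = sum(
        1 for gid, cls in breadth["breadth_class"].items() if truth_breadth.get(gid) == cls
    )
    truth_apa = sum(1 for g in truth.genes.values() if g.is_apa) / max(1, len(truth.genes))
    return {
        "site_recovery_fraction": n_matched / n_sites if n_sites else float("nan"),
        "recovered_site_precision": rec_matched / rec_total if rec_total else float("nan"),
        "gene_cluster_count_match_fraction": (
            n_count_match / n_genes if n_genes else float("nan")
        ),
        "decoy_clusters_seen": decoy_seen,
        "decoy_flag_fraction": decoy_flagged / decoy_seen if decoy_seen else float("nan"),
        "true_site_clusters_flagged": flagged_true,
        "apa_fraction_truth": truth_apa,
        "breadth_class_accuracy": breadth_match / max(1, len(breadth)),
        "planted_loss_fraction": truth.config.planted_loss_fraction,
        "recovered_loss_fraction": loss_overall,
    }


def _write_outputs(outdir, genome, genes, truth, clusters, isoforms, switches,
                   fpkm_df, breadth, targets, fates, report) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_fasta(genome, os.path.join(outdir, "genome.fa"))
    write_gff3(genes, os.path.join(outdir, "annotation.gff3"))
    truth.usage_table().to_csv(os.path.join(outdir, "truth_usage.tsv"), sep="\t", index=False)
    truth.sites_bed().to_csv(
        os.path.join(outdir, "truth_sites.bed"), sep="\t", index=False, header=False
    )
    truth.breadth_table().to_csv(
        os.path.join(outdir, "truth_breadth.tsv"), sep="\t", index=False
    )
    clustering.clusters_to_frame(clusters).to_csv(
        os.path.join(outdir, "clusters.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "clusters.gff3"), "w") as fh:
        fh.write(clustering.clusters_to_gff3(clusters))
    utrome.isoforms_to_frame(isoforms).to_csv(
        os.path.join(outdir, "isoforms.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "isoforms.gff3"), "w") as fh:
        fh.write(utrome.isoforms_to_gff3(isoforms, genes))
    switches.to_csv(os.path.join(outdir, "switch_matrix.tsv"), sep="\t")
    fpkm_df.to_csv(os.path.join(outdir, "fpkm.tsv"), sep="\t")
    breadth.to_csv(os.path.join(outdir, "breadth.tsv"), sep="\t")
    targets.to_csv(os.path.join(outdir, "targets.tsv"), sep="\t", index=False)
    fates.to_csv(os.path.join(outdir, "target_fates.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        fh.write(report_to_json(report))


def report_to_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
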