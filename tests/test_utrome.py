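"""3'UTR isoform catalogs: usage, APA rates, switching, lengths, PAS classes."""

import itertools
from collections import Counter

import numpy as np
import pytest

from apa_utrome.annotation import GeneModel, revcomp
from apa_utrome.clustering import PolyACluster
from apa_utrome.utrome import (
    CANONICAL_PAS_DNA,
    PAS_VARIANTS_DNA,
    UTRIsoform,
    apa_rate,
    breadth_length_comparison,
    call_isoforms,
    classify_pas,
    length_stats,
    switch_matrix,
    weighted_median,
)


def _cluster(site, counts, gene="gA", strand="+"):
    return PolyACluster(
        contig="chrI", strand=strand, start=site - 5, end=site + 6,
        counts=counts, end3_counts=Counter({site: sum(counts.values())}),
        representative_site=site, gene_id=gene,
    )


def _iso(gene, length, usage, detected=None, site=0):
    detected = detected or {t: u > 0 for t, u in usage.items()}
    return UTRIsoform(
        gene_id=gene, cleavage_site=site, utr_length=length,
        usage=usage, detected=detected, tissue_counts={t: 0 for t in usage},
    )


GENE = GeneModel(gene_id="gA", contig="chrI", strand="+", stop_start=997,
                 stop_end=1000, furthest_site=1200)
DATASET_TISSUES = {"muscle.rep1": "muscle", "intestine.rep1": "intestine"}


def test_utr_length_and_usage_from_clusters():
    """Stop codon ending at 1000 with cleavage at 1041 gives a 41-nt 3'UTR."""
    short = _cluster(1041, {"muscle.rep1": 30, "intestine.rep1": 10})
    long = _cluster(1078, {"intestine.rep1": 30})
    isoforms = call_isoforms([short, long], [GENE], DATASET_TISSUES)
    assert [i.utr_length for i in isoforms] == [41, 78]
    assert isoforms[0].usage["muscle"] == 1.0
    assert isoforms[0].usage["intestine"] == 0.25
    assert isoforms[1].usage["intestine"] == 0.75
    assert not isoforms[1].detected["muscle"]
    # single-cluster gene: usage 1.0 wherever detected
    solo = call_isoforms([_cluster(1041, {"muscle.rep1": 5})], [GENE], DATASET_TISSUES)
    assert solo[0].usage["muscle"] == 1.0


def test_usage_sums_to_one_over_detected(default_report):
    for tissue, rate in default_report["apa"]["per_tissue"].items():
        assert 0.0 <= rate <= 1.0


def test_minus_strand_utr_length():
    gene = GeneModel(gene_id="gB", contig="chrI", strand="-", stop_start=2000,
                     stop_end=2003, furthest_site=1900)
    c = _cluster(1959, {"muscle.rep1": 4}, gene="gB", strand="-")
    isoforms = call_isoforms([c], [gene], DATASET_TISSUES)
    assert isoforms[0].utr_length == 41


# ---------------------------------------------------------------------------
# PAS classification
# ---------------------------------------------------------------------------

def _pas_oracle(window: str) -> str:
    """Brute force over all 4^6 hexamers in the window."""
    if CANONICAL_PAS_DNA in window:
        return "canonical"
    best = None
    for start in range(len(window) - 5):
        hexamer = window[start : start + 6]
        mismatches = sum(a != b for a, b in zip(hexamer, CANONICAL_PAS_DNA))
        if mismatches == 1:
            best = hexamer  # later (closer to site) occurrences overwrite
    return "variant:" + best.replace("T", "U") if best else "none"


def test_classify_pas_examples():
    win = "C" * 15 + "AATAAA" + "C" * 19  # canonical ending 19 nt upstream
    genome = {"chrI": "G" * 960 + win + "G" * 100}
    assert classify_pas("chrI", "+", 1000, genome) == "canonical"
    win_var = "C" * 15 + "AATGAA" + "C" * 19
    genome = {"chrI": "G" * 960 + win_var + "G" * 100}
    assert classify_pas("chrI", "+", 1000, genome) == "variant:AAUGAA"
    genome = {"chrI": "G" * 960 + "C" * 40 + "G" * 100}
    assert classify_pas("chrI", "+", 1000, genome) == "none"


def test_classify_pas_minus_strand():
    window = "C" * 10 + "AATAAA" + "C" * 24  # transcribed-strand window
    genome = {"chrI": "G" * 1000 + revcomp(window) + "G" * 100}
    assert classify_pas("chrI", "-", 1000, genome) == "canonical"


def test_classify_pas_matches_brute_force_oracle():
    rng = np.random.default_rng(11)
    bases = np.array(list("ACGT"))
    for _ in range(1000):
        window = "".join(rng.choice(bases, size=40))
        genome = {"chrI": "G" * 100 + window + "G" * 100}
        assert classify_pas("chrI", "+", 140, genome) == _pas_oracle(window)


def test_planted_pas_recovered(clean_world):
    """>=99% of isoform sites classify to the planted hexamer class."""
    cfg, genome, genes, truth = clean_world
    gene_map = {g.gene_id: g for g in genes}
    total = match = 0
    for gt in truth.genes.values():
        g = gene_map[gt.gene_id]
        for site, planted in zip(gt.cleavage_sites, gt.pas_classes):
            total += 1
            if classify_pas(g.contig, g.strand, site, genome) == planted:
                match += 1
    assert match / total >= 0.99


# ---------------------------------------------------------------------------
# APA rate
# ---------------------------------------------------------------------------

def test_apa_rate_constructed_31_percent():
    isoforms = []
    for i in range(100):
        gene = f"g{i:03d}"
        if i < 31:
            isoforms.append(_iso(gene, 50, {"muscle": 0.6}))
            isoforms.append(_iso(gene, 150, {"muscle": 0.4}))
        else:
            isoforms.append(_iso(gene, 50, {"muscle": 1.0}))
    rates = apa_rate(isoforms)
    assert rates["per_tissue"]["muscle"] == pytest.approx(0.31)
    assert rates["anywhere"] == pytest.approx(0.31)
    only_single = [_iso(f"g{i}", 50, {"muscle": 1.0}) for i in range(5)]
    assert apa_rate(only_single)["per_tissue"]["muscle"] == 0.0


def test_apa_rate_order_invariant():
    rng = np.random.default_rng(2)
    isoforms = []
    for i in range(50):
        for j in range(int(rng.integers(1, 4))):
            usage = {t: float(rng.random() > 0.3) for t in ("a", "b", "c")}
            isoforms.append(_iso(f"g{i}", 50 + 100 * j, usage))
    ref = apa_rate(isoforms)
    shuffled = [isoforms[k] for k in rng.permutation(len(isoforms))]
    assert apa_rate(shuffled) == ref


def test_apa_recovered_from_planted_fraction(default_report):
    """Pipeline recovers the generator's planted APA gene fraction."""
    rep = default_report
    assert rep["apa"]["anywhere"] == pytest.approx(
        rep["truth_recovery"]["apa_fraction_truth"], abs=0.05
    )


# ---------------------------------------------------------------------------
# switch matrix
# ---------------------------------------------------------------------------

def test_switch_matrix_cells():
    isoforms = [
        _iso("gA", 50, {"muscle": 0.8, "intestine": 0.5, "neuron": 0.0},
             detected={"muscle": True, "intestine": True, "neuron": False}),
        _iso("gA", 150, {"muscle": 0.2, "intestine": 0.5, "neuron": 0.0},
             detected={"muscle": True, "intestine": True, "neuron": False}),
        _iso("gB", 70, {"muscle": 1.0, "intestine": 0.0, "neuron": 0.0}),  # 1 isoform
    ]
    m = switch_matrix(isoforms)
    assert list(m.index) == ["gA"]  # only exactly-two-isoform genes
    assert m.loc["gA", "muscle"] == "proximal"
    assert m.loc["gA", "intestine"] == "distal"  # exact tie goes distal
    assert m.loc["gA", "neuron"] == "n/a"


# ---------------------------------------------------------------------------
# length statistics
# ---------------------------------------------------------------------------

def test_length_median_and_empty_tissue():
    isoforms = [
        _iso("g1", 41, {"muscle": 0.2}),
        _iso("g2", 78, {"muscle": 0.3}),
        _iso("g3", 200, {"muscle": 0.5}),
    ]
    stats = length_stats(isoforms)
    assert stats["muscle"]["median"] == 78
    empty = [_iso("g1", 41, {"muscle": 1.0, "ghost": 0.0},
                  detected={"muscle": True, "ghost": False})]
    with pytest.raises(ValueError, match="ghost"):
        length_stats(empty)


def _weighted_median_oracle(values, weights):
    total = sum(weights)
    acc = 0.0
    for v, w in sorted(zip(values, weights)):
        acc += w
        if acc >= total / 2:
            return v


def test_weighted_median_matches_oracle():
    rng = np.random.default_rng(5)
    for _ in range(100):
        n = int(rng.integers(1, 30))
        values = rng.integers(10, 500, size=n).tolist()
        weights = rng.random(n) + 0.01
        assert weighted_median(values, weights) == _weighted_median_oracle(values, weights)


def test_usage_weighted_length_stats():
    isoforms = [
        _iso("g1", 41, {"muscle": 0.9}),
        _iso("g1", 300, {"muscle": 0.1}),
    ]
    stats = length_stats(isoforms, weighting="usage_weighted")
    assert stats["muscle"]["median"] == 41


# ---------------------------------------------------------------------------
# breadth / length comparison
# ---------------------------------------------------------------------------

def test_breadth_length_comparison_constructed():
    isoforms = [_iso(f"c{i}", 300, {"m": 1.0}) for i in range(10)]
    isoforms += [_iso(f"r{i}", 100, {"m": 1.0}) for i in range(10)]
    classes = {f"c{i}": "commonly_transcribed" for i in range(10)}
    classes.update({f"r{i}": "tissue_restricted" for i in range(10)})
    res = breadth_length_comparison(isoforms, classes, seed=1)
    assert res["mean_difference"] == pytest.approx(200.0)
    identical = breadth_length_comparison(
        [_iso(f"c{i}", 100 + (i % 3), {"m": 1.0}) for i in range(20)]
        + [_iso(f"r{i}", 100 + (i % 3), {"m": 1.0}) for i in range(20)],
        {f"c{i}": "commonly_transcribed" for i in range(20)}
        | {f"r{i}": "tissue_restricted" for i in range(20)},
        seed=1,
    )
    lo, hi = identical["ci95"]
    assert lo <= 0.0 <= hi


def test_breadth_length_shift_recovered():
    """The generator's +100 nt common-gene extension is recovered within the
    bootstrap CI of the catalog's common-vs-restricted mean difference."""
    from apa_utrome.clustering import (
        attach_to_gene, filter_low_usage, fragments_from_alignments,
        merge_across_datasets, merge_fragments,
    )
    from apa_utrome.readprep import GenomeIndex, extract_polya_reads, map_trimmed_reads
    from apa_utrome.readprep import alignments_to_frame
    from apa_utrome.synthetic_data import SimConfig, generate_genome, simulate_reads

    cfg = SimConfig(
        n_genes=60, seed=17, internal_priming_rate=0.0, contaminant_rate=0.0,
        gene_expression_sigma=0.0, n_tissues=2, n_replicates_per_tissue=1,
        common_gene_fraction=0.5, restricted_gene_fraction=0.5,
        apa_gene_fraction=0.0,  # isolate the planted common-gene shift
    )
    genome, genes, truth = generate_genome(cfg)
    index = GenomeIndex(genome)
    clusters = []
    dataset_tissues = {}
    for i, (tissue, rep) in enumerate(cfg.datasets):
        ds = f"{tissue}.{rep}"
        dataset_tissues[ds] = tissue
        reads, _ = simulate_reads(genome, genes, truth, tissue, rep, seed=100 + i)
        kept, _ = extract_polya_reads(reads)
        alignments, _ = map_trimmed_reads(kept, index)
        frags = fragments_from_alignments(alignments_to_frame(alignments, ds), ds)
        ds_clusters = merge_fragments(frags)
        attach_to_gene(ds_clusters, genes)
        clusters.extend(ds_clusters)
    merged = merge_across_datasets(clusters)
    filter_low_usage(merged)
    isoforms = call_isoforms(merged, genes, dataset_tissues)
    classes = {g.gene_id: g.breadth_class for g in truth.genes.values()}
    res = breadth_length_comparison(isoforms, classes, seed=4)
    lo, hi = res["ci95"]
    assert lo <= cfg.common_length_bonus <= hi
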