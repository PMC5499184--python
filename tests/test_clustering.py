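"""Poly(A)-cluster building, filtering, attachment and cross-dataset merging."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apa_utrome.annotation import GeneModel
from apa_utrome.clustering import (
    PolyACluster,
    attach_site,
    attach_to_gene,
    build_gene_windows,
    filter_internal_priming,
    filter_low_usage,
    fragments_from_alignments,
    merge_across_datasets,
    merge_fragments,
)
from apa_utrome.readprep import EndAlignment

from conftest import brute_force_interval_union, brute_force_single_linkage


def _cluster(contig="chrI", strand="+", start=0, end=11, counts=None, site=5, gene=None):
    counts = counts or {"d1": 1}
    return PolyACluster(
        contig=contig, strand=strand, start=start, end=end, counts=counts,
        end3_counts=Counter({site: sum(counts.values())}), representative_site=site,
        gene_id=gene,
    )


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def test_fragment_window_arithmetic():
    """+-5 nt around end3, half-open, clipped at contig edges."""
    alns = [EndAlignment("r1", "chrI", "+", 1000), EndAlignment("r2", "chrI", "+", 2)]
    frags = fragments_from_alignments(alns, "d1", {"chrI": 100_000})
    assert list(frags.loc[0, ["start", "end"]]) == [995, 1006]
    assert list(frags.loc[1, ["start", "end"]]) == [0, 8]
    assert len(frags) == len(alns)


# ---------------------------------------------------------------------------
# merge_fragments vs brute-force interval-union oracle
# ---------------------------------------------------------------------------

def test_merge_two_overlapping_and_two_disjoint():
    df = pd.DataFrame(
        {
            "contig": "chrI", "strand": "+",
            "start": [995, 1000], "end": [1006, 1011],
            "end3": [1000, 1005], "dataset": "d1",
        }
    )
    clusters = merge_fragments(df)
    assert len(clusters) == 1
    assert (clusters[0].start, clusters[0].end) == (995, 1011)
    df2 = df.assign(start=[995, 1007], end=[1006, 1018])
    assert len(merge_fragments(df2)) == 2
    single = merge_fragments(df.iloc[:1])
    assert (single[0].start, single[0].end) == (995, 1006)


def test_merge_fragments_matches_interval_union_oracle():
    """Sweep merge equals the O(n^2) fixpoint union on 100 random instances."""
    rng = np.random.default_rng(42)
    for trial in range(100):
        n = int(rng.integers(1, 60))
        starts = rng.integers(0, 400, size=n)
        widths = rng.integers(1, 15, size=n)
        df = pd.DataFrame(
            {
                "contig": "chrI", "strand": "+",
                "start": starts, "end": starts + widths,
                "end3": starts + 5, "dataset": "d1",
            }
        )
        got = sorted((c.start, c.end) for c in merge_fragments(df))
        expected = brute_force_interval_union(list(zip(starts, starts + widths)))
        assert got == expected


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.tuples(st.integers(0, 300), st.integers(1, 12)), min_size=1, max_size=40)
)
def test_merge_fragments_interval_union_property(intervals):
    df = pd.DataFrame(
        {
            "contig": "chrI", "strand": "+",
            "start": [s for s, _ in intervals],
            "end": [s + w for s, w in intervals],
            "end3": [s + 5 for s, _ in intervals],
            "dataset": "d1",
        }
    )
    got = sorted((c.start, c.end) for c in merge_fragments(df))
    assert got == brute_force_interval_union([(s, s + w) for s, w in intervals])


def test_merge_conserves_reads_and_separates_strands():
    rng = np.random.default_rng(1)
    n = 200
    df = pd.DataFrame(
        {
            "contig": "chrI",
            "strand": rng.choice(["+", "-"], size=n),
            "start": rng.integers(0, 500, size=n),
            "dataset": rng.choice(["d1", "d2"], size=n),
        }
    )
    df["end"] = df["start"] + 11
    df["end3"] = df["start"] + 5
    clusters = merge_fragments(df)
    assert sum(c.total_reads for c in clusters) == n
    for c in clusters:
        assert all(c.start <= e < c.end for e in c.end3_counts)


def test_representative_site_modal_with_distal_tie_break():
    df = pd.DataFrame(
        {
            "contig": "chrI", "strand": "+",
            "start": [995, 995, 997], "end": [1006, 1006, 1008],
            "end3": [1000, 1000, 1002], "dataset": "d1",
        }
    )
    assert merge_fragments(df)[0].representative_site == 1000  # mode wins
    df_tie = df.assign(end3=[1000, 1002, 1002], start=[995, 997, 997], end=[1006, 1008, 1008])
    assert merge_fragments(df_tie)[0].representative_site == 1002
    # on the minus strand "distal" is the lower coordinate
    df_minus = pd.DataFrame(
        {
            "contig": "chrI", "strand": "-",
            "start": [995, 997], "end": [1006, 1008],
            "end3": [1000, 1002], "dataset": "d1",
        }
    )
    assert merge_fragments(df_minus)[0].representative_site == 1000


# ---------------------------------------------------------------------------
# internal-priming filter
# ---------------------------------------------------------------------------

def test_internal_priming_threshold_boundaries():
    """>=65% A in the 20 nt downstream flags a cluster; 60% does not."""
    win13 = "A" * 13 + "C" * 7
    win12 = "A" * 12 + "C" * 8
    genome = {"chrI": "G" * 1000 + win13 + "G" * 100, "chrII": "G" * 1000 + win12 + "G" * 100}
    c13 = _cluster(contig="chrI", start=989, end=1000, site=995)
    c12 = _cluster(contig="chrII", start=989, end=1000, site=995)
    allc = _cluster(contig="chrI", start=100, end=111, site=105)  # downstream all G
    filter_internal_priming([c13, c12, allc], genome)
    assert c13.flags == {"internal_priming"}
    assert c12.flags == set()
    assert allc.flags == set()


def test_internal_priming_minus_strand_and_truncated_window():
    # minus strand: window is upstream in genome coordinates, A = genomic T
    genome = {"chrI": "G" * 80 + "T" * 20 + "G" * 900}
    c = _cluster(strand="-", start=100, end=111, site=105)
    filter_internal_priming([c], genome)
    assert c.flags == {"internal_priming"}
    # truncated window at the contig end still uses the 65% rule
    genome2 = {"chrI": "G" * 990 + "AAAAAAAAAA"}  # 10 nt available, all A
    c2 = _cluster(start=979, end=990, site=984)
    filter_internal_priming([c2], genome2)
    assert c2.flags == {"internal_priming"}


# ---------------------------------------------------------------------------
# gene attachment
# ---------------------------------------------------------------------------

def _gene(gene_id="gA", strand="+", stop_start=997, furthest=1200, contig="chrI"):
    return GeneModel(
        gene_id=gene_id, contig=contig, strand=strand,
        stop_start=stop_start, stop_end=stop_start + 3, furthest_site=furthest,
    )


def test_attach_downstream_boundary_and_strand():
    """Attachment reaches exactly 100 nt past the furthest 3'UTR end."""
    gene = _gene()
    windows = build_gene_windows([gene])
    assert attach_site(1300, "chrI", "+", windows) is gene  # 100 nt past: attached
    assert attach_site(1301, "chrI", "+", windows) is None  # 101 nt past: not
    assert attach_site(1100, "chrI", "-", windows) is None  # wrong strand
    assert attach_site(1000, "chrI", "+", windows) is None  # stop codon exclusive
    assert attach_site(1001, "chrI", "+", windows) is gene


def test_attach_minus_strand_window():
    gene = _gene(strand="-", stop_start=1000, furthest=800)
    windows = build_gene_windows([gene])
    assert attach_site(999, "chrI", "-", windows) is gene
    assert attach_site(700, "chrI", "-", windows) is gene  # exactly 100 past
    assert attach_site(699, "chrI", "-", windows) is None
    assert attach_site(1000, "chrI", "-", windows) is None


def test_attach_prefers_nearest_furthest_utr_end():
    near = _gene("near", stop_start=500, furthest=1190)
    far = _gene("far", stop_start=200, furthest=1400)
    windows = build_gene_windows([near, far])
    assert attach_site(1200, "chrI", "+", windows).gene_id == "near"


def test_attach_to_gene_skips_flagged_clusters():
    gene = _gene()
    flagged = _cluster(start=1095, end=1106, site=1100)
    flagged.flags.add("internal_priming")
    ok = _cluster(start=1095, end=1106, site=1100)
    attach_to_gene([flagged, ok], [gene])
    assert flagged.gene_id is None
    assert ok.gene_id == "gA"


# ---------------------------------------------------------------------------
# cross-dataset merge
# ---------------------------------------------------------------------------

def test_cross_dataset_merge_distance_boundary():
    """Representative sites <=5 nt apart merge; 6 nt apart do not."""
    a = _cluster(counts={"d1": 3}, site=1000, start=995, end=1006, gene="g")
    b = _cluster(counts={"d2": 2}, site=1005, start=1000, end=1011, gene="g")
    merged = merge_across_datasets([a, b])
    assert len(merged) == 1
    assert merged[0].counts == {"d1": 3, "d2": 2}
    c = _cluster(counts={"d2": 2}, site=1006, start=1001, end=1012, gene="g")
    assert len(merge_across_datasets([a, c])) == 2


def test_cross_dataset_merge_transitive_chain():
    chain = [
        _cluster(counts={f"d{i}": 1}, site=1000 + 5 * i, start=995 + 5 * i,
                 end=1006 + 5 * i, gene="g")
        for i in range(3)
    ]
    merged = merge_across_datasets(chain)
    assert len(merged) == 1
    assert merged[0].total_reads == 3


def test_cross_dataset_merge_matches_single_linkage_oracle():
    """Transitive merge equals single-linkage clustering on 100 random sets."""
    rng = np.random.default_rng(7)
    for trial in range(100):
        n = int(rng.integers(1, 40))
        sites = [int(s) for s in rng.integers(0, 300, size=n)]
        clusters = [
            _cluster(counts={f"d{i}": 1}, site=s, start=s - 5, end=s + 6, gene="g")
            for i, s in enumerate(sites)
        ]
        merged = merge_across_datasets(clusters)
        got = sorted(sorted(c.end3_counts.elements()) for c in merged)
        assert got == brute_force_single_linkage(sites, 5)


def test_cross_dataset_merge_respects_gene_and_strand():
    a = _cluster(counts={"d1": 1}, site=1000, gene="g1")
    b = _cluster(counts={"d2": 1}, site=1002, gene="g2")
    c = _cluster(counts={"d2": 1}, site=1003, gene="g1", strand="-")
    assert len(merge_across_datasets([a, b, c])) == 3


def test_merge_weighted_mode_recomputed():
    a = _cluster(counts={"d1": 2}, site=1000, gene="g")
    a.end3_counts = Counter({1000: 2})
    b = _cluster(counts={"d2": 3}, site=1003, gene="g")
    b.end3_counts = Counter({1003: 3})
    merged = merge_across_datasets([a, b])
    assert merged[0].representative_site == 1003


# ---------------------------------------------------------------------------
# low-usage filter
# ---------------------------------------------------------------------------

def test_low_usage_boundary():
    """<5% of a gene's pooled reads is flagged; exactly 5% survives."""
    big = _cluster(counts={"d1": 96}, site=1000, gene="g")
    small = _cluster(counts={"d1": 4}, site=1500, gene="g")
    filter_low_usage([big, small])
    assert small.flags == {"low_usage"} and big.flags == set()
    a = _cluster(counts={"d1": 95}, site=1000, gene="g2")
    b = _cluster(counts={"d1": 5}, site=1500, gene="g2")
    filter_low_usage([a, b])
    assert a.flags == set() and b.flags == set()
    solo = _cluster(counts={"d1": 1}, site=1000, gene="g3")
    filter_low_usage([solo])
    assert solo.flags == set()


# ---------------------------------------------------------------------------
# order invariance
# ---------------------------------------------------------------------------

def test_output_independent_of_input_order():
    rng = np.random.default_rng(3)
    n = 120
    base = pd.DataFrame(
        {
            "contig": "chrI",
            "strand": rng.choice(["+", "-"], size=n),
            "end3": rng.integers(50, 400, size=n),
            "dataset": rng.choice(["d1", "d2", "d3"], size=n),
        }
    )
    base["start"] = base["end3"] - 5
    base["end"] = base["end3"] + 6

    def run(df):
        clusters = merge_fragments(df)
        merged = merge_across_datasets(
            [c for c in clusters], max_distance=5
        )
        return sorted(
            (c.contig, c.strand, c.start, c.end, c.representative_site,
             tuple(sorted(c.counts.items())))
            for c in merged
        )

    shuffled = base.sample(frac=1, random_state=99).reset_index(drop=True)
    assert run(base) == run(shuffled)
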