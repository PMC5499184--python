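"""Shared fixtures: small synthetic experiments generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from apa_utrome.pipeline import PipelineConfig, run_pipeline
from apa_utrome.synthetic_data import SimConfig, generate_genome


@pytest.fixture(scope="session")
def small_world():
    """A 30-gene synthetic genome with default (noisy) conditions."""
    cfg = SimConfig(n_genes=30, seed=7)
    genome, genes, truth = generate_genome(cfg)
    return cfg, genome, genes, truth


@pytest.fixture(scope="session")
def clean_world():
    """Noise-free 30-gene genome: no decoys, no contaminants, flat expression."""
    cfg = SimConfig(
        n_genes=30,
        seed=13,
        internal_priming_rate=0.0,
        contaminant_rate=0.0,
        gene_expression_sigma=0.0,
        common_gene_fraction=1.0,
        restricted_gene_fraction=0.0,
    )
    genome, genes, truth = generate_genome(cfg)
    return cfg, genome, genes, truth


@pytest.fixture(scope="session")
def default_report():
    """Full pipeline report on a 40-gene default-condition run."""
    cfg = PipelineConfig(seed=3)
    cfg.sim.n_genes = 40
    return run_pipeline(cfg)


def brute_force_interval_union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """O(n^2) fixpoint merge of overlapping-or-bookended intervals."""
    merged = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                a, b = merged[i], merged[j]
                if a[0] <= b[1] and b[0] <= a[1]:  # overlap or bookended
                    merged[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    merged.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(iv) for iv in merged)


def brute_force_single_linkage(points: list[int], cutoff: int) -> list[list[int]]:
    """O(n^2) single-linkage clustering of 1-D points with a distance cutoff."""
    groups = [[p] for p in sorted(points)]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(abs(a - b) <= cutoff for a in groups[i] for b in groups[j]):
                    groups[i] = sorted(groups[i] + groups[j])
                    groups.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(groups)
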