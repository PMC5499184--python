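# apa-utrome

Tissue-specific **alternative polyadenylation (APA)** analysis for 3'-end
RNA-seq: call poly(A) clusters from polyA-tailed reads, build per-tissue
3'UTR isoform catalogs, quantify APA and proximal/distal isoform switching,
overlay miRNA target predictions to measure APA-induced target loss, and
quantify a dual-fluorophore miRNA-escape reporter. A first-class synthetic
data module generates desk-scale experiments with complete ground truth, so
every stage can be validated by parameter recovery.

## The problem

Most metazoan genes can cleave and polyadenylate their transcripts at more
than one position, producing 3'UTR isoforms of different lengths. Because
miRNA target sites live in 3'UTRs, a tissue that switches to a proximal
cleavage site sheds the distal portion of the UTR — and with it any miRNA
sites located there — letting broadly transcribed genes escape repression in
specific tissues. Measuring this requires (i) precise cleavage-site calls
from 3'-end sequencing, (ii) per-tissue isoform usage, and (iii) an overlay
of target annotations onto the per-tissue UTR catalog.

## Method

Reads carrying an untemplated poly(A) tail pinpoint cleavage sites. The
cluster caller implements, in order:

1. **Read selection/trimming** — keep a read iff its maximal terminal run of
   A is ≥ 23 nt and the remainder after trimming is ≥ 10 nt.
2. **Mapping** — unique perfect match of the trimmed read (both strands);
   multi-mappers are dropped. The read's 3' terminus `end3` is the candidate
   cleavage position (half-open convention: one past the last base on `+`,
   the first coordinate on `-`).
3. **Fragments → clusters** — each `end3` becomes a ±5 nt fragment;
   overlapping-or-bookended fragments on one contig/strand merge into a
   poly(A) cluster whose *representative site* is the read-weighted modal
   `end3` (ties to the 3'-most).
4. **Internal-priming filter** — a cluster is an oligo-dT artifact if the
   20 genomic nt immediately downstream of its 3' end are ≥ 65% adenosine on
   the transcribed strand.
5. **Gene attachment** — a cluster attaches to the nearest same-strand gene
   whose window (stop codon, exclusive, to 100 nt past the furthest
   annotated 3'UTR end, inclusive) contains its representative site.
6. **Cross-dataset merge** — clusters from different datasets whose
   representative sites lie within ≤ 5 nt merge transitively.
7. **Usage filter** — clusters holding < 5% of a gene's pooled reads are
   discarded.

Surviving clusters define 3'UTR isoforms (length = first base after the stop
codon through the last transcribed base). Per tissue, usage is the read
share among a gene's clusters; `u(proximal) > 0.5` marks a proximal-
preferring tissue in the isoform-switch matrix. PAS classification scans the
40 nt upstream of each site for canonical `AAUAAA`, else its closest
single-substitution variant. Expression uses FPKM
(`count / (length_kb × mapped_reads_millions)`) with a replicate-median ≥ 1
threshold; expression breadth (tissue-restricted / intermediate / commonly
transcribed) is counted over the tissue panel. A target site at UTR offsets
`[s, s+7)` is *lost* in a tissue when the gene is expressed there but every
detected isoform ends at or before `s+7`; the headline statistic is
`lost / (lost + retained)` pooled over tissues. The reporter module computes
per-channel corrected integrated densities
`ID_t − (ID_b/Area_b)×Area_t − ID_N2` and their GFP/mCherry ratio.

## Worked example

```python
from apa_utrome import PipelineConfig, run_pipeline

config = PipelineConfig(seed=3)
config.sim.n_genes = 40
report = run_pipeline(config)

print("clusters:", report["clusters"])
print("APA rate (mean across tissues): %.3f" % report["apa"]["mean_across_tissues"])
print("APA rate (>=2 isoforms anywhere): %.3f" % report["apa"]["anywhere"])
print("noncanonical PAS fraction: %.3f" % report["pas"]["noncanonical_fraction"])
print("miRNA target loss: %.3f" % report["mirna"]["loss_fraction_overall"])
print("site recovery: %.3f" % report["truth_recovery"]["site_recovery_fraction"])
```

prints

```
clusters: {'built': 888, 'internal_priming_flagged': 318, 'gene_attached': 570, 'after_cross_merge': 378, 'low_usage_flagged': 0, 'surviving': 60}
APA rate (mean across tissues): 0.456
APA rate (>=2 isoforms anywhere): 0.400
noncanonical PAS fraction: 0.583
miRNA target loss: 0.005
site recovery: 1.000
```

Reading this: 888 per-dataset clusters were built from 16 simulated
datasets (8 tissues × 2 replicates); 318 were flagged as internal-priming
artifacts (every one a planted A-rich decoy), and after cross-dataset
merging and the usage filter, 60 clusters survive — exactly the simulated
cleavage sites, every one recovered at its true coordinate. The recovered
APA rate (0.400) matches the generator's planted APA gene fraction (0.4
by default). Target loss is ~0 here because default usage mixtures keep
distal isoforms detected in every tissue; planting a loss rate
(`config.sim.planted_loss_fraction`) produces short-UTR-only tissues and a
matching recovered loss fraction.

The same stages are available as a CLI:

```bash
apa-utrome simulate --outdir sim/
apa-utrome readprep trim --fastq sim/t01.rep1.fastq --out trimmed.fastq
apa-utrome readprep map --fastq trimmed.fastq --genome sim/genome.fa --out ends.bed
apa-utrome cluster build --alignments ends.bed --genome sim/genome.fa \
    --annotation sim/annotation.gff3 --out clusters.tsv
apa-utrome run --outdir results/        # full pipeline + report.json
```

## Layout

| module | role |
| --- | --- |
| `synthetic_data` | genome/annotation/read/target generator with ground truth |
| `readprep` | tail selection, trimming, exact-match mapping, BED import |
| `clustering` | fragments, cluster merge, internal-priming/usage filters, gene attachment, cross-dataset merge |
| `utrome` | isoform catalog, APA rates, switch matrix, length stats, PAS classes |
| `expression` | per-gene counts, FPKM, expressed calls, breadth, group overlaps |
| `mirna` | target tables, seed scanning, per-tissue fates, loss, rankings |
| `reporter` | integrated-density corrections, GFP/mCherry ratios, paired tests |
| `pipeline` / `cli` | end-to-end driver, YAML config, command-line interface |

See `docs/methods.md` for modeling assumptions, parameter defaults and
known limitations.
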