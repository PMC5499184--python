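# Methods

## Scope and model

The package analyzes 3'-end RNA-seq in which each read terminates in an
untemplated poly(A) tail. The generative picture: a gene transcribes
through its stop codon into a 3'UTR and is cleaved at one of 1–3
polyadenylation sites; a tissue is characterized by a usage mixture over
those sites. Reads sample (gene, site) pairs in proportion to expression
and usage; two artifact classes contaminate the library — oligo-dT priming
at genomically encoded A-rich stretches (internal priming), and short-tail
fragments that never saw a poly(A) tail. The analysis recovers sites,
per-tissue usage, and downstream statistics (APA rates, isoform switching,
miRNA target loss) from the reads alone; the simulator provides the ground
truth to validate that recovery.

## Coordinate conventions

All genomic coordinates are 0-based, half-open on the contig's plus strand.
A cleavage site is the 3' boundary of the transcribed interval: one past
the last transcribed base on `+`, the coordinate of the last transcribed
base itself on `-`. 3'UTR length counts nucleotides from the first base
after the stop codon through the last transcribed base, excluding the tail.
Target sites use 0-based half-open UTR offsets; a 7-nt seed at offsets
50–56 inclusive is stored as `[50, 57)` and is retained by an isoform iff
`utr_length ≥ 57` (a seed that crosses the cleavage site is treated as
non-functional, configurable).

## Stage parameters (defaults)

| parameter | default | meaning |
| --- | --- | --- |
| min tail | 23 nt | minimal terminal A run (strict, mismatch-free; an optional mode tolerates one 1-nt interruption) |
| min remainder | 10 nt | minimal trimmed read length |
| fragment flank | ±5 nt | window around each read 3' end before merging |
| internal-priming rule | ≥ 65% A in 20 nt | downstream of the cluster 3' end, transcribed strand; truncated windows use the same fraction over the available bases |
| gene attachment | ≤ 100 nt | past the furthest annotated 3'UTR end, stop codon exclusive |
| cross-dataset merge | ≤ 5 nt | between representative sites, single linkage, per contig/strand/gene |
| usage filter | < 5% | of the gene's reads pooled over all datasets |
| expressed | FPKM ≥ 1 | replicate median (with two replicates the median is their mean); `per_run` mode uses the replicate mean |
| PAS window | 40 nt | upstream of the cleavage site; canonical = exact AAUAAA, else the closest single-substitution variant, else none |

Open design points resolved here (all configurable): the A-content window
is placed *downstream* of the cluster's 3' end, where the priming template
must lie; the usage-filter denominator pools reads across datasets, with
per-tissue usage computed afterwards from surviving clusters; fragment
merging uses gap 0 (overlap or bookended); cross-dataset distance is
measured between representative sites, not interval edges; attachment ties
between equally near furthest-UTR ends go to the nearer stop codon, then
gene id; APA rates are reported both per tissue (genes with ≥ 2 isoforms
detected in that tissue) and as the fraction of genes with ≥ 2 isoforms
detected anywhere, since the two definitions differ whenever usage is
strongly tissue-specific.

## The synthetic-data generator

`SimConfig` defaults describe the study conditions: 8 tissues × 2
replicates, ~50 reads per gene per dataset (scaled by transcript length
relative to the panel mean, so FPKM is rank-faithful to the planted
expression factors), 40% APA genes (2 or 3 sites), canonical PAS for 39% of
sites with single-substitution variants otherwise placed 10–30 nt upstream,
pure-A 30-nt decoys producing 10% internal-priming reads, 5% short-tail
contaminants, true tails 23–60 nt, trimmed read lengths 30–50 nt, and
miRNA targets at ~10 sites/kb of longest UTR with 95% placed distal to the
proximal site (target predictions from union databases are dense, and the
distal concentration is the phenomenon under study). Commonly transcribed
genes carry a +100 nt extension of their distal-most segment, emulating the
longer UTRs of broadly expressed genes. Proximal UTR lengths draw from
U(80, 120) and inter-site gaps from U(250, 350), capped by the configured
maximum.

Planted fractions (APA membership, breadth classes, per-class target
presence) are assigned as exact counts over random subsets rather than
independent coin flips, so a planted 31% APA rate is the realized rate up
to rounding — parameter-recovery experiments then measure pipeline error,
not generator sampling noise.

**Loss planting.** With `planted_loss_fraction = L`, each APA gene keeps
one *anchor* tissue running a mixed (distal-dominant) usage program; every
other expressed tissue switches to proximal-only with probability
`p = L / φ`, where `φ` is the share of target × expressed-tissue pairs
that are distal-on-APA with a non-anchor tissue, computed from the
generator's own realized target placement. The expected pooled loss
fraction then equals `L` by construction; the generator raises an error if
the requested `L` exceeds what the placement supports. Mixed tissues give
the distal site the largest usage share (tissues either run the short
program exclusively or predominantly the long one), which keeps distal
clusters above the 5% pooled-usage filter.

**Exact recoverability guarantees.** So that ground truth is recoverable
bit-for-bit on noise-free runs, the generator enforces three sequence
properties: the base immediately 5' of every true cleavage site is non-A
(tail trimming removes exactly the tail); the 30 nt downstream of every
true site hold ≤ 12 adenosines on the transcribed strand (no 20-nt
subwindow can reach the 65% internal-priming threshold); and the 40-nt PAS
search window contains no PAS-like hexamer other than the planted one
(scrubbing mutations only increase Hamming distance to AAUAAA and never
introduce adenosines, so they cannot create new signals). Contaminant reads
are placed so their genomic segment also ends in a non-A base, making the
<23-nt-tail rejection exact. Decoys are intergenic, so internal-priming
reads never contaminate gene-attached clusters.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: sequencing errors (tails are pure A by
default; an optional per-base error rate exists), spliced 3'UTRs and
gapped alignment, overlapping genes, antisense transcription, nucleotide
composition bias around real cleavage sites, heterogeneous cleavage
(±1–2 nt wobble), germline tissue, and library-prep amplification effects.
Real-data headline numbers (cluster totals, 31% APA, 37% loss, 95%/46%
presence, 60%/74% noncanonical PAS) depend on deep sequencing of real
tissues and are not reproducible at desk scale; the package instead
verifies that each statistic's *estimator* recovers planted values under
the stated conditions.

`generate_target_table` samples a fresh table by the same zoning rules
without re-embedding sequence, emulating an externally supplied prediction
table; the embedded ground-truth targets (recoverable by the 7mer-m8 seed
scanner) live in `GroundTruth.targets`.

## Numerical and procedural choices

- Mapping is exact-match via a 16-mer anchored index; reads shorter than
  16 nt fall back to a linear scan. Multi-mappers are dropped, not placed.
- Representative sites are read-weighted modes; ties break to the 3'-most
  position (strand-aware). Weighted medians are lower medians (smallest
  value whose cumulative weight reaches half the total).
- The breadth/length comparison uses a seeded 1000-resample bootstrap
  percentile CI on the difference of means of each gene's longest detected
  isoform length.
- The reporter's corrected density is computed exactly as
  `ID_t − (ID_b/Area_b)×Area_t − ID_N2` per channel, with `Area_t` the
  whole-image pixel count taken literally and the N2 baseline subtracted
  raw (not area-normalized). A non-positive corrected mCherry invalidates
  the ratio. Group comparisons use a two-sided paired t-test.
- Pipeline determinism: all randomness flows from one seed; per-dataset
  seeds are derived arithmetically, and reports serialize with sorted keys,
  so double runs are byte-identical.
- Acceptance experiments use 100-gene panels (site recovery, decoy
  specificity) and a 500-gene panel (statistic recovery), sizes at which
  every recovered statistic's sampling error is well inside the ±0.05
  recovery bands while a full run stays under a minute.

## Known limitations

- The internal-priming window placement (downstream) is a modeling choice;
  datasets processed with a centered or upstream window will differ at
  A-rich boundaries.
- Gene-level counting splits no multi-gene reads (genes are assumed
  non-overlapping on a strand); the uniform-split fallback noted in the
  interface is not needed on simulator output.
- The expressed-gene threshold treats a two-replicate median as the mean;
  with many replicates the median is the usual order statistic.
- `load_target_table` validates against the longest *detected* UTR, so a
  gene whose distal cluster falls below the usage filter sheds its distal
  targets from the table — visible as the `n_targets_dropped` counter.
- Family enrichment ranks are count-based with alphabetical tie-breaks; no
  enrichment statistics (hypergeometric or otherwise) are attached.
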