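# Methods

## Model

`ghannot` treats fine-grained CAZyme annotation as hierarchical best-hit
classification against a curated, labelled reference database. The unit of
evidence is a single pairwise hit between a query protein and a reference
protein, summarized by three quantities:

* **percent identity** — identical aligned columns / alignment length × 100;
* **query coverage** — aligned query span / query length (the query-side
  convention, matching `--cov-mode 2` clustering);
* **bitscore** — (λ·S − ln K)/ln 2 with gapped Karlin–Altschul parameters.

A query's hits are ranked by bitscore, then identity, then target id (a fixed
total order, so annotation is deterministic). Hits failing the coverage
(≥ 0.50) or bitscore (≥ 200) gate are discarded; the single best survivor
decides the annotation. The assignment is *competitive*: non-HMG clusters
stay in the database and can win the competition, absorbing queries that
would otherwise map weakly onto HMG clusters. The HMG filter
(`hmg_unknown` / `hmg_only` / `all_genes`) therefore only shapes reporting,
never assignment.

Two-stage rule, with family threshold T_f and cluster threshold T_c of the
best hit's reference:

1. identity ≥ T_f → family assigned; otherwise no annotation (no fallback to
   the next-best hit — the simplest reading of a best-hit classifier; a
   retry-next-hit variant would blur the competitive-mapping semantics).
2. identity ≥ T_c as well → cluster assigned; otherwise the sentinel
   `cluster undefined`.

## Aligner

The internal search is an affine-gap Smith–Waterman (Gotoh) over the 20
canonical residues plus X, BLOSUM62 (loaded from Biopython), gap open 11,
extend 1 (a gap of length k costs 11 + k). X scores 0 against everything —
neutral ambiguity. λ = 0.267, K = 0.041 (the standard gapped BLOSUM62
parameterization) convert raw scores to bits, which is what makes the 200-bit
gate meaningful. The dynamic program is numba-jitted; its traceback uses a
fixed convention (endpoint with the highest score, ties to the smallest query
then target index; diagonal preferred over gap-in-query over gap-in-target;
gap closure preferred over extension), so results are reproducible to the
byte. The test suite holds an independently written pure-Python
implementation of the same conventions as an oracle.

A k-mer prefilter (k = 5, shared-k-mer screen) skips reference sequences that
share no k-mer with the query. It is disabled automatically during threshold
calibration, where the *weak* cross-family hits it would drop are exactly the
negative examples being calibrated. No e-values are computed: the method
gates on identity, coverage and bitscore only.

## Threshold calibration

For every reference sequence we record the identity of its best non-self hit
inside its family and its best hit into each other family (one-vs-rest; a
pooled-negatives variant would under-weight small families). Calibration
hits are gated by the coverage cutoff only — ungated local alignment admits
micro-alignments (e.g. 7 identities over 8 columns) whose "identity" is
meaningless as a negative example, while the bitscore gate would remove all
negatives and degenerate the sweep.

* **Family thresholds**: sweep a grid (30–100% in 0.5 steps — fine enough
  that the grid, not the data, never limits resolution) and pick the
  threshold maximizing F1, ties resolved toward the larger (more stringent)
  value. F1(0,0) = 0 by convention.
* **Cluster thresholds**: 10th percentile (linear interpolation between
  closest order statistics) of the cluster's distribution of best non-self
  intra-cluster hit identities; singletons, where a percentile is undefined,
  inherit the family threshold.
* **Harmonization**: T_c = max(T_f, percentile), which guarantees the
  hierarchy invariant (cluster assignment at least as stringent as family
  assignment); `validate_threshold_hierarchy` re-checks it on every load.

Self-hits are excluded throughout — including them forces identity 100 and
voids the calibration.

## Database construction

`greedy_cluster` implements set-cover clustering within one family: repeat —
pick the unassigned sequence covering the most unassigned sequences at
identity ≥ `min_seq_id` (default 0.70) and query coverage ≥ 0.80, make it a
centroid, assign its cover. Ties break toward the longer sequence, then the
smaller id, so builds are deterministic. `filter_min_size` (default 5)
removes sparse clusters, which are numerous but contribute little sequence
diversity and tend to reflect errors or rare variants.

`merge_by_neighbourhood` consolidates clusters of one family whose flanking
gene content (orthologue-label sets within a 20 kb window around each anchor,
extracted from per-genome gene tables rather than raw GenBank — testable
without external annotation tools) differs by ≤ 2 genes, transitively via
union–find, keeping the smallest constituent id. Loci are deduplicated on
(genome, locus coordinates) first, since one locus can be found by seeds from
several clusters. An optional predicted-function grouping restricts merging
to clusters annotated with similar functions — shared genomic context is
evidence of orthology only within a function. Merging can only reduce the
cluster count and is idempotent.

## Transporter annotation

A flat best-hit assignment against the transporter references at ≥ 80%
identity. The query-coverage gate applies (guards against spurious short
matches) but the 200-bit gate does not — only the identity threshold defines
this module; the convention is echoed in the run header so users see it.

## Benchmarking

`score` matches annotations to gold records per (genome, protein id) with
label equivalence (case-folded equality or synonym-table link; in cluster
mode either the cluster id or the enzyme label may match, since published
repertoires use free-text enzyme names). Gold records without protein ids
fall back to per-genome label-multiset matching. False positives count only
unmatched annotations with HMG status yes/unknown on gold genomes: extra
calls on non-HMG clusters are the competitive-mapping sink working as
intended, not errors. Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 the
exact harmonic mean.

## Reporting

Copy-number matrices count annotations per (label, genome) at family, enzyme
and cluster level; the HMG filter applies at the cluster level (`all_genes`
adds `cluster undefined` as its own row; the enzyme level aggregates defined
clusters by enzyme label). Heatmaps are seaborn clustermaps, white-to-blue,
average-linkage/Euclidean hierarchical clustering of columns and rows (only
when ≥ 2 of them exist), genome-metadata column bars and an HMG-status row
bar on the cluster heatmap, written as SVG + PNG and always paired with the
underlying TSV so values stay machine-checkable. Table rows are sorted by
(genome, protein), and SVG ids are salted deterministically, so reruns are
byte-identical.

## Synthetic data

The generator emulates the structure the method relies on: GH families as
unrelated ancestors (independent uniform sequences, pairwise identity ≈ 5%),
clusters as ancestor mutants at the within-family identity (default 75%),
members as centroid mutants at the within-cluster identity (default 90%),
sequence length 240 — typical of single-domain GH catalytic regions and long
enough that band identities clear the 200-bit gate with a wide margin.
Defaults are 2 families × 3 clusters × 8 members with a 45% cross-family
ceiling — the separable design used throughout the tests. Mutation is
substitution-only, so positional identity is controlled exactly; planted
queries additionally keep 5 residues at each end unmutated, which pins the
optimal local alignment to full length and makes measured identity equal
planted identity. Planted queries are placed relative to the *calibrated*
thresholds: cluster-assigned queries above their cluster threshold,
cluster-undefined queries at the best achievable identity inside the
(T_f, T_c) band (skipped with a warning when no cluster leaves an achievable
band), decoys as random sequences verified post hoc to have no hit passing
all gates. Verification aligns a planted query only against its source
member — the generator never runs the annotator, so closed-loop tests are not
circular.

What the generator does **not** emulate: real bifidobacterial residue
composition, domain architecture, indels, fragmented genes, or the ragged
identity structure of real families. Passing the closed-loop tests therefore
shows the classifier applies its rules exactly under separable conditions; it
does not measure performance on real genomes, which depends on the curated
database.

## Problem sizes and numerics

Tests and the acceptance script run on compact designs (24–48 reference
sequences, 100 queries, pairs ≤ 240 residues) chosen so the identity bands
are unambiguous at small n. All randomness flows through
`numpy.random.default_rng` seeds; percentiles use linear interpolation; all
ranking ties have declared resolutions (documented above), so every output is
deterministic. Degenerate inputs have defined behaviour: empty cluster maps
harmonize to family thresholds only, 1×1 matrices render without clustering,
empty annotation sets produce header-only tables.

## Known limitations

* The internal aligner is exhaustive (modulo the k-mer prefilter) and
  single-threaded; for large batches an external engine's tabular output can
  be imported instead (`import_external_hits`).
* A best hit that fails its family threshold ends annotation for that query;
  no second-best fallback.
* Multi-domain proteins receive at most one annotation.
* Localization is a database attribute; no signal-peptide prediction runs at
  annotation time.
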