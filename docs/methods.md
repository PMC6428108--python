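# Methods

## Scope and data model

apakit analyses UTR-APA — alternative polyadenylation events that change
3'UTR length without touching the coding region.  All coordinates are
0-based, intervals half-open (BED convention); GTF is converted on
read/write.  A gene's 3'UTR anatomy is reduced to a strand-aware pair
(`stop_pos`, the first UTR base; `utr_len`), and every UTR position is
addressed by its distance `d ∈ [1, utr_len]` from the stop codon, which
removes strand branching from all downstream arithmetic.

## pA-site identification

1. **Strand correction.**  3'-end libraries sequence the poly(A)
   junction; the mate that reads into the tail begins with the
   reverse-complemented tail, a poly(T) head.  Exactly the records whose
   prefix starts with `TTT` (case-insensitive, no mismatches) are kept;
   the transcript strand is opposite to that mate's alignment strand and
   the cleavage position is its aligned coordinate.  The rule is literal
   by design — a configurable mismatch tolerance would change the
   kept-set in ways that are hard to reason about, and the contaminant
   model in the simulator exists precisely to exercise this filter.
2. **Clustering.**  Cleavage positions on one (chromosome, strand) are
   single-linkage clustered with an inclusive gap threshold
   (`max_gap`, default 24 nt): two tags join transitively iff their
   coordinate difference is ≤ the gap.  The representative site
   (`mode_pos`) is the most frequent position; ties resolve to the most
   upstream position in transcription direction, which is deterministic
   and strand-symmetric.  Samples are clustered jointly so cluster
   boundaries are shared between conditions and per-gene comparisons are
   site-matched; per-sample counts are retained.  Clusters with fewer
   than `min_cluster_tags` (default 5) summed tags are dropped.
   The defaults are conventional 3'-seq values and exposed in
   configuration; they are not tuned to any dataset.
3. **Internal-priming filter.**  Oligo(dT) can prime on genomic A-runs,
   producing false sites.  A cluster is flagged when the 10-nt genomic
   window immediately downstream of `mode_pos` (transcript strand)
   contains ≥ 6 consecutive A or ≥ 70% A.  Flagged clusters stay in the
   output (they are informative QC) but are excluded from usage metrics.
4. **Annotation.**  Categories are assigned with fixed priority
   known_pA > UTR3 > exon > intron > intergenic; "known" means within
   ± `known_tol` (default 24 nt, matching cluster granularity) of a
   catalog site on the same strand.
5. **Signal scan.**  The 40 nt upstream of `mode_pos` (transcript
   strand) are searched for AATAAA, then ATTAAA; the first match by that
   priority gives the class.  The canonical-signal fraction of a cluster
   set is the fraction classed AATAAA or ATTAAA.

## Usage statistics

**eUTR** is the tag-share-weighted mean site distance
`Σ d_i · n_i / N` over a gene's non-flagged UTR3/known sites.  It is
bounded by the extreme site distances, invariant to uniform count
scaling, and strictly decreases when tag mass moves proximally.  Genes
need ≥ 2 sites and ≥ `min_gene_tags` (default 20) tags per condition;
weighting uses within-sample tag fractions only, so no between-sample
depth normalisation is required.

**RUD** divides mean per-base RNA-seq coverage over the aUTR (proximal →
distal site) by that over the cUTR (stop codon → proximal site).  Only
the most proximal and most distal site enter; intermediate sites are
ignored for RUD but kept for eUTR.  The raw density ratio is reported —
not log-transformed and not clipped at 1 — because its expectation under
a two-isoform Poisson mixture equals the long-isoform fraction, and the
delta cutoffs are defined on that linear scale.  Genes are excluded with
a reason code when the cUTR is shorter than `min_cutr_len` (default
100 nt — in real data the large majority of genes clear this) or carries
less than `min_cutr_reads` (default 30) summed coverage, since the
denominator is then too noisy to interpret.

**Classification.**  Δ = knockdown − control; `Δ ≤ −c` is shortened and
`Δ ≥ +c` lengthened, boundaries inclusive.  A relative epsilon
(1e−9 · c) absorbs floating-point representation at decimal cutoffs
(0.45 − 0.50 evaluates a hair above −0.05).  No per-gene hypothesis
tests or multiple-testing corrections are applied: classification is by
effect size, and a single Welch two-sample t-test (on log2 values for
eUTR, raw for RUD) summarises the global distribution shift.

**CLIP windows.**  Tags are counted by their 5' position (the
crosslink-site convention) in symmetric windows around each pA site and
normalised to RPM.  Windows clipped at chromosome bounds are
length-normalised so truncation does not bias density.  The paired
proximal-vs-distal comparison uses the Wilcoxon signed-rank test
(two-sided, zero differences dropped); the test behind the published
box-plot comparisons of this kind is typically unnamed, so a paired
t-test is reported alongside for transparency.  At least 10 pairs are
required by default.

## The simulator

The generator emulates a knockdown-vs-control APA study: `n_genes`
two-pA-site genes laid out ≥ `gene_spacing` (5 kb) apart on a synthetic
chromosome, alternating strands, each with a 450-nt two-exon CDS stub
(so exon/intron annotation categories are exercised) and a 3'UTR drawn
from `utr_len_range`.  Per gene, a long-isoform fraction `f_long` drives
everything: PA-seq tags choose the distal site with probability
`f_long` (Poisson(`pa_depth`) tags per gene and condition, Normal
positional jitter clipped to the UTR, a `contaminant_frac` of non-T-headed
reads, default 0.1); RNA-seq coverage is Poisson(`cov_depth`) per cUTR
base and Poisson(`cov_depth · f_long`) per aUTR base, making the true
RUD equal `f_long`; the true eUTR is
`f_long · d_distal + (1 − f_long) · d_proximal`.  A `shifted_gene_frac`
of genes (Bernoulli per gene) switch `f_long` from `f_long_ctrl` to
`f_long_kd` in the knockdown.

CLIP tags fall uniformly over the 3'UTR *plus a 200-nt flank on both
sides* at rate `clip_depth / utr_len` per nt, with an extra
`(clip_prox_enrich − 1)`-fold rate within ±200 nt of proximal sites of
shifted genes.  The flank matters: the distal site sits at the UTR end,
and without flanking background its window would be half-empty by
construction, biasing every proximal/distal comparison even with no
enrichment.  Biologically the flank stands for pre-mRNA/readthrough
signal around cleavage sites.

The synthetic genome is uniform A/C/G/T with an AATAAA hexamer planted
10–30 nt upstream of every true site, an A-depleted downstream 10-mer
(true sites must never trip the priming filter), and — for an
`ip_decoy_frac` of genes — a decoy position mid-cUTR with a planted
10-nt poly(A) run downstream and no signal, receiving
`decoy_tag_frac · pa_depth` expected T-headed tags.

Randomness: one `numpy` stream per (data-type, gene, condition), spawned
from the master seed via `SeedSequence` spawn keys.  Adding genes,
reordering conditions or skipping a data type never perturbs other
draws, and identical configurations reproduce outputs byte-for-byte.

What the simulator does *not* model: read-level sequencing errors,
fragment-length effects, replicate batch effects, expression-level
variation between genes, > 2 pA sites per gene, and overlapping genes.
Passing recovery tests therefore demonstrates estimator correctness
under the stated noise model, not robustness to alignment artifacts or
annotation errors in real data.

## Validation studies and problem sizes

The statistical test-bed uses sizes that keep the full suite within a
few minutes while leaving comfortable statistical margins:

- estimator oracles: 1000 random profiles (eUTR vs exact weighted sum);
  200 random tag sets of ≤ 500 positions (clustering vs an independent
  pairwise-adjacency/graph-components oracle);
- RUD recovery: 500 genes, 50× coverage, cUTR ≥ 400 nt, `f_long`
  uniform on (0.1, 0.9) — mean absolute error ≲ 0.005 against the
  ≤ 0.02 requirement;
- shortening detection and the global-trend comparison: 1000 genes,
  UTR lengths 800–1200 nt, proximal site at 40–60% of the UTR, ~300
  shifted genes with `f_long` 0.7 → 0.4, PA-seq depth 200, coverage
  100×.  This geometry keeps the ΔeUTR ≤ −50 nt rule's per-gene false
  call probability ≈ 2% (binomial noise on a ~450-nt aUTR at 200 tags)
  while true shifts of ~0.3 · aUTR ≈ 150 nt are detected essentially
  always;
- CLIP: 200 fully-shifted genes at 2-fold enrichment for power, and 50
  null replicates for type-I calibration of the signed-rank test.

## Known limitations

- The eUTR route assigns clusters to genes by UTR overlap and refuses
  ambiguous assignments; overlapping real genes require pre-filtering.
- RUD assumes the two-site model; genes with heavy intermediate-site
  usage violate its mixture interpretation (their eUTR remains valid).
- bedGraph coverage is materialised densely per chromosome, which is
  fine for targeted/simulated genomes but memory-hungry for a full
  mammalian genome; a windowed backend would be the natural extension.
- The Welch test on per-gene values treats genes as independent and
  ignores pairing; it mirrors the field's box-plot comparisons rather
  than a formal mixed model.
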