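# Methods

This note documents the models, conventions and design choices behind
`tfekit`, in the order the pipeline applies them.

## The TFE quantification unit

The input is a stream of strand-aware alignment 5'-end events, each
carrying a UMI and a sample identity (read either from a 7-column TSV or
from SAM records with `RX`/`RG` tags). The 5' end of a read is the
leftmost aligned reference base on the plus strand and the rightmost on
the minus strand, with spliced blocks respected. PCR duplicates are
collapsed to one event per distinct `(sample, chrom, strand, position,
UMI)` tuple; deduplication is order-independent.

TFE regions are called on the deduplicated events *pooled over all
samples*, so the experiment has a single TFE catalogue: per chromosome
and strand, event positions are single-linkage clustered with inter-event
gap ≤ `max_gap` (default 60 bp), and clusters with pooled count <
`min_count` (default 2) are dropped. A region spans `[min pos, max pos+1)`;
its summit is the modal position, ties broken toward the farthest-5' base.
Full-scale pipelines for this protocol define TFEs via transcript assembly
(retaining reads on assembled first exons); the clustering form used here
is a deliberate, declared surrogate that reproduces the unit's intent —
one region per active TSS neighbourhood — and is validated against a
brute-force clustering oracle and against the generator's planted TSS loci
(≥ 99% recovered as exactly one TFE when jitter ≪ `max_gap`).

Counting is by half-open interval membership of the event position, with
strand and chromosome matched; events outside every region are tallied,
and the matrix total plus that tally always equals the deduplicated event
count.

## Genomic annotation

Each TFE is classified by its **summit** against same-strand gene models
(one model per gene = its longest transcript; ties break by transcript
id). Nine categories are assigned with a fixed priority —
`Coding5UTR > CodingUpstream > CodingCDS > Coding3UTR > Noncoding1stExon >
NoncodingUpstream > NoncodingOtherExon > Intron > Unannotated` — where
"upstream" means within `upstream_bp` (default 500) 5' of a model's TSS,
and intronic means inside the gene span but outside every exon. Summit
classification and the priority toward promoter-like labels are design
choices: the analysis is promoter-centric, and a single deterministic
label per TFE is required. The 9→6 merge is the fixed total map that
combines coding upstream with coding 5'-UTR, coding CDS with coding
3'-UTR, and noncoding upstream with noncoding first exon.

Stage proportion tables divide each sample's per-category count sums by
the sample total (×100) and then average the *percentages* over each
stage's samples — not the pooled counts — so each stage row sums to 100.

## Spike-in normalization and absolute copies

Every sample receives the same spike-in input of `M` molecules (default
9216), so spike-in rows isolate technical depth differences. Size factors
are the median-of-ratios estimator restricted to spike-in rows (rows with
a zero count in any sample are excluded; at least two must remain),
rescaled to geometric mean 1.

Log2 normalized values follow the convention

    value = log2( count / (size_factor × S_ref) ),

with `S_ref` the mean total spike-in UMI count per sample. This anchors
the scale to the spike-in yield: a value `v` estimates `2^v × M` molecule
copies, and at `M = 9216` a value of −10 is exactly 9 copies. Zero counts
map to a `-inf` sentinel ("not expressed" at any finite threshold); a
pseudocount-1 variant provides finite values for correlation and
clustering inputs (a simple variance-stabilization proxy; an exact VST is
out of scope). Relative poly(A) content per stage is the per-sample ratio
of endogenous to spike-in totals, averaged by stage and divided by the
reference stage (GV); spike-ins are excluded from the numerator because
the quantity of interest is endogenous RNA.

## Technical noise and variable-TFE selection

The spike-in CV²-versus-mean relation is modelled as
`CV²_tech(μ) = a1/μ + a0` and fitted by a gamma GLM with identity link on
≥ 10 usable spike-in points (OLS fallback if IRLS fails, logged and
flagged). A TFE with observed mean μ and squared coefficient of variation
CV² (unbiased variance, size-factor-normalized counts) is tested for
excess variability with

    T = (n − 1) · CV² / CV²_tech(μ),   p = P(χ²_{n−1} ≥ T),

the classical scaled-chi-square form for a variance-ratio test. Under
Poisson nulls the empirical type-I rate at p < 0.05 is ≈ 0.05 (checked at
n = 6 over 10,000 draws), and power at a planted biological CV² of 0.5 is
≈ 1. Selection keeps the top-K TFEs (default 20,000) by CV² among those
with BH-adjusted p < 0.05, ties broken by TFE id for determinism.

## Differential expression

Consecutive-stage contrasts run in the fixed ladder MII|GV, 2c|MII,
4c|2c, 8c|4c, 16c|8c, Blc|16c (later vs earlier). The test is a
transparent negative-binomial Wald test on size-factor-normalized counts:

- per-TFE dispersion by method of moments, pooling within-group variances:
  `α = (s²_pooled − m̄) / m̄²`-style with sample-size weights, floored at
  1e-8; no shrinkage toward a mean trend, no LFC shrinkage, no independent
  filtering, no outlier handling — all declared simplifications that keep
  every number traceable;
- LFC = log2 of the ratio of group means after adding a single global
  offset (half the smallest positive normalized count) to both means; the
  offset is global rather than per-TFE so that all-zero-versus-expressed
  rows (stage-exclusive markers) retain their large fold changes;
- delta-method standard error `SE² = Σ_g (m_g + α m_g²)/(n_g m_g² ln²2)`;
- the Wald statistic is referred to a **t distribution with n₁+n₂−2
  degrees of freedom**. With per-TFE moment dispersions the normal
  reference is anticonservative at small n (measured type-I 0.10 at
  4 vs 4, dispersion 0.1, versus 0.059 for the t form); the t reference
  restores calibration at the cost of bounded per-test evidence.

Rows with zero counts across the contrast's samples are removed before
testing; BH adjustment is per contrast; direction is up/down at adjusted
p < 0.05 by LFC sign.

## Markers, scaling, clustering

Stage medians are computed per TFE with sentinels participating as −∞, so
a stage whose lower middle value is a sentinel has a sentinel median. A
TFE is a marker of stage S iff its median is strictly above the
expression threshold (default −10 ≈ 9 copies) in S, strictly below it in
every other stage, and the contrast of S against its preceding stage
shows adjusted p < 0.05 with LFC > 3. The first stage (GV) has no
predecessor and is tested against MII instead (upregulation in GV = LFC
< −3 in the MII|GV table). Exclusivity makes marker sets pairwise
disjoint by construction. Marker calling defaults to the stage subset
{GV, MII, 16c, Blc}; the cleavage stages 2c/4c/8c have near-identical
profiles and essentially no exclusive TFEs, but any subset is accepted.

Row scaling is the per-TFE z-score across samples (constant rows become
zeros with a warning). Temporal clustering is k-means (k = 6, 1000
restarts, 20 Lloyd iterations, random row-sampled initial centers, best
WCSS kept) on row-scaled sample-level values of the selected variable
TFEs, seeded for reproducibility.

## Promoter windows

Windows anchor on the TFE summit. With anchor p: plus strand →
`[p−up, p+down)`, minus strand → `[p−down+1, p+up+1)` (defaults up = 400,
down = 100); "downstream" includes the anchor base, so unclipped windows
have length exactly up+down. Windows are clipped at chromosome ends (with
a flag); minus-strand sequences are reverse-complemented on export.
Outputs are BED6 plus FASTA, directly consumable by motif suites; motif
discovery itself is out of scope.

## The synthetic study

The generator emulates the maternal-to-zygotic transition at desk scale.
Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| genes | 1200 coding + 300 noncoding | enough loci for stable proportions, minutes-scale runtime |
| chromosomes | 6 × 1 Mb | holds all models with ≥ 700 bp gaps (beyond the 500 bp upstream window, so classifications never collide) |
| stages × replicates | 7 × 6 | the staged single-oocyte/embryo designs this emulates profile roughly six samples per stage; six replicates are also what the unshrunken NB test needs for BH-corrected marker detection |
| spike-ins | 50 species, M = 9216 molecules/sample | log-spaced dilution ladder; M makes value −10 ↔ 9 copies exact |
| capture efficiency η | 0.15 | typical UMI-method molecule capture |
| PCR duplicate rate | 0.5 extra reads/molecule | exercises deduplication |
| TSS jitter | σ = 4 bp | ≪ max_gap, one TFE per locus |
| mean expression | 100 molecules (lognormal, σ = 1) | tens of UMIs per expressed TFE per sample after capture |
| markers | 30/stage at 150–400 molecules | "well above" the −10 ≈ 9-copy threshold (values −5.5…−4) |
| biological CV² | 0.3 | inter-embryo variability |
| maternal decay | (1, 1, 0.35, 0.9, 0.9, 0.5, 1) cumulative | two degradation waves: post-fertilization and at 16c |
| content multipliers | (1, 1, 0.8, 0.65, 0.55, 0.35, 0.75) | decline-then-recovery shape of total poly(A) content |
| unannotated TSS fraction | 0.25 | a quarter of loci absent from the GTF |

Stage means are built from class profiles (maternal decay applied
cumulatively; zygotic genes at a 0.02 basal level until the 16-cell onset,
then 1.0 and 1.2×; housekeeping flat; markers nonzero only in their
stage), then renormalized per stage so expected totals follow the content
multipliers exactly — the multiplier is the ground truth the
relative-content estimator must recover. A consequence of the
renormalization is that maternal means, monotone through the 16-cell
stage with their largest drops at 2c and 16c, can tick up again at the
blastocyst when total content recovers; only the GV→16c shape is asserted.
Molecule counts are gamma-Poisson (negative binomial) around stage means
(exactly Poisson at CV² = 0); each molecule is captured with probability
η, positioned at the true TSS plus rounded Gaussian jitter on the gene's
strand, tagged with a random 10-mer UMI, and replicated 1 + Poisson(rate)
times.

What the generator does **not** emulate: sequencing errors and base
qualities, barcode demultiplexing, cellular heterogeneity within an
embryo, assembly-dependent TFE definitions, 3'-end information, and
genome-scale gene density. Passing tests therefore demonstrate that the
implementation recovers what it planted under an idealized error model —
calibration and internal consistency — not performance on real bovine
libraries.

## Numerical conventions and edge cases

- All coordinates 0-based half-open internally; GTF converted on read.
- Sentinels: `-inf` for zero counts at pseudocount 0; medians propagate
  them; copy conversion refuses them; correlation and scaling require the
  pseudocount variant.
- Determinism: every stochastic step derives from explicit integer seeds
  (config seed spawning fixed substreams; k-means seeded); reruns of the
  pipeline with one config+seed are byte-identical, and the manifest
  records a hash over every output-affecting parameter (the output path
  deliberately excluded).
- Degenerate inputs: empty event sets yield empty TFE catalogues (not
  errors); constant rows scale to zeros with a warning; samples with
  all-zero spike-ins, unknown stage labels, unsorted event files, and
  windows fully outside a chromosome raise named errors.
- Spike-in identification is by reference-name prefix (default
  `spike_`), configurable.

## Known limitations

- The NB test's bounded per-test evidence (t reference) means detection in
  sparse contrasts relies on adequate replication; with fewer than ~5
  replicates per stage, BH-corrected marker detection loses power quickly.
- The clustering TFE caller can merge two true TSSs closer than `max_gap`
  on the same strand; the generator's placement avoids this, real genomes
  do not always.
- Median-of-ratios on spike-ins assumes spike-in counts are unaffected by
  biology; composition effects of extreme content change between stages
  are handled by construction here but only approximately in real data.
- The copies calibration treats capture efficiency as uniform across
  molecules; length- or GC-dependent capture is not modelled.
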