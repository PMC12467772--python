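# Methods

`ota-sentinel` implements a desk-scale off-target risk assessment for an
RNAi crop construct against a non-target insect transcriptome. This note
records the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic fixtures do and do not demonstrate.

## The assessment model

An interfering dsRNA silences through short sequence identity, so the
exposure question for a non-target species decomposes into:

1. **Contiguous-match scanning.** For each transcript, the maximal exact,
   gap-free run shared with either strand of the construct. Interference
   has been reported from runs as short as 7 bp, which sets the default
   reporting floor (`min_length = 7`, configurable). Each gene is binned
   once, at its maximum, so per-length class counts are disjoint and sum
   to the number of qualifying genes — the reading under which the
   published per-length tables are internally consistent (row totals sum
   to the Total row). Matching is exact: no mismatches and no G:U wobble,
   since the end point is "continuously matched base pairs", and both
   construct strands are searched because a dsRNA exposes guide strands
   from both.
2. **Regulation screen.** A gene is differentially expressed when
   |log2 fold change| > 1 **and** BH-FDR < 0.05, strict at both
   boundaries; the sign gives the direction. The fold-change magnitude
   rule (rather than a one-sided log2FC > 1) is required for the screen
   to be able to report down-regulated genes at all.
3. **Cross-tabulation and correlation.** Matched genes are
   cross-tabulated against regulation status (counts plus percentages),
   and match length is rank-correlated (Spearman by default; lengths are
   ordinal and no linearity is claimed) against |log2FC| — the magnitude,
   because the question is silencing strength regardless of direction; a
   signed variant is available by flag.
4. **Homology screen.** A from-scratch seed-and-extend local aligner asks
   whether the construct has a homologous fragment in the transcriptome
   at a Karlin–Altschul expectation threshold (defaults: E < 1e-10 for
   homolog calling; the literature also uses 1e-5 for "no homologous
   fragment" statements).
5. **Pathway neighbourhood levels.** Breadth-first rings around seed
   genes: level-1 pathways contain a seed gene and contribute their
   members as level-1 genes; level-(k+1) pathways share at least one gene
   with level-k genes and contribute their still-unlevelled members.
   Genes claimed by several rings keep the minimal level. The published
   level tables report levels 2 and 3, so `level_table` excludes level 1
   by default. Seed genes default to the homolog-search hits; an explicit
   gene list can be supplied instead, since a curated pathway seed set is
   equally defensible.
6. **Enrichment.** One-sided upper-tail hypergeometric p per gene set,
   BH-adjusted across sets.
7. **Transcriptome entropy.** Per sample, H = −Σ p_i log2 p_i over
   per-gene expression proportions; groups compared with a pooled
   (Student's) t-test. Proportions are invariant to per-sample linear
   scaling, so counts, CPM and TPM-like units give identical H; only
   gene-length reweighting would shift it, and both input kinds are
   accepted. Base 2 (bits) by default — group comparisons are
   base-invariant, so the base is a display choice.

## Percentage arithmetic

Cross-table percentages are computed from exact integer counts as
100·n/total, rounded half-up to 2 decimals via `decimal.Decimal`, never
from floating-point intermediates. A few printed cells in the source
tables are inconsistent with their own integer counts under any rounding
rule (e.g. a 99.90% where the counts give 99.89%); the package reproduces
the arithmetic, not the typos, and the affected cells are excluded from
the checks.

## The differential-expression screen

The internal test is deliberately simple and declared as such: it is a
stand-in for a negative-binomial GLM fit (DESeq2 or similar), whose
output can be imported through `read_deg_table` when exact parity is
wanted — statuses are always recomputed from the thresholds, never
trusted from the file.

* Normalisation: median-of-ratios size factors, excluding genes with a
  zero in any sample from the geometric-mean reference; library-size
  fallback when no gene survives the filter.
* Test: two-sided two-sample t on log2(normalised count + 1), pseudocount
  1. The default is the **pooled-variance** (Student's) t rather than
  Welch's: with three replicates per group, the Satterthwaite degrees of
  freedom behind Welch's test are estimated from the data and collapse
  toward 2 whenever one group's sample variance degenerates — common
  with small integer counts — which both mis-calibrates the null and
  caps the smallest attainable p-value. Under the generator's
  shared-dispersion model the equal-variance assumption is exact, and
  measured null tails match the nominal rate. `equal_var=False` restores
  Welch for designs with enough replicates.
* Multiple testing: Benjamini–Hochberg step-up (statsmodels backend),
  validated in the tests against an independent enumeration.
* Each stage (larva, adult) is screened separately against its own
  controls; a stage-blind run would mix developmental expression
  programmes into the residual.

### Power regime of the recovery calibration

The planted-DEG recovery checks run at baseline means 10^U(2,3)
(100–1000) with dispersion 0.01. Below roughly mean 100, the Poisson
term 1/μ dominates the per-gene noise, and no dispersion setting makes a
3-vs-3 screen reliably recover even 8-fold changes; the calibration
therefore sits in the regime where the dispersion term dominates, which
is what "low dispersion implies high power" presumes. The generator's
*default* mean range stays at 10^U(1,3) (10–1000), which is the more
realistic mixture and is also why the bundled demo — like the real
screen — recovers only a subset of its planted knockdowns.

## Homology search statistics

Seeding uses exact words (default 11-mers) on both query strands;
seeds on an already-extended diagonal are skipped; each seed is extended
without gaps under an X-drop rule (default X = 20). Gapped refinement —
a full affine-gap local alignment (gap open 5, extend 2, first gap
residue costs 7) — triggers only when the ungapped score reaches
`gap_trigger` (default 25): chance-level segments keep their ungapped
score, which matches the *ungapped* Karlin–Altschul constants used in
the E-value, E = K·m·n·e^(−λS) with λ = 1.33 nats, K = 0.621 (the
classic +1/−2 nucleotide values), m the query length and n the total
transcriptome length. λ and K are user-supplied constants, not estimated
from score distributions — at desk scale determinism beats fitted
statistics. One best HSP is reported per subject. Consequences to be
aware of: E-values for strongly gapped alignments are computed with
ungapped constants (slightly conservative scores, slightly optimistic
E), and no finite-size edge correction is applied (a few percent on a
432-nt query).

`pairwise_identity` is global-alignment identity (matches over alignment
columns, gaps included) via Biopython's `PairwiseAligner` under the same
scoring — the operation used for "most homologous to the target"
statements; the seed-and-extend machinery is not involved.

## Synthetic data generator

The generator fabricates every pipeline input under one seed
(`numpy.random.default_rng` substreams per artefact, so regenerating one
artefact never shifts another) and returns ground truth beside each:

* **Transcriptome with planted matches.** Background sequence is drawn
  uniformly over {A,C,G,T} with on-the-fly avoidance of every construct
  7-mer (both strands) — pure rejection sampling is hopeless here, since
  a random gene of length G shares an accidental 7-mer with a 432-nt
  construct with expectation ≈ G/19. A planted gene takes a random
  construct substring of the requested length and strand at a random
  offset. Every gene, planted or background, is then verified against
  the dynamic-programming longest-common-substring oracle and resampled
  on any accidental longer match (budget 100 attempts, loud failure), so
  requested class sizes are exact. Planting *below* the 7-bp background
  floor is rejected as infeasible: 1–6-mer background matches are
  statistically unavoidable, so an "exactly 5" class cannot be realised.
* **Counts.** Negative binomial with var = μ + αμ², one shared α per run
  (no per-gene dispersion structure is claimed by the assessment, and a
  single knob is what the recovery tests need), baseline means 10^U(1,3)
  shared across stages, treatment means multiplied by 2^(planted log2FC)
  per stage. Default design: treatment vs control × larva/adult × 3
  replicates.
* **Pathways.** A chain of gene sets in which pathway i shares a fixed
  fraction of genes with pathway i−1; carried genes are drawn only from
  the previous pathway's fresh genes and never include the seed gene, so
  genes first appearing in pathway i sit at breadth-first level i+1 *by
  construction*, and the intended level map is returned for
  parameter-recovery tests.

The bundled demo (`demo_config`) scales the study's per-length ladder
~100-fold down (55/37/13/3/1/1/1/1/1 genes at 7–15 bp out of 300 genes,
alternating strands so both scanner branches are exercised) and plants
2 larval and 8 adult knockdowns at log2FC −3, mirroring the per-stage
DEG counts the assessment design anticipates.

What the fixtures do **not** emulate: read-level sequencing artefacts,
assembly chimeras, isoform families, GC or length bias, per-gene
dispersion trends, and database-scale transcriptomes (tens of thousands
of genes). Passing tests therefore demonstrate the *arithmetic and
algorithmic* correctness of each stage and its calibration under a clean
generative model — not that a real 55k-unigene assembly would yield the
published gene counts, which depend on the sequenced samples and the
annotation version.

## Problem sizes

The bundled demo uses 300 genes of 200–400 nt against a 432-nt
construct; screen calibration uses 2,000-gene matrices over 20 (null)
and 5 (recovery) seeds; scanner/oracle agreement uses 1,000 random
pairs at transcript lengths 20–2,000 nt; entropy null calibration uses
40–60 seeds of 120–150-gene matrices. These sizes were chosen so the
whole suite re-runs in well under half an hour on one core while keeping
every Monte-Carlo tolerance at 3σ or better.

## Known limitations

* The match scanner models exposure, not efficacy: no siRNA thermo-
  dynamics, no seed-region weighting, no mismatch tolerance.
* The internal DE screen makes no claim of DESeq2 parity; import real
  DESeq2 output for regulatory work.
* E-values use ungapped constants throughout (see above).
* Pathway levels depend entirely on the supplied annotation; the package
  ships no pathway database.
* Entropy comparisons at n = 3 per group have little power; the metric
  is a coarse stability indicator, not a safety proof.
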