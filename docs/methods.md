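# Methods

## The model

A read alignment's MAPQ encodes the misalignment probability `p` on the
Phred scale, `Q_m = -10 log10(p)`. `mapqcal` treats misalignment
detection as binary classification: each primary alignment is described
by 22 features and labelled 0 (at its true locus) or 1 (elsewhere), the
classifier's score is converted into a calibrated probability by
isotonic regression, and the probability back into an integer MAPQ.
The pipeline assumes:

- alignments come from a Bowtie2-like aligner that reports `AS`
  (alignment score), `XS` (best secondary score, when one exists), `YS`
  (mate score), `NM`, `XM`, `XO`, `XG`;
- labels are only observable on simulated reads, so the classifier is
  trained on a simulation matched to the target data (same read
  length, coverage, fragment-length distribution, variant density and
  base-quality profile) and then applied to the real alignments;
- reads whose best and best-secondary scores are equal ("multi-mapped")
  carry no usable signal; they are excluded from training and keep
  their original MAPQ.

### Features

Tag-derived: MAPPING_QUALITY, ALIGNMENT_SCORE (`AS`),
SECONDARY_ALIGN_SCORE (`XS`), ALIGN_SCORES_DIFF (`AS - XS`),
MATE_ALIGN_SCORE (`YS`), EDIT_DISTANCE (`NM`), MISMATCHES (`XM`),
GAP_OPENS (`XO`), GAP_EXT (`XG`). Pair-derived: PAIR_ALIGN_TYPE
(0 proper, 1 discordant, 2 mate unmapped), PAIR_ORIENTATION (0 FR,
1 RF, 2 same-strand/no pair), INSERT_SIZE (`|TLEN|`). Sequence-derived:
READ_GC_CONT, READ_COMPR_SIZE (gzip level 6, bytes), SLOPE / INTERCEPT /
R_VALUE (ordinary least squares of base quality on 0-based cycle;
zero-variance qualities give slope 0, r 0), N_LOWQ_BASES and
AVG_LOWQ_SCORE (bases with Q < 20; the mean is 0 when the set is
empty). Reference-derived over the aligned span (`pos` to
`pos + reference-consumed CIGAR length - 1`): REF_GC_CONT,
REF_COMPR_SIZE. DEPTH is the primary-read depth at the leftmost
aligned base (>= 1, the read itself).

Unstated details fixed here: missing `XS`/`YS` take the sentinel
`min_score - 1` (default min_score -61, the end-to-end minimum for
100 bp reads), preserving the "unique alignment is far from its best
secondary" ordering; GC content excludes ambiguous bases from the
denominator; the low-quality cut Q20 is the conventional one. Features
are min-max scaled to [0, 1]; the scaler is fitted on the training
split only (fitting on all data would leak) and clips unseen values.

### Truth labels

A read is "correct" when it aligns to its origin chromosome within
`tolerance_bp` (default 20 bp) of the true leftmost coordinate.
The tolerance absorbs placement wiggle caused by indels between the
haplotype a read was sequenced from and the reference; strict equality
would mislabel reads near true indels.

### Imbalance schemes

Misaligned reads are ~0.1-2% of an alignment, so plain training
collapses to the majority class. Balanced subsets contain every
minority row plus an equal-count majority sample drawn without
replacement; the subset count is `ceil(N_majority / N_minority)`
(majority-coverage semantics; configurable via `max_subsets`).
`RUSVM`/`RULR` fit each subset (grid search, stratified 5-fold CV,
F1 of the minority class) and keep the best model by F1 on an
evaluation set. `RUSVMS`/`RULRS` additionally predict on the full
training split after each subset fit, then retrain on all false
positives plus an equal number of true positives — a balanced set
concentrated on the confusion region, which sharply raises precision.
When true positives are scarcer than false positives they are sampled
with replacement to keep that set balanced (taking them raw makes
logistic refits collapse to the all-majority classifier). `DTBAG`
averages per-subset decision-tree probabilities. `ADABST` is classic
AdaBoost (SAMME) over depth-1 stumps on the full imbalanced matrix.
`RUBST` re-draws a balanced sample inside every boosting round while
the boosting weights live on the full set; rounds whose weighted error
reaches 0.5 are resampled up to 10 times, then boosting stops.

By default the best-subset-model selection uses a carve-out from the
training split (half of it), never the test set; `paper_faithful=True`
restores the published protocol, which evaluates candidate subset
models on the test data and therefore leaks.

### Calibration and MAPQ rewriting

SVM decision distances (SVMs produce no probabilities) and the other
schemes' probability estimates are calibrated by isotonic regression
fitted on the model's own training-split predictions. The solver is
pool-adjacent-violators on scores sorted ascending, ties pre-pooled by
weighted mean so the fit is independent of sort stability; applying the
model interpolates linearly between breakpoints (a pure step function
would map large score ranges to one MAPQ) and clips outside the range.
New MAPQ = `round(-10 log10 p)` capped at 60 (configurable; `p = 0`
maps to the cap). Class assignment thresholds the calibrated
probability strictly at 0.5. Calibration quality is judged by the
Brier score `(1/N) sum (f_t - o_t)^2` and by assigned-vs-observed
calibration curves, where a score bin's observed value is its
misaligned fraction pushed through the Phred formula.

### SNP evaluation

Called variants are reduced to biallelic SNPs (multi-allelic lines
split), filtered to quality strictly above the threshold (default 20),
and matched to the truth on exact (chrom, pos, ref, alt); genotypes are
ignored. Before/after comparisons report relative percent change,
`100 * (after - before) / before`. The optional caller integration
uses `bcftools mpileup -A -B | bcftools call -mv` — anomalous pairs
counted and BAQ disabled, i.e. the caller as permissive as possible so
MAPQ effects are visible.

## The synthetic universe

`simgen` emulates a low-coverage plant resequencing experiment:

| parameter | default | rationale |
|---|---|---|
| read length | 100 bp | paired-end short-read standard |
| coverage | 3x | the low-coverage regime of interest |
| fragment length | Normal(240, 80) bp | typical tight Illumina library |
| SNP rate | 1/3,500 bp | tomato-like inter-cultivar density |
| INDEL rate | 1/21,000 bp | ~1/6 of small variants, 1-10 bp |
| het fraction | 0.5 | unstated upstream; half-and-half |
| mislocation | 0.14-0.19% (tests use 0.2-1%) | observed misplacement regime |
| quality profile | mean Q38 -> Q28 across cycles, sd 4 | HiSeq-like decay |

Pair count is `round(coverage * reference_length / (2 * read_len))`.
The fragment sampler draws plain Normal(mean, sd); `simulate_reads`
enforces `[read_len, chrom_len]` by resampling (no point mass at the
bound). Note the bound at 100 bp shifts the *realized* fragment mean
up by ~7 bp; configuration fidelity is therefore measured on the
sampler's configured distribution. Het variants go to haplotype 1;
sequencing errors substitute uniformly among the three alternatives at
per-base rate `10^(-Q/10)`. Read names encode the pair's true
reference coordinates (`sim:HAP:CHROM:START:END:STRAND:...:SERIAL`),
so labels never need the truth VCF.

`fabricate_alignments` stands in for a real aligner: each read is
placed at its origin with probability `1 - mislocation_rate`, otherwise
at a random other locus. NM/XM/XO/XG and the CIGAR come from actual
alignment of the read against the reference window at its placement
(fast unit-cost edit distance; placements containing gaps are refined
with an affine-gap aligner — unit-cost alignment scatters one multi-bp
indel into several small gaps whose interleaved bases create artifact
mismatch columns that a real affine-gap aligner does not produce).
`AS` uses Bowtie2-like penalties (mismatch 6, gap open 5, extend 3) and
the fabricated MAPQ follows a Bowtie2-like tier table (unique
high-scoring alignments 42, equal-best 1, otherwise falling off with
the AS-XS gap) — deliberately miscalibrated, since replacing it is the
point. About 2% of correct reads are given `XS == AS` so the
multi-mapped exclusion path is exercised.

What the generator does **not** emulate: PCR bias, context-dependent
substitution errors, long insertions, translocations, soft-clipping,
and real repeat structure beyond motif copies. Misplaced reads land at
random loci, so they carry far higher edit distances than real
misplacements (which favour plausible secondary loci in repeats);
classification on this universe is therefore much easier than on real
data, and perfect synthetic F1 scores say nothing about real-data F1.
What passing tests *do* show: the feature definitions, exclusion rules,
isotonic calibration, Phred conversions, rewrite plumbing and the
direction of the end-to-end effect (calibration improves; SNP recall
rises with stable precision at Q>20 when caller evidence is reweighted
by better MAPQ).

## Numerical choices

- gzip compression level fixed at 6 for both complexity features.
- Pearson r of constant sequences defined as 0.
- Grid-search ties break deterministically toward the earlier grid
  point; CV folds whose validation part lacks positives are skipped
  with a warning; data too small for two stratified folds fall back to
  the first grid point.
- SVM uses the RBF kernel with `gamma = 1 / (n_features * Var(X))`
  (scikit-learn's "scale"), grids centred on C = 10; AdaBoost grid
  {500, 1000, 2000} estimators x learning rate {0.5, 1.0}.
- PAVA pre-pools tied scores by weighted mean; weights must be
  strictly positive.
- MAPQ rounding is nearest-integer; the cap (default 60) is
  configurable because `p = 0` must map to a finite SAM value.
- Coordinate maps are exact outside inserted/deleted spans; positions
  inside insertions map to the insertion's reference anchor, inverted
  spans map linearly across the same reference window.

## Problem sizes

The test suite runs entirely on generated data: a 2 x 100 kb universe
for unit tests, ~50k reads at 0.5% mislocation for parameter recovery,
100k reads at 0.2% for the calibration-improvement check, an
overlapping-Gaussian fixture (n = 150,000, 0.2% prevalence, three
seeds) for the scheme-ordering comparison, and three 1 Mb simulations
for the bcftools end-to-end loop. These sizes keep every stochastic
check adequately powered (binomial/Poisson bounds noted in the tests)
while the whole suite completes in a few minutes.

## Known limitations

- The fabricated aligner is not Bowtie2; its score and MAPQ surfaces
  are simplified, and real-data feature distributions will differ.
- ReliefF is the standard O(n^2) formulation, intended for the
  balanced selection subset, not for millions of rows.
- `rewrite_mapq` materialises the file in memory; very large BAMs
  should be processed in chunks (out of scope here).
- SNP matching is exact-position; callers that left-shift around
  indels could in principle be scored unfairly (deduplication and the
  affine-gap fabrication keep this from arising in the bundled
  universe).
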