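# Methods

This note documents the statistical models implemented in `locus2gene`,
the assumptions behind them, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the numerical
decisions that a maintainer would otherwise have to reverse-engineer.

## Pipeline model

The pipeline treats gene prioritization as an evidence-aggregation problem
over a fixed set of disease-associated regions. Inputs are (a) GWAS
summary statistics for a case/control trait, (b) individual-level genotype
dosages and expression for an eQTL panel, and (c) gene annotation. The
genotype panel doubles as the LD reference for clumping and LD overlap —
appropriate when the eQTL cohort's ancestry matches the GWAS population,
and a deliberate simplification otherwise.

### Regions

Clumping is the standard greedy algorithm: repeatedly promote the
smallest-p unassigned variant with p below the threshold, absorbing
unassigned variants within the window whose dosage r² with the lead
exceeds the LD threshold. Ties in p are broken by (chromosome, position,
variant id), making the output invariant to input row order — a detail
most implementations leave to hash order. Variants absent from the LD
reference can lead but neither absorb nor be absorbed. The extended MHC
interval (chr6:25–37 Mb by default) is removed before clumping because its
long-range LD violates the window assumption. Lead windows of ±1 Mb are
merged when overlapping or book-ended (adjacent base pairs), and a gene is
a candidate of a region when its [start, end] span intersects the region
with inclusive ends. Coordinates are 1-based inclusive internally; emitted
BED is 0-based half-open.

### eQTL mapping and instruments

Cis is defined as ±1.5 Mb around the gene span — wider than the usual
±0.5 Mb so that eQTL signal fully covers a region even for genes at its
edge. Mapping is OLS of per-gene standardized expression on alt-allele
dosage with a two-sided t test; standardization puts betas in
expression-SD-per-allele units comparable across genes (switchable off).
Optional covariates are residualized out of expression before mapping; no
kinship or mixed-model correction is attempted (sample-level QC and
relatedness removal are upstream concerns, out of scope here).

Conditionally independent instruments are selected by exact forward
stepwise regression on the individual-level data: at each step every
remaining cis candidate is scored by its conditional p given the current
model (computed by residualizing both expression and candidates against
the selected columns — the Frisch–Waugh identity makes this the exact
joint-model t-test), the best candidate enters while its p clears the
entry threshold (default 5×10⁻⁶) and its marginal r² with every selected
variant stays below 0.9, and the final effects are re-estimated jointly.
This targets the same quantity as summary-statistic conditional analysis
with an LD reference, but exactly, since individual-level data are
available. Degenerate candidates (residual variance ≈ 0 after projection)
are dropped with a log line.

### MR-IVW

With k ≥ 3 instruments, each Wald ratio uses the first-order standard
error se_Y/|β_X| — standard practice when instruments are strong (all pass
5×10⁻⁶); a second-order option including the exposure term exists behind a
flag. The IVW estimate is identical to weighted least squares through the
origin (asserted in tests to 10⁻⁸). Cochran's Q uses the same weights with
a χ²(k−1) p-value. The weighted median follows the cumulative-weight
interpolation estimator, with a parametric bootstrap SE (instrument effects
resampled from their normal sampling distributions, fixed seed, 1,000
draws by default). Instruments with β_X = 0 are dropped; fewer than three
remaining renders the gene not-testable rather than significant or not.
The per-test threshold is family-alpha divided by the number of MR-testable
genes, computed by the caller — at the reference scale of 162 testable
genes this is 0.05/162 ≈ 3.1×10⁻⁴.

### Colocalization

Per-variant Wakefield approximate Bayes factors with prior effect SD 0.2
for the case/control trait and 0.15 for expression, enumerated over the
five standard hypotheses with priors p1 = p2 = 10⁻⁴ and p12 = 10⁻⁵
(the defaults of the established colocalization software the thresholds
were taken from). All sums run in log space; the H3 cross-term
log(Σᵢ Σⱼ≠ᵢ) is computed as a guarded log-difference. Posteriors sum to 1
within 10⁻⁸. At least two shared variants are required; fewer is
not-testable. The single-causal-variant-per-trait assumption is inherited:
loci with multiple causal variants can split posterior mass between H3 and
H4, which is why the evidence model treats colocalization as one line
among four rather than a veto.

### Direction assignment

Per-variant direction is sign(β_eQTL × β_GWAS) after allele harmonization
("+" = expression-increasing allele increases risk). Swapped alleles flip
the GWAS sign; palindromic A/T and G/C variants cannot be harmonized
without strand information and force "?". The six rules (concordance ×
significance patterns with an MR override, and genome-wide-significance
tie-breaks for discordant tops) are implemented as a total function and
verified against an independently hand-enumerated decision table. When the
two top variants coincide, concordance is automatic and the concordant
rules apply. "Significant" inside the concordance rules defaults to the
instrument/clump threshold 5×10⁻⁶ in each dataset (configurable, since
reasonable analyses differ here); "genome-wide" is fixed at 5×10⁻⁸.

### Co-regulation clustering

Gene similarity is the Pearson correlation of component-loading profiles,
Fisher-transformed: Z = atanh(r)·√(n_components − 3). Self-correlations
(and any |r| = 1) are capped at atanh(1 − 10⁻¹²)·√(n−3) to keep the matrix
finite. Ward clustering treats each gene's row of the Z matrix as its
feature vector under Euclidean distance — the most literal reading of
"clustering the Z-score matrix" that Ward supports — and the tree is cut
to exactly k clusters (default 4, a parameter). Labels are renumbered by
the lexicographically first member so results are independent of input
order. Constant-profile genes have undefined correlations and are excluded
with a warning.

### Trans-mediation

Candidate triples require a trans-eQTL at p < 5×10⁻⁸ whose variant lies
inside an associated region and whose target gene lies outside every
region; the top variant per (region, target) is paired with each
prioritized cis gene of the region. The co-expression filter keeps pairs
with |r| > 0.1: the absolute value is deliberate — a signed threshold
would silently discard negatively co-regulated chains, which the test
itself handles fine (a flag restores the signed behavior). The
Freedman–Schatzkin statistic compares the dosage coefficient before and
after adjusting for the mediator, with the closed-form covariance implied
by the dosage–mediator correlation ρ and a t(n−3) reference distribution.
This covariance form is validated against a nonparametric bootstrap of the
coefficient difference rather than trusted blindly; the null rejection
rate is confirmed to sit at the nominal level by simulation. A numerically
zero denominator (possible when ρ ≈ 0 and the two SEs coincide) is floored
at a configurable epsilon with a warning; in that regime the numerator is
correspondingly tiny and the test remains calibrated. Bonferroni control
uses the number of pairs actually tested as the denominator. Covariate
controls — cell-type proportions, or residualizing the mediator on a
neighboring gene — are handled by residualizing all variables before
testing; the mediation test itself is unchanged, and the scan is invariant
to residualizing the mediator on an unrelated gene.

### Gene-set permutation statistic

Counting individually significant genes overstates the differential
expression of a co-expressed set. The statistic used instead is the median
absolute per-gene T over the set, referenced against random same-size sets
drawn uniformly without replacement (independently across draws), in both
a control contrast and a knockdown contrast. Exceedance uses a strict
inequality and the add-one estimator 100·(k+1)/(n_perm+1), the standard
positive-biased permutation p estimator, which also guarantees both
percentages are positive so the fold-change is always defined. The
fold-change is control exceedance ÷ knockdown exceedance: values above 1
mean random sets beat the observed median more easily in the control
contrast than in the knockdown contrast, i.e. the set responded to the
knockdown. Both worked arithmetic examples (1/0.01 = 100 and
0.264/0.005 = 52.8) follow this orientation.

A caution on the null distribution: for a set exchangeable with random
sets, each exceedance percentage is approximately uniform, so the null
fold-change is a heavy-tailed ratio — centered at 1 on the log scale but
with wide spread (roughly half of null seeds fall outside [0.5, 2] even
with the contrasts sharing a control arm). Single null fold-changes should
therefore never be over-interpreted; order-of-magnitude enrichments are
the meaningful signal, and the acceptance script reports the median over
seeds for the null condition.

## Synthetic cohorts

The generator emulates the minimal structure each method needs, with all
randomness drawn from one explicit seeded generator (fixed seed ⇒
bit-identical output):

* **Genotypes** — founder-haplotype copying within LD blocks: each block
  holds a small pool of founder haplotypes whose allele frequencies match
  the target MAF, and every individual draws two. This yields exactly
  block-diagonal LD (between-block r² ≈ 0) at trivial cost; realized
  frequencies carry founder-pool sampling noise around the target (their
  expectation over seeds). No phasing realism, imputation, population
  structure, or relatedness is simulated.
* **Expression** — cis genes get β·dosage + noise; chain targets inherit
  α·mediator-expression, so the target's trans association with the
  mediator's cis variant vanishes on conditioning — exactly the property
  the mediation module must recover. Chains are one level deep.
* **GWAS** — a liability-threshold model (liability = Σβ·dosage + N(0,1),
  cases above a quantile) with per-variant linear regression on case
  status, the score-test equivalent of logistic regression in the
  small-effect regime. Note that every planted locus inflates total
  liability variance and thereby dilutes all other loci's marginal
  signals; fixture effect sizes account for this.
* **DE statistic tables** — three arms (untreated / control siRNA /
  knockdown), contrasts sharing the control arm as in a real knockdown
  design, with a per-replicate latent factor shared by the target set
  inside every arm so the set co-fluctuates in both contrasts.
* **Component matrix** — cluster prototypes plus per-gene noise, giving
  correlated within-cluster and near-orthogonal between-cluster profiles.

What passing these tests shows is that each method recovers the structure
it assumes when that structure is actually present, at realistic
calibration levels; it does not show robustness to confounding, population
stratification, assay batch effects, or mis-specified LD — none of which
the generator produces.

### Fixture scales

`make_fixture` writes ready-to-run cohorts at two scales: tiny (200
individuals × 500 variants × 50 genes; genotypes as VCF with GT+DS) and
standard (2,000 × 5,000 × 500; genotypes as a dosage TSV, where a VCF of
that size would be pointlessly slow to parse). The tiny scale exists for
smoke tests and determinism checks: at n = 200, effect sizes large enough
to clear p < 5×10⁻⁶ are necessarily unrealistic (cis β = 1.2 SD/allele,
liability effects ≈ 1.4), and the GWAS-only decoy locus is omitted because
no realistic effect would be detectable. The standard scale uses
conventional magnitudes (cis β = 0.6, liability effects ≈ 0.4, a
41-target master regulator) and is the scale at which end-to-end recovery
is asserted. The calibration suites in `locus2gene.validation` use
n = 5,000 (colocalization), 500 replicates (MR coverage), 2,000 replicates
(FS type-I), and n = 2,000 with 41 targets + 100 decoys (master-regulator
recovery) — sizes chosen so each suite completes in seconds while leaving
binomial noise well inside the asserted bands.

## Numerical and design decisions

* p-values from t or normal tails are floored at the smallest positive
  double rather than returned as 0; a p of exactly 0 in input GWAS rows is
  rejected, not silently floored.
* Zero-variance variants are skipped in mapping (logged), rejected by MAF
  QC, and render LD overlap not-testable.
* HWE uses a 1-df chi-square on hard calls (dosages rounded), matching the
  classical test; the imputation-quality filter is only applied when a
  per-variant quality column is supplied, since dosage files carry none.
* Alleles are assumed forward-strand in all inputs; harmonization handles
  swaps, never strand flips.
* "Not-testable" is distinct from "false" throughout the evidence model:
  a method whose preconditions fail contributes no line of evidence in
  either direction.
* The pipeline writes all floats with a fixed format and sorts all
  groupings, so identical configs give byte-identical output trees (the
  manifest records the output directory and is the one file excluded from
  that guarantee across differing destinations).

## Known limitations

Single-mediator models only (no joint or structural-equation modeling);
no MR-Egger or multi-tissue colocalization; no gene-level FDR for eQTL
mapping; LD reference and eQTL panel are the same cohort; the permutation
statistic consumes externally computed DE tables and does not fit count
models itself.
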