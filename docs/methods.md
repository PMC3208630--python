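# Methods

`pamethyl` implements a genome-wide differential-methylation comparison
between a small number of cases and controls — the design of a pilot
primate study: visceral adipose tissue from prenatally androgenized (PA)
female rhesus monkeys versus controls, 5 vs 7 animals in the infant arm
and 5 vs 8 in the adult arm, assayed on a human 27,578-probe CpG
methylation array.  This note records the models, the choices made where
the design was genuinely open, and what the synthetic benchmarks do and
do not demonstrate.

## Beta values and quality control

Methylation at each CpG is the beta value, the methylated fraction of
total locus intensity, β = M/(M+U) ∈ [0, 1].  `compute_beta` uses the
plain ratio; a configurable denominator offset (default 0) is available
for low-intensity stabilization.  Negative background-corrected
intensities are clamped to 0 so β stays in range; M+U = 0 yields a
missing value, not an error.

Probes are filtered on detection p-values (signal above background): a
probe is kept iff p < 0.01 in all samples (both threshold and the
required sample fraction are configurable; the strict default is
deliberate for a small-n study where a single undetected sample is a
third of a class).  Samples are screened by PCA on the probe-mean-imputed
beta matrix; a sample is flagged as an outlier when any of the top 5
principal-component scores exceeds 3 SD (the 3-SD rule is this package's
choice; the upstream analysis reported PCA outlier screening without
printing a rule).  The top components are then regressed on technical
covariates — ordinary least squares for continuous covariates (DNA
amount, OD 260/280), logistic regression with a likelihood-ratio test
for nominal ones (batch/plate).  Perfect separation in the logistic
screen is reported as a flag, not an exception.

## The simultaneous Bayesian test (BCSVD)

All probes are tested in a single model rather than one at a time.  The
beta matrix is standardized per probe (mean 0, variance 1; probes with
sd ≤ 1e-9 are dropped — a numerically constant column never has sd
exactly 0 in floating point) and decomposed as Z = U D Vᵀ.  All singular
values above 1e-10 are retained (at most n−1 after centering); no
further truncation is applied.  A Bayesian probit classifier is fitted
on the sample scores T = U D:

u_i ~ N(μ + t_iᵀγ, 1), y_i = 1[u_i > 0], γ ~ N(0, τ²I), μ ~ N(0, 100)

with τ² = 100 by default.  The latent-variable augmentation makes every
conditional conjugate and the model is fitted by Gibbs sampling.  The
original method's likelihood, prior and statistic are not recoverable
from the source description ("Bayesian classification", "SVD dimension
reduction", "Gibbs sampler", "permutation empirical P"); this probit
reconstruction is exactly that — a reconstruction — and is flagged as
such here.

Numerical choices that matter:

- **Multiple pooled chains.**  Each fit runs 4 independent chains from
  overdispersed starts and pools the kept draws (default 2,000
  iterations, 500 burn-in per chain for the observed fit; 600/100 inside
  permutations).  With separable or near-separable data — the normal
  situation when 163 loci differ by Δβ = 0.3 against noise of 0.05 — the
  posterior forms a long flat-likelihood ridge that a single
  data-augmentation chain traverses very slowly; single-chain statistic
  levels were observed to vary ~3-fold across chain seeds, which is
  enough to silently erase or restore the entire significant set.
  Pooling removes this level noise.
- **Probe statistic.**  Probe effects are the posterior mean of
  b = V γ.  Because probes enter standardized, these effects are
  scale-free across probes.  An sd-standardized version (posterior mean
  divided by posterior SD) was evaluated and rejected: under strong
  separation the posterior widens along the ridge, so dividing by the SD
  shrinks the statistic exactly when the signal is strongest, inverting
  the intended ranking and in some datasets collapsing recall entirely.
- **Permutation p-values.**  Labels are permuted B times (default 99);
  the standardization and SVD do not involve the labels, so the
  decomposition is computed once and only the classifier is refitted per
  permutation.  Each probe's observed |effect| is ranked within its own
  permutation distribution with the add-one correction,
  p = (1 + #{|stat_perm| ≥ |stat_obs|})/(B+1), so p ≥ 1/(B+1).  Ties
  count as exceedances (conservative).  A pooled reference (all probes'
  permutation statistics together) is available behind a flag but is not
  the default: with many strong probes the pool's right tail is
  dominated by the signal probes' own permutation statistics and the
  behavior becomes erratic.  When B reaches the number of distinct
  label assignments (C(n, n_cases)), permutations are enumerated
  exhaustively instead of sampled.
- **Seeds.**  A single master seed expands into per-chain and
  per-permutation seeds through a counter scheme
  (`SeedSequence(seed, spawn_key=...)`), so enlarging B never changes
  earlier permutations.

Known limitation: at n = 12, about 4% of random label permutations are
one-pair swaps that agree with the true labels in 10 of 12 samples.
Their statistics genuinely approach the observed ones, so each signal
probe's per-probe empirical p has a floor near the number of such
near-replicas over B+1.  This caps single-dataset recall (observed range
0.85–1.0, median ≈ 0.99, across seeds at the infant-arm conditions) and
is a property of permutation testing at this sample size, not of the
implementation.

## Cross-species probe validity

Human-designed 50-nt probes (each ending on the interrogated CpG) are
re-aligned to the target genome before their results are trusted.
Alignment is exhaustive and ungapped on both strands — the criteria
count substitutions within a fixed 50-nt window, so gapped alignment
adds nothing at this length — with all placements at ≤ 7 mismatches
reported (the validity cut is at 3; the wider net lets the 4+ class be
diagnosed as TOO_MANY_MISMATCHES rather than NO_HIT).  The criteria:

1. the probe's 3′-terminal CG must match the genome exactly at both
   bases (single-base extension requires it);
2. at most 3 mismatches in 50 nt (identity ≥ 94%);
3. with multiple placements, the probe is valid only if exactly one hit
   is a perfect match, and that hit is retained.  "Perfect" here means
   100% identity *and* an intact anchor (the conjunction is this
   package's reading; an unanchored perfect body cannot be extended).
   A unique hit with ≤ 3 mismatches is valid without invoking
   criterion 3, which by its wording applies only when multiple matches
   are found.

A surviving probe keeps its human gene annotation only if the aligned
interval overlaps the 1.5 kb window upstream of the annotated gene's
TSS or the gene body.  The upstream window is strand-aware
([TSS−1500, TSS) on +, the mirrored interval on −; the source is silent
on strand).  Probes are aligned as designed, without in-silico bisulfite
conversion, matching the genomic (not converted) alignment used
upstream.  Coordinates are 0-based half-open internally; BED6 is read
and written natively and GFF3 (1-based inclusive) is converted on read.

## Validation and power

LOOCV refits the entire pipeline (standardize → SVD → probit) on n−1
samples per fold and predicts the held-out sample from its posterior
predictive probability, thresholded at 0.5 with ties going to control.
The probe set is fixed once, before cross-validation — matching the
validated design — which makes the estimate optimistic with respect to
the selection step; a `selector` hook enables nested re-selection for
callers who want the honest-but-noisier version.

Power uses the generalized likelihood ratio λ between the intercept-only
null and the fitted model: power = 1 − Pr(χ²(1) ≥ −2 ln λ).  The 1-df
reference for a multi-probe alternative is implemented exactly as the
source prints it; the single degree of freedom is the source's stated
choice, not a derived one.

Sample clustering is agglomerative with Euclidean distance and average
linkage (the defaults of the classic microarray viewers), deterministic
given input order; dendrograms are written as Newick text.

## Phenotype association and enrichment

Clinical labels follow the cohort's printed rules: intermittent or
anovulatory cycling for mean cycle length > 34 days; hyperandrogenism
for testosterone ≥ 0.32 ng/ml (inclusive; the threshold is the control
mean + 1 SD from a larger reference colony and is accepted as a literal
override, or can be re-derived from supplied controls); polycystic ovary
morphology for ≥ 10 follicles per greatest ovarian diameter.

Probe-wise association of methylation with a numeric phenotype is OLS
with the Pearson R and two-sided slope p, run within a mandatory sample
subset (cases), with the control subset produced alongside as the
negative comparison.  Raw, Bonferroni and Benjamini–Hochberg columns are
all reported and the caller chooses the threshold: the evaluated study's
reported associations (raw p 0.018–0.049) cannot survive correction over
hundreds of probes, so the correction policy is left explicit rather
than silently applied.

Over-representation is the right-tailed Fisher test computed as the
exact hypergeometric tail (set sizes are small; no approximation),
against a caller-supplied reference list — e.g. the array's own gene
list rather than the genome — so array design bias is not mistaken for
biology.

## The synthetic-data generator

The generator is the ground-truth source for every downstream test.  It
emulates: the 5 vs 7 (infant) and 5 vs 8 (adult) designs; a
27,578-probe array down-sampled to 2,163 probes with 163 differential
(the infant arm's reported count); beta noise as a clipped normal
around per-probe baselines drawn from U(0.15, 0.85) (the source states
no noise model; the clipped normal is a stand-in chosen for simplicity,
not a claim about real arrays); additive batch effects on the beta
scale, with batches assigned round-robin; two-channel intensities as a
Poisson total split binomially so E[M/(M+U)] equals the input β;
phenotype tables shaped like the study's (controls with basal
testosterone 0.05–0.27 ng/ml and 24–34-day cycles, cases elevated on
both, technical covariates independent of group); and a 2-chromosome
× 50 kb toy genome with 20 genes hosting seven planted probe classes,
one per validity-criterion outcome.

What passing the benchmarks does *not* show: real beta values are
bimodal with heteroscedastic, bounded noise and probe-dependent dye
chemistry; real cross-species alignment faces repeats, indels and
assembly gaps that the ungapped toy-genome contract excludes by
construction; and the default effect size (Δβ = 0.3 at SD = 0.05) is a
strong-signal regime chosen to make the study's reported
100%-sensitivity/100%-specificity LOOCV reproducible, not an estimate
of typical methylation effect sizes.

## Problem sizes

Default benchmark sizes were chosen so every check runs on a laptop:
2,163 probes × 12 samples for the infant-arm replica (B = 99
permutations, 4 chains × 2,000 iterations observed, 4 × 600 inside
permutations), 500 × 12 for the effect-size sweep, 100 × 12 × 50 seeds
for null calibration, and 50 kb toy genomes for alignment oracles.
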