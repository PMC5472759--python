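# Methods

This note documents the statistical procedures implemented in `rccpipe`,
the conventions pinned where the underlying methods are commonly stated
ambiguously, the design of the synthetic-data generators, and the known
limitations of both.

## Normalization and differential expression

Raw counts are **upper-quartile normalized**: each sample is rescaled so
that the 75th percentile of its *nonzero* counts equals the across-sample
mean of those percentiles. Using the cohort mean as the common target makes
the operation idempotent and leaves within-sample gene ordering unchanged.
Samples with no nonzero counts are rejected rather than silently repaired.

Differential expression uses the two-sided **Welch (unequal-variance)
t-test** on log2(x + 1) of the normalized counts, with the group-2-minus-
group-1 convention throughout. The variance assumption is a deliberate
choice: with small, possibly unequal groups the pooled-variance test is
fragile, and Welch is the robust default. The input scale for testing
(normalized counts vs log values) is likewise a documented choice — testing
on log2 values keeps the fold-change filter and the test on the same scale.
Degenerate genes are resolved deterministically: both groups constant with
equal means gives t = 0 (p = 1); constant with unequal means gives ±∞
(p = 0), signed by the mean difference.

A gene is called **up** when its log2 mean difference exceeds log2(2) = 1
and its Benjamini–Hochberg adjusted p-value is below 0.05 (symmetrically
for **down**); both thresholds are configurable but those defaults define
the standard two-fold / FDR < 0.05 rule. BH adjustment delegates to
statsmodels' step-up implementation; the test suite verifies it against the
literal min<sub>j≥i</sub> m·p<sub>(j)</sub>/j definition.

"Most differentially expressed genes" as a co-clustering filter is
interpreted as highest across-sample variance (no contrast is defined in
that context); ties are broken lexicographically by gene identifier so the
filter is deterministic.

## Ranked-list gene-set enrichment

The enrichment procedure is bespoke and fully specified here:

1. Rank all genes by descending Welch t (ties lexicographic by id).
2. For each set, map the member ranks to u<sub>i</sub> = r<sub>i</sub>/N and
   apply a one-sample **two-sided K–S test** against Uniform(0,1). The
   u = r/N convention (rather than (r−0.5)/N) is the simplest; the
   difference is O(1/N) and irrelevant at transcriptome scale, but it is
   pinned for reproducibility. The p-value uses the exact two-sided null
   for ≤ 35 members and the asymptotic Kolmogorov distribution beyond —
   the usual small-sample/asymptotic split.
3. BH-adjust the K–S p-values across all tested sets; q < 0.05 is the
   pass criterion.
4. For every set compute the **partial AUC over the top 10%** of the list:
   with k = ⌈0.10·N⌉, walk positions 1..k and average the fraction of the
   set's in-list members seen so far. This normalization puts the score in
   [0, 1] — a set sitting wholly at the very top of the list scores
   1 − (m−1)/2k ≈ 1, and random placement scores ≈ 0.05 — which is the
   only scale on which the 0.25 signature threshold is meaningful (an
   unnormalized area over a 10% truncation is bounded by 0.1).
5. Sets passing the K–S filter are reported first, ordered by descending
   partial AUC.

The K–S test is two-sided (it detects clustering at either end), while the
AUC is one-sided toward the top of the list; a `direction` flag flips the
ranking for the opposite contrast. Sets with no genes in the matrix are
reported with `n_in_list = 0` and no statistics rather than dropped.

## Signature Z-scores

The per-sample raw score of a signature is the mean over the signature's
in-matrix genes of the gene-wise median-centred log2 values. The underlying
per-sample score is not uniquely determined by the activation rule alone
("z above 1 s.d."), so this mean-of-centred-values definition is a
documented interpretation. Scores are standardized with the cohort mean and
**sample** (n−1) standard deviation; activation is z > 1.0 by default. A
zero-variance cohort yields z = 0 everywhere and no activations, with a
warning, rather than NaNs.

## Genotype stratification

The three boolean alteration flags — VHL inactivated, MYC activated, CDKN2A
deleted — map to: VIM = all three; VM = VHL∧MYC without CDKN2A; V = VHL
only; everything else, including VHL∧CDKN2A without MYC and all VHL-intact
samples, is "other". The partition is total and mutually exclusive.
MYC activation may be sourced from a copy-number flag or from a signature-z
call; the copy-number flag takes precedence when both are available, since
co-occurrence analyses are conventionally defined on copy-number calls
while expression-based activation serves prognostic scoring. Stage
frequencies are simple per-stage fractions with counts reported alongside;
group comparisons use the Pearson chi-square without continuity correction
(df = k−1), with zero expected cells rejected as a validation error.

## Copy-number minimal common regions

Gene-level segmented copy values (diploid ≈ 2) are summarized by per-gene
cohort means ordered by (chromosome, start), with 1-based inclusive
coordinates. The **minimal common region** for a direction (gain/loss) and
threshold is anchored at the cohort peak gene — the gene with the extreme
cohort mean — so multi-peak chromosomes do not conflate regions: each
altered sample contributes its maximal run of consecutive genes beyond
threshold that contains the peak, and the MCR is the intersection of those
runs. A sample beyond threshold somewhere on the chromosome but not at the
peak contributes no run; the result is then reported empty with
diagnostics instead of being silently narrowed. The default gain threshold
is 2 + 0.3 on the segmented-copy scale (δ = 0.3 configurable). Formal
significance of a region (GISTIC-style background modelling) is out of
scope; a significant region is an input, or arises from the planted-peak
rule on synthetic data.

**Percentile rank** of a candidate driver within a region is the fraction
of the *other* region genes whose mean is strictly below the driver's; all-
equal regions therefore score 0.

## Cross-species comparison

Homolog mapping is **strict 1:1**: a pair is used only if its source and
target identifiers each occur exactly once in the whole map. Real homology
tables contain many-to-many entries with no principled resolution at this
level, so they are dropped with a logged count.

Dataset offsets are removed by **per-cohort gene-wise median centring**
before combining cohorts. This is a deliberate, transparent batch
adjustment: it removes any cohort-constant per-gene offset exactly (which
is the component that corrupts centroid correlations) and nothing else. It
does not model latent structured batch effects the way surrogate-variable
methods do; analyses on real multi-platform data should treat it as the
minimal adjustment it is.

A cohort's **centroid** is the per-gene median over its samples (even
cohorts use the midpoint convention). Cohorts are compared by Pearson
correlation between centroids over the shared gene space; zero-variance
centroids make the correlation undefined and raise an error naming the
centroid. Co-clustering uses average-linkage agglomeration on
1 − Pearson correlation between samples ("centred" clustering: the
correlation itself centres each profile), over a top-variance gene filter;
flat labels come from cutting the dendrogram at a requested cluster count.
Adjustment always precedes centroid computation.

## Survival models

Kaplan–Meier estimation, the unweighted log-rank test and Cox
proportional-hazards fitting are delegated to lifelines behind validated
interfaces. Cox fits use the **Efron approximation** for tied event times
(less biased than Breslow at no practical cost) and enter genotype as
indicator covariates with **V as the reference**; stage and grade enter as
ordinal integers 1–4, since no richer coding is defensible for four-level
ordinal clinical variables. Constant covariates are rejected; monotone
likelihood (separation) returns a fit flagged non-converged rather than an
exception. Times must be positive and event indicators 0/1; these are
enforced at the container level so every estimator can assume them.

## Synthetic-data generators

All generators are deterministic given the spec seed (a single
`numpy.random.default_rng` stream per call) and return truth objects
sufficient to score recovery without re-deriving the simulation.

- **Two-group counts**: gamma-Poisson (negative-binomial) counts with mean
  `base_mean`, overdispersion `dispersion` (variance μ + dμ²), per-sample
  log-normal library-size factors (sd 0.2 on the log scale), and the
  planted signal genes' means multiplied by 2^`effect_log2fc` in group 2.
  This is the minimal generative model under which upper-quartile
  normalization is meaningful. Default 10 samples per group reflects a
  small-cohort design; the defaults are free parameters of the synthetic
  design, not estimates of any real study.
- **Gene-set cohort**: Gaussian log2 values (per-gene baseline + unit
  noise), `collection_size` disjoint random sets, exactly one shifted by
  `effect_log2fc` standard deviations in group 2. Disjoint null sets give
  clean type-I-error accounting. Defaults (5,000 genes, 10 vs 10, one
  100-gene set shifted +1 s.d. among 19 nulls) define the enrichment
  operating point exercised by the acceptance checks.
- **Cross-species cohort**: latent per-gene subtype centroids
  ~ N(0, subtype_sd) shared by both species; each sample is its centroid
  plus N(0, noise_sd) noise plus a species-constant per-gene offset
  ~ N(0, batch_shift). Defaults subtype_sd = 3, noise_sd = 1 set the
  signal-to-noise 3 regime; 80% of genes get clean 1:1 homolog pairs and
  the rest map many-to-one so the strict 1:1 filter is exercised.
- **Copy number**: genes on one chromosome at 1 Mb spacing, baseline
  N(2, σ) with σ = 0.05 by default so that baseline noise sits several
  standard deviations below the default calling threshold (2.3) and the
  planted signal is the only region — a consistency requirement between
  the generator and its truth contract, since the planted amplicon is
  defined as the exact intersection of the per-sample gained intervals.
  Each altered sample gains over the amplicon extended by up to `pad`
  genes per side, with at least one interval flush at each amplicon
  boundary so the intersection equals the amplicon; the driver gene gets
  an extra gain in a stated fraction of altered samples.
- **Survival**: exponential event times with hazard
  h₀ · hazard_ratio(genotype) (h₀ = 1/1000 per day), independent
  exponential censoring with rate mean-hazard · c/(1−c) so the expected
  censored fraction is `censor_rate` (independent of genotype, keeping
  log-rank/Cox recovery unbiased); stage and grade are drawn 1–4 with
  probabilities tilted by hazard^(0.5·(level−1)) so adjustment has
  something to adjust for.

### What the generators do and do not emulate

They reproduce the *statistical structure* the analyses assume — planted
rank shifts, shared latent centroids with cohort-constant offsets, exact
interval intersections, proportional hazards. They do not mimic RNA-seq
GC/length biases, real copy-number noise spectra, non-proportional
hazards, or informative censoring. Passing recovery tests therefore
demonstrates correctness of the procedures under their own assumptions,
not robustness to real-data violations of those assumptions.

## Numerical choices and problem sizes

Exact ties in every ranking are broken lexicographically by identifier;
all "sorted first/then" orderings use stable sorts, so outputs are
bit-reproducible. The acceptance script runs 100 seeded cohorts per
recovery analysis, n = 2,000 for Cox coefficient recovery, and 1,000 null
simulations for log-rank calibration — sizes chosen so each rate estimate
has a standard error comfortably below the margins being checked while the
whole script completes in well under a minute on one CPU.

## Known limitations

- The batch adjustment removes only cohort-constant per-gene offsets (see
  above).
- The MCR intersection-of-runs rule is a self-contained reconstruction of
  a minimal common region from gene-level copy values; whether it matches
  the output of background-model-based tools on real cohorts is not
  claimed and not testable here.
- Upstream alteration flags (mutation calls, methylation, GISTIC
  thresholds) are inputs, not products of this package.
- Single-contrast designs only: no multi-group DE, no shrinkage/dispersion
  modelling, no permutation-based weighted enrichment scores, no
  time-varying covariates or frailty terms.
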