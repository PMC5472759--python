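# rccpipe

A pipeline for connecting genetically engineered mouse (GEM) kidney-tumour
transcriptomes to human renal cell carcinoma (RCC) genomics. It implements,
as tested reusable library code with a CLI, the analyses used to compare
mouse papillary/clear-cell RCC models against human ccRCC/pRCC cohorts:

- **Ranked-list gene-set enrichment.** Genes are ranked by the between-group
  Welch *t*-statistic; for each gene set a one-sample two-sided
  Kolmogorov–Smirnov test asks whether the members' normalized ranks
  *u<sub>i</sub> = r<sub>i</sub>/N* are Uniform(0,1); K–S *p*-values are
  Benjamini–Hochberg controlled at 5% FDR across sets; surviving sets are
  ranked by the normalized partial AUC of the set-recovery curve over the
  top 10% of the list, with AUC > 0.25 flagging top signatures.
- **Signature activation.** A per-sample score (mean of gene-wise
  median-centred log2 values over a signature, e.g. a MYC-activation
  pathway) is standardized across the cohort; samples with *z* > 1 s.d.
  above the mean are called activated.
- **Genotype stratification.** Per-sample VHL/MYC/CDKN2A alteration flags
  map to V (VHL alone), VM (VHL+MYC), VIM (VHL+MYC+CDKN2A) and "other",
  with per-TNM-stage alteration frequencies and chi-square enrichment.
- **Survival models.** Kaplan–Meier curves per genotype stratum, unweighted
  log-rank tests, and Cox proportional-hazards fits with V as the reference
  class, optionally adjusted for ordinal TNM stage and Fuhrman grade.
- **Copy-number minimal common regions.** Per-gene cohort means by genomic
  position, the minimal common region (the consecutive-gene run beyond a
  copy threshold shared by every altered sample around the cohort peak),
  and percentile ranking of a candidate driver within a region.
- **Cross-species centroid correlation.** Mouse genes are collapsed onto
  human identifiers through strict 1:1 homolog pairs, cohort-constant
  offsets are removed by per-cohort gene-wise median centring, cohorts are
  summarized by per-gene median centroids, and compared by Pearson
  correlation and average-linkage co-clustering on correlation distance.
- **Normalization and differential expression.** Upper-quartile
  normalization of counts, log2(x+1) transform, Welch *t*-tests, and
  two-fold / FDR < 0.05 up/down calls with Venn overlap accounting.
- **Synthetic cohorts.** Deterministic generators for every input class
  (negative-binomial two-group counts, gene-set cohorts, two-species
  subtype cohorts, planted copy-number amplicons, genotype-dependent
  exponential survival) with truth objects for scoring recovery.

## Worked example

Simulate a 5,000-gene, 10 vs 10 cohort in which one of five 100-gene sets
is shifted up by 1 s.d. in group 2, then run the enrichment procedure:

```python
import rccpipe as rp

spec = rp.SimulationSpec(n_genes=5000, n_samples_per_group=10, seed=11,
                         signal_set_size=100, effect_log2fc=1.0)
m, collection, activated = rp.simulate_gene_set_cohort(spec, collection_size=5)
result = rp.enrich(m, m.sample_ids[:10], m.sample_ids[10:], collection)
print(result.round(4))
```

```
      n_in_list       D    p_ks    q_ks  auc_top  pass_ks  pass_auc
SET4        100  0.7060  0.0000  0.0000   0.5528     True      True
SET1        100  0.0788  0.5638  0.5970   0.0659    False     False
SET3        100  0.1230  0.0970  0.2426   0.0503    False     False
SET5        100  0.0878  0.4238  0.5970   0.0416    False     False
SET2        100  0.0768  0.5970  0.5970   0.0383    False     False
```

The planted set (SET4) has an extreme K–S departure from rank uniformity
(D = 0.71, q ≈ 0) and a partial AUC of 0.55 — far above the 0.25 signature
threshold — while the four null sets sit near the random-placement
expectation (≈ fraction/2 = 0.05) and fail the FDR filter.

Genotype-stratified survival on a simulated cohort with hazard ratios
1 : 2 : 3 for V : VM : VIM (300/150/150 patients, 20% censoring):

```python
spec = rp.SimulationSpec(seed=11, censor_rate=0.2,
                         hazard_ratios={"V": 1.0, "VM": 2.0, "VIM": 3.0})
clinical = rp.simulate_survival(spec, ["V"]*300 + ["VM"]*150 + ["VIM"]*150)
stat, df, p = rp.logrank_test(
    [clinical[clinical.genotype == g] for g in ("V", "VM", "VIM")])
fit = rp.cox_fit(clinical, ["genotype", "stage", "grade"])
```

This prints `log-rank chi2=99.04 df=2 p=3.11e-22`, and the Cox fit recovers
the planted effects with V as reference: hazard ratio 1.94 for VM (truth 2)
and 3.13 for VIM (truth 3), with near-null stage/grade coefficients as
simulated.

The same stages are available as CLI subcommands, each reading a YAML
config and writing tab-separated outputs plus a run log:

```bash
rcc simulate --kind geneset --config sim.yaml --seed 1 --out sim/
rcc enrich --config enrich.yaml --out enr/
rcc de | classify | mcr | crossmap | survive ...
```

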