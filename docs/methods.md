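# Methods

## Estimand and sampling model

The analysis treats the allele as the sampling unit. For a biallelic SNP
with risk-allele frequency `p1` in cases and `p0` in controls, the target of
estimation is the allelic odds ratio `OR = [p1/(1−p1)]/[p0/(1−p0)]`. Under
retrospective case-control sampling with Hardy–Weinberg genotypes within
each stratum, the 2×2 allele-count table is the sufficient statistic, which
is why both the association test and the synthetic generator are phrased in
terms of `(p0, OR)` pairs: the generator draws controls `Binomial(2, p0)`
and cases `Binomial(2, p1)` with `p1` the image of `p0` under the
allelic-odds map. This "allelic retrospective sampling" is exactly the model
under which the allelic OR is the estimand; no liability-threshold layer is
introduced, and nothing in the pipeline requires one.

## Association testing and QC

* Test statistic: uncorrected 1-df Pearson χ² on the allele table (the
  classic PLINK-style allelic test). No continuity correction is applied by
  default; Fisher's exact test is available for small cells.
* Interval: Woolf log-OR interval with variance `1/a+1/b+1/c+1/d`. A zero
  cell triggers the Haldane–Anscombe +0.5 correction for the OR/CI only,
  flagged in the output.
* HWE QC: 1-df goodness-of-fit χ² at the sample allele frequency,
  **controls-only by default**. Under case-control sampling with a real
  effect the pooled sample is a mixture of two binomial strata with
  different allele frequencies, and the resulting Wahlund heterozygote
  deficit makes pooled-sample HWE tests reject the strongest true signals —
  on cohorts simulated at the bundled parameters the HLA-C proxy
  (OR ≈ 4) fails pooled HWE routinely while being exactly HWE within each
  stratum. Combined- and case-sample options exist for diagnostic use.
  SNPs with HWE P < 0.05 are excluded before analysis (configurable).
  Monomorphic SNPs return P = 1 by convention, separately flagged.
* Multiplicity: Bonferroni gate `p < 0.05/m`, `m` defaulting to the number
  of SNPs analysed after HWE exclusion.

## Score, panels, missing data

The GRS is the unstandardised weighted allele count `Σ dosage·ln(OR)` with
in-sample re-estimated ORs as default weights; a literature-OR column can be
substituted. Panel variants are defined by significance rules (all, P<0.1,
P<0.05, Bonferroni, HLA-only, HLA-removed, proxy-substituted), always
pruning the declared LD partner (of the two HLA-C tags only the
HLA-C*06:02 proxy is scored; the "ALL" panel therefore scores 37 of 38
SNPs). Samples missing any panel dosage are excluded listwise — matching
the study behaviour where a handful of cases dropped out of the score —
with optional mean-dosage imputation that fills the score but keeps the
incompleteness flag.

Quartile cutpoints are the empirical 25/50/75 percentiles of the
**control** score distribution (this reproduces the published even
123/122/122/123 control split for 490 controls with continuous scores);
binning is half-open `[Q_k, Q_{k+1})`. Per-quartile odds ratios against the
bottom quartile are computed from the 2×2 sample counts with Woolf CI and
χ² P; a logistic route with the quartile as a categorical predictor is also
provided and — being a saturated model — necessarily returns the same point
estimates with Wald-based uncertainty. The published top-quartile OR in the
source setting does not equal its count ratio and its estimator is
unstated; this package reports what it computes and does not force that
number.

## ROC and DeLong machinery

AUC is the tie-aware Mann–Whitney statistic (ties weight ½), identical to
the trapezoidal area of the plotted curve. Variances and the paired
covariance use DeLong placement values computed via midranks; paired
comparisons restrict to samples complete on both panels so the pairing is
valid, and disjoint-cohort comparisons (training vs test) use the same
z-statistic with zero covariance. Classification thresholds are midpoints
between adjacent distinct scores with sentinels beyond the extremes
("positive iff score ≥ t"); the Youden threshold takes the lowest maximiser
of `tpr − fpr`. Degenerate comparisons (identical scores, zero variance)
return Δ = 0, P = 1.

## Logistic evaluation

Logistic models are fitted by statsmodels' Newton/IRLS maximum-likelihood
solver (tolerance 1e-8, 100 iterations); (quasi-)separation is detected and
flagged as non-convergence rather than raised. "Variance explained" is
reported as Nagelkerke R² by default — the usual convention in the GRS
literature — with McFadden available; the source study did not name its
pseudo-R², so no specific printed value is targeted. Sub-phenotype
associations are within-case logistic fits of the trait on the raw GRS
(OR per score unit; a per-SD option exists because the published scale is
unstated), requiring ≥ 20 informative cases.

## Internal validation

The cohort is split 75/25 at random, stratified by case status and fully
seeded. Association ORs, panel membership and weights are re-estimated on
the training split only; both splits are scored, AUCs are compared with the
unpaired z-test, and confusion metrics are evaluated at the training-set
Youden threshold. Because the panel and weights are refit on the training
data, the training AUC carries a small optimism (mean ΔAUC ≈ 0.016 on
cohorts simulated at the bundled 16-SNP parameters), so train/test AUCs are
statistically indistinguishable (P > 0.05) in about 91% of seeded
replicates rather than the nominal 95% — the tests assert a band safely
below that observed rate.

## Power

Power of the allelic test is the two-sided normal approximation for two
proportions with `2n` alleles per stratum: pooled-variance null SE,
unpooled alternative SE, both tails counted (so OR = 1 returns exactly α).
Against Monte-Carlo power of the actual χ² test on a 3×3 grid of
(p0 ∈ {0.1, 0.3, 0.5}) × (OR ∈ {1.15, 1.3, 1.7}) at 480/490 the
approximation agrees within 0.03.

## Synthetic generator: what it does and does not emulate

Defaults encode the emulated study's conditions: 480 cases / 490 controls;
the bundled 38 control RAFs and ORs as targets; the HLA-C pair coupled at
r² = 0.79; 0.1% per-cell missingness (completely at random); sub-phenotype
prevalences nail 52.3%, psoriatic arthritis 33.8%, family history 43.3%,
late-onset 25% (the published early/late split is not tabulated; 25% is the
literature figure for onset at ≥40 years); per-unit-GRS effects
ln(0.92), ln(0.73), ln(0.56), ln(1.83) respectively. The per-cell missing
rate is set to 0.1% rather than the 2% upper bound implied by the reported
per-SNP success rate because listwise exclusion on a 16-SNP panel at 2% per
cell would drop ~28% of samples, whereas the study lost only 11 of 480
cases; 0.1% reproduces both reported facts.

Two structural caveats:

* **LD feasibility.** The published r² = 0.79 between the two HLA-C tags is
  not attainable at the printed (rounded) control frequencies 0.112 and
  0.222 — the Lewontin bound caps r² at ≈ 0.44 in controls and ≈ 0.63 in
  cases. The generator raises a feasibility error (reporting the attainable
  bound) unless clipping is requested; the bundled default spec clips |D| to
  the per-stratum bound, which preserves the qualitative structure (a
  strongly coupled proxy pair) without touching any scored panel, since the
  second tag is always LD-pruned.
* **What passing tests show.** The generator reproduces the *statistical*
  structure the analysis assumes — independent HWE strata, one LD pair,
  MCAR missingness, logistic sub-phenotype links in the raw score. It does
  not emulate population structure, relatedness, genotyping batch effects,
  non-random missingness, or LD beyond the single declared pair, so green
  pipeline tests certify the arithmetic and the sampling theory, not
  robustness of the method to those real-data complications.

Sub-phenotype assignment solves the logistic intercept by root-finding so
the marginal prevalence among the simulated cases hits its target exactly
in expectation; assignment uses the complete pre-missingness generating
score (weights = ln of the target ORs over the 16-SNP generating panel).

## Determinism and problem sizes

Every stochastic step (genotypes, LD haplotypes, missingness masks,
sub-phenotypes, validation splits) flows from explicit integer seeds via
`numpy.random.default_rng`; equal seeds give byte-identical cohorts and
identical splits. The test suite's simulation-based properties use 10–30
replicate cohorts of 970 × 16–38 genotypes, 20 000–100 000 permutation or
Monte-Carlo draws for resampling oracles, and 10⁴–10⁵-individual strata for
distributional checks — sizes at which every asserted band has several
standard errors of margin while the whole suite runs in well under a
minute.
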