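# Methods

This note describes the statistical methods implemented by `ewas_hypogen`,
stage by stage, in the order the pipeline runs them.

## Case and control definition

Case status is derived from repeated questionnaire responses. A sample is a
**case** if they ever reported the symptom *and* a doctor visit for it; a
**less-severe** stratum holds those who reported the symptom but never a
doctor visit; **controls** never reported the symptom (reports marked mild
at the earliest wave may be rolled into the controls). Samples with no
usable responses, a configured comorbidity, or (optionally) a first report
postdating their methylation measurement are **excluded**. A doctor-visit
report without a symptom report is treated as a data error and raised
rather than silently classified. Three sensitivity variants re-run the
pipeline with (a) comorbid samples excluded, (b) the less-severe stratum
as the case group with primary cases excluded, and (c) only
pre-measurement reporters retained.

## Methylation quality control

Probes are removed in a fixed order: sex-chromosome probes, SNP and
control probes, then probes failing detection. Removal counts are reported
per category. Probes on the published cross-reactive/polymorphic list are
*flagged* in the results but never removed, so the reader can judge hits
at those sites.

Per-probe outliers are blanked using Tukey fences at three times the
interquartile range: quartiles use linear interpolation (the type-7
convention), values **strictly** outside `[Q1 − 3·IQR, Q3 + 3·IQR]` are set
to missing (values exactly on a fence are kept), and probes with fewer
than four non-missing values are left untouched and flagged. Downstream
models are complete-case per probe, so a blanked cell drops only that
sample from that probe's regression.

## Surrogate variables

Unmeasured technical structure (batch/plate effects) is captured by
surrogate variables estimated from the beta matrix itself, protecting the
study design (intercept, case status, age) from absorption.

The number of surrogate variables is estimated by permutation parallel
analysis: the matrix is residualised on the protected design, each probe's
residuals are independently permuted across samples to build a null
singular-value spectrum, and the estimate is the number of leading
consecutive observed singular values exceeding the null's 95th-percentile,
rank by rank.

The surrogate variables themselves come from two-step iteratively
reweighted estimation. Starting from the leading right-singular vectors of
the design residuals, each iteration (default five) computes, per probe,
a nested-F p-value for association with the surrogate structure and one
for association with the protected variables given the surrogates,
converts both to local false-discovery rates (probit transform, Gaussian
kernel density estimate of the mixture, Storey-type null proportion at
λ = 0.5), weights each probe by
`(1 − lfdr(p_surrogate)) · lfdr(p_protected)`, and recomputes the singular
vectors of the row-centred, weighted matrix. Output columns are zero-mean,
mutually orthogonal, and deterministically signed. Missing beta-values are
mean-imputed per probe for this step only.

## Epigenome-wide scan

The scan is mass-univariate ordinary least squares with the methylation
beta-value as the outcome and case status as the exposure, adjusting only
for age and the surrogate variables — deliberately *not* for lifestyle or
environmental covariates, because confounding by such factors is the
signal being harvested. Each probe's model is complete-case; estimates,
standard errors, t-based 95% confidence intervals and p-values follow the
standard linear-model theory (a vectorised QR-based path handles all
complete probes in one pass). Probes with essentially zero residual
variance are reported as degenerate with an undefined p-value.

Diagnostics: genomic inflation λ is the ratio of the median observed
1-df chi-square statistic (inverse survival transform of the p-values) to
the theoretical null median, and QQ data pair order statistics with
expected quantiles `rank/(m+1)` on the −log10 scale. Hits are probes with
p **strictly** below the suggestive threshold 1e-5, ordered by p-value
with ties broken by probe id.

## Catalog trait harvesting

Each hit CpG is looked up in an EWAS-catalog store (an offline TSV or a
REST endpoint) for previously published trait associations, first by CpG
id, then by each gene symbol annotated at the probe (multi-gene
annotations are split). Traits are deduplicated case-insensitively with
whitespace collapsed; a trait found at both levels keeps CpG-level
provenance. The result is invariant to hit ordering and duplication.
Trait over-representation among the hits can be tested with Fisher's exact
test on the (hit vs non-hit) × (trait-annotated vs not) table over the
analysed probe universe; the reported odds ratio is the cross-product
ratio with a 0.5 continuity correction only when a cell is zero.

## Cohort hypothesis testing

Harvested traits are mapped onto measured cohort variables (unmappable
traits are reported, not dropped silently) and screened by the
fewer-than-five rule: for binary exposures every cell of the non-missing
exposure × condition 2×2 table must hold at least five samples; for
continuous exposures the non-missing count must reach five within cases
and within controls; exactly five is eligible.

Each eligible exposure is tested by logistic regression of the condition
on the exposure, once unadjusted and once adjusted for socioeconomic
position and age at menarche. Every model is complete-case on exactly the
variables it uses, and continuous exposures are z-scored on that
complete-case sample so odds ratios are per standard deviation. Estimates
come from maximum likelihood (iteratively reweighted least squares) with
95% Wald intervals on the log-odds scale; perfect separation,
non-convergence or unstable standard errors yield an omitted result with
the reason recorded rather than an unreliable estimate.

Descriptive case/control tables report, for binary variables, the positive
count and a percentage whose denominator is the **total** group size
including missing values, and for continuous variables the mean and
standard deviation over non-missing values; all displayed values are
rounded to one decimal, half-up. Missing counts are always shown.

## Determinism

A single seed drives every stochastic step; independent substreams are
spawned per component, so identical configuration and inputs give
byte-identical stage outputs.
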