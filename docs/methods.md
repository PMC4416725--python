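# Methods

This note documents the statistical procedures psorprs implements, the
design of the synthetic-cohort generator, the numerical conventions, and
the limitations a user should keep in mind when transferring conclusions
from simulated to real data.

## Scoring model

The polygenic risk score of individual *j* is `PRS_j = Σ_i ln(OR_i)·g_ij`
over the variants of the chosen model, where `g_ij` counts risk alleles
(0/1/2) and `OR_i` is the variant's *published* per-allele odds ratio —
weights are inputs, never re-estimated from the analysed cohort. The panel
is structured as 13 small-effect non-HLA variants plus one large-effect
HLA variant; the `snp`, `hla` and `snp-hla` models partition or combine
these, and `snp-hla-drink` adds `ln(OR_drink)` for ever-drinkers (the
never-drinking category includes light drinkers). Scores are additive
across the partition: `snp-hla = snp + hla` for every sample, which the
tests assert.

**Missing genotypes.** The default policy drops any sample missing a
genotype at a model SNP, mirroring how incompletely genotyped subjects are
usually excluded; an `expected-dosage` policy instead substitutes twice
the control risk-allele frequency (the HWE expectation), which keeps
sample size at the cost of shrinking extreme scores slightly.

## Quality control and single-variant statistics

Filters run samples → SNPs → control HWE, with the paper-standard
thresholds as defaults: keep call rate strictly greater than 90% (per
sample, then per SNP on the surviving samples) and keep SNPs whose exact
HWE p in controls exceeds 10⁻³. The HWE test is the exact conditional
test: given the observed allele counts it sums the probabilities of all
heterozygote counts no more probable than the one observed ("no more
probable" definition, not mid-p), computed with log-gamma arithmetic and
validated exhaustively against exact-rational enumeration for every table
with ≤ 50 alleles.

Association per SNP is the 1-df Pearson chi-square on the 2×2 allele
table with no continuity correction (the convention of the standard
allelic test in PLINK), `OR = ad/bc` with the Woolf interval
`exp(ln OR ± 1.96·√(Σ 1/cell))`; a zero cell triggers the
Haldane–Anscombe 0.5 correction for the OR/CI only, flagged in the
result. Power uses the noncentral chi-square with noncentrality from the
case/control allele-frequency difference implied by the
retrospective-sampling closed form (below); it matches Monte-Carlo
rejection rates to ±0.03 in the tests.

## Logistic modelling

Risk-group and continuous-PRS models are fitted by the package's own
iteratively reweighted least squares: Newton steps with step-halving,
convergence when the maximum absolute score falls below 1e-8 (50
iterations cap), Wald inference from the observed information. Two
failure modes are made explicit rather than returned as garbage numbers:
a rank-deficient design raises a singular-design error, and separated
data — diagnosed either by a failure to converge with diverging
coefficients or by "convergence" at |β| > 12, which happens because the
IRLS weights collapse to zero under separation — raise a separation
error. With a single binary predictor the fit reproduces the closed-form
2×2 log-OR and Woolf SE to 1e-6, and it agrees with an independent
maximiser (statsmodels) to 1e-6 on general designs; both are asserted in
the tests.

Risk groups are the quartiles of the control score distribution
(linear-interpolation percentiles, `numpy.percentile`). Boundary
membership is lower-inclusive: group 0 is score ≤ Q1, then (Q1,Q2],
(Q2,Q3], > Q3. Group odds ratios come from one logistic fit with
indicators for groups 1–3 (group 0 reference) plus age and sex; empty
groups are flagged and reported as undefined rather than dropped
silently. Variance explained is Nagelkerke's rescaled Cox–Snell R²; the
group × drinking interaction is a joint likelihood-ratio test of all
product terms, with empty cells of the cross-table flagged (and
collinear product columns dropped so the LRT can still be computed).
Family-history association among cases reports both a logistic slope of
history on PRS and a Welch two-sample comparison of score means.

## Discrimination

AUC is the midrank Mann–Whitney statistic — the probability a random case
outscores a random control, ties counted half — and the empirical ROC
curve is built over all distinct thresholds, so its trapezoidal area
equals the Mann–Whitney value exactly (asserted to 1e-12, ties included).
Model comparison uses DeLong's structural-component covariance estimator
for paired AUCs with a two-sided normal z-test; the implementation
matches R's pROC `roc.test` to 1e-8 and a paired bootstrap to ±0.02.
Operating points maximise the Youden index, breaking ties toward higher
specificity; which rule produced any published operating point is rarely
stated, so Youden is adopted and documented here.

## Age-of-onset analysis

All case onsets are observed events; right-censoring is nonetheless
supported throughout. Kaplan–Meier medians are the first time survival
reaches 0.5. The log-rank test is the k-group Mantel–Haenszel chi-square
with k−1 df. Cox models use the Efron tie correction (onset ages cluster
heavily on integer years); lifelines provides the estimators behind this
module's surface, with constant covariates rejected up front and monotone
partial likelihoods (e.g. a perfectly ordered binary covariate) raised as
explicit errors. Onset differences across risk groups are additionally
summarised by a one-way ANOVA F and by the difference in KM median onset
between the extreme groups.

One caveat the pipeline reports around: recruitment age mechanically
exceeds onset age in any retrospective case series, so a Cox model of
onset that adjusts for recruitment age can absorb genuine signal. The
report therefore carries both the age+sex-adjusted fit (the conventional
covariate set) and a sex-only fit; on generator output the sex-only fit
is the faithful estimate of the encoded hazard ratio.

## The synthetic-cohort generator

The generator reproduces the statistical structure the analysis assumes,
at the study's scale (3621 cases / 3350 controls by default):

* **Genotypes.** Controls are drawn per SNP from HWE at the configured
  control frequencies; cases from the retrospective-sampling law
  `P(g|case) ∝ P(g|control)·OR^g`. This makes marginal per-allele odds
  ratios exact by construction and implies the closed form
  `p' = p·OR/(1−p+p·OR)` for the case allele frequency (cases remain in
  HWE at p'). SNPs are independent (linkage equilibrium). Genotypes are
  set missing uniformly at rate 0.004, chosen so that roughly 5% of
  samples have at least one missing genotype across 14 SNPs, matching the
  scale of missing-genotype exclusions such a study reports.
* **Default panel.** One HLA-like locus with per-allele OR 8.0 at control
  frequency 0.14 and thirteen loci with ORs 1.13–1.55 at frequencies
  0.19–0.52. These defaults give an HLA-alone AUC near 0.80 and a
  combined AUC near 0.855 at study scale — the qualitative regime of the
  psoriasis panel, where the HLA locus dominates. The shipped identifiers
  (`sim_snp01`…) are synthetic stand-ins: the real panel's ids and ORs are
  user inputs via the weights TSV.
* **Exposure.** Ever-drinking has control prevalence 0.30 and OR 2.49;
  case prevalence follows from the odds transform. Drinking is
  independent of genotype given status, the simplest structure consistent
  with a null group × exposure interaction.
* **Covariates.** Age ~ Normal(30.2, 11.5) truncated to [3, 81]; sex is
  male with probability 0.585 — the study's margins.
* **Family history.** Cases only (controls are screened negative):
  Bernoulli with logit equal to logit(0.3134) plus 0.15 per PRS unit
  (centred at the case mean), giving the observed ~31% familial rate with
  a positive PRS–history association of the reported size.
* **Onset.** Exponential proportional hazards: rate
  `(1/45)·1.08^PRS`, left-truncated at one year (by memorylessness,
  1 + Exp draws — hazards stay exactly proportional). The scale 45 puts
  the median case onset near 21 years. Because an exponential onset can
  exceed a plausible recruitment age, recruitment age is lifted to the
  onset age where needed; this preserves the onset ≤ age invariant and
  the proportional-hazards structure exactly, at the cost of making case
  recruitment age right-shifted and correlated with onset (see the Cox
  caveat above). A hard upper truncation of onset at recruitment age was
  rejected: it destroys proportionality and caps the achievable median
  onset near 15 years under these age margins.
* **Randomness.** One integer seed feeds a single `numpy` Generator;
  draws occur in a documented order (per-SNP control then case dosages,
  missingness, age, sex, drinking, family history, onset), so identical
  seeds give byte-identical fixture bundles.

**What the generator does not emulate.** Linkage disequilibrium between
panel SNPs, population structure, genotyping-error patterns beyond
uniform missingness, winner's-curse inflation of discovery-cohort
weights, and a realistic onset distribution — the exponential tail is far
heavier than real onset data (real onsets rarely exceed 40 years; the
generator's can), which inflates onset means and median-onset gaps
relative to a real cohort. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the
assumed structure, not the field performance of any specific panel.

## Problem sizes and numerical conventions

Tests run the generator at reduced sizes (hundreds to a few thousand
samples) for unit-level checks and at full study scale for the
parameter-recovery and ordering properties (20 seeds for Cox recovery, 12
for AUC ordering); the acceptance script uses one full-scale cohort. The
published risk-group count table and case characteristics are recomputed
exactly from their printed counts. Quartile cutpoints use linear
interpolation; the exact HWE p-value comparison uses a 1+1e-9 relative
guard against floating-point ties; logistic convergence is max |score| <
1e-8; Cox convergence is delegated to lifelines with divergence
re-diagnosed at |coef| > 12. Status is coded 0 = control / 1 = case and
sex 1 = male / 0 = female everywhere; PLINK phenotype (1/2) and sex (1/2)
codes are translated on read, and missing PLINK phenotypes drop the
sample with a logged warning.
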