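# psorprs

Weighted polygenic risk score (PRS) analysis for psoriasis case–control
cohorts, built as a tested, reusable pipeline. It is aimed at
statistical-genetics analysts who have (a) genotypes at a small panel of
susceptibility variants — for psoriasis in Han Chinese, 13 small-effect
SNPs plus one large-effect HLA variant — (b) published per-allele odds
ratios for those variants, and (c) case/control phenotypes with age, sex,
family history, drinking status and, for cases, age of onset.

## The model

Each individual's score is a weighted count of risk alleles,

    PRS_j = Σ_i  w_i · g_ij ,      w_i = ln(OR_i) ,

where `g_ij ∈ {0,1,2}` is the risk-allele dosage of variant *i* in person
*j* and `OR_i` is that variant's published per-allele odds ratio. Four
nested scores are supported: the 13 non-HLA SNPs (`snp`), the HLA variant
alone (`hla`), all 14 variants (`snp-hla`), and all 14 plus
`ln(OR_drink)` for ever-drinkers (`snp-hla-drink`).

Around the score the package implements the full analysis a PRS study
needs:

* **QC** — per-sample and per-SNP call-rate filters (> 90%) and an exact
  conditional Hardy–Weinberg test in controls (keep p > 10⁻³);
* **association** — 1-df Pearson chi-square on the 2×2 allele table, Woolf
  CIs, and noncentral-chi-square power for replication planning;
* **risk groups** — samples binned at the quartiles (Q1/Q2/Q3) of the
  *control* score distribution; per-group odds ratios vs the bottom
  quartile from a logistic model with age and sex as covariates (fitted by
  the package's own IRLS engine, with explicit separation and
  rank-deficiency diagnostics), plus the continuous-PRS effect and its
  Nagelkerke pseudo-R²;
* **discrimination** — midrank (Mann–Whitney) AUC with DeLong variance,
  paired DeLong z-tests between models, and Youden-index operating points;
* **onset** — among cases: Kaplan–Meier curves and medians, k-group
  log-rank tests, Cox proportional-hazards fits (Efron ties, via
  lifelines) of onset age on PRS or family history, and a one-way ANOVA of
  onset across risk groups;
* **synthetic cohorts** — a seeded generator producing case–control data
  with the exact retrospective-sampling structure the analysis assumes
  (case genotype law ∝ control law × OR^g), so the whole pipeline is
  testable end to end without access to any real cohort.

## Worked example

Simulate a 1000-case / 1000-control cohort under the default study
conditions and run every stage:

```python
import psorprs as pp

config = pp.paper_like_config(n_cases=1000, n_controls=1000, seed=7)
cohort, panel = pp.simulate_cohort(config)
report = pp.run_full_analysis(cohort, panel, provenance={"seed": 7})
d = report.to_dict()
```

Formatting the relevant report entries prints:

```
control-quartile cutpoints: [1.908, 2.47, 3.611]
  group 0:   25 cases /  236 controls   OR = 1.00
  group 1:   51 cases /  236 controls   OR = 2.16
  group 2:  121 cases /  235 controls   OR = 5.11
  group 3:  739 cases /  236 controls   OR = 35.51
continuous PRS: beta = 1.010, p = 2.03e-101
Nagelkerke R2 = 0.553
AUC[snp] = 0.6848 (95% CI 0.6611-0.7084)
AUC[hla] = 0.7995 (95% CI 0.7818-0.8172)
AUC[snp-hla] = 0.8477 (95% CI 0.8305-0.8649)
AUC[snp-hla-drink] = 0.8548 (95% CI 0.8380-0.8717)
Cox HR per PRS unit (cases, sex-adjusted): 1.110 (p = 5.16e-07)
median onset gap, top vs bottom PRS group: 12.5 years
```

Read bottom-up: risk rises steeply across control-quartile groups (a
~35-fold odds ratio in the top quartile here), the HLA variant carries
most of the discriminatory ability, adding the 13 small-effect SNPs and
the drinking exposure each raises the AUC a little further, and
higher-PRS cases develop psoriasis earlier (HR > 1 per PRS unit, with a
double-digit gap in median onset between the extreme risk groups).

The same analysis runs from the shell on PLINK text genotypes plus
weights/phenotype TSVs:

```sh
psorprs simulate --out demo/ --seed 7           # or bring your own files
psorprs run --config run.yaml --out report.json
psorprs roc --ped demo/cohort.ped --map demo/cohort.map \
    --weights demo/weights.tsv --pheno demo/phenotypes.tsv \
    --models snp,hla,snp-hla
```

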