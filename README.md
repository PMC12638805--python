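# prsport

Evaluation of published polygenic risk scores (PRSs) in a target cohort:
variant harmonization with retention diagnostics, weighted-allele scoring,
cross-sectional and longitudinal predictive evaluation, and quantile-based
risk stratification.

## The problem

A polygenic risk score is a weighted sum of effect-allele dosages,
PRS_i = Σ_j w_j · d_ij, with weights w_j published by a discovery GWAS.
Applying a published score to a new cohort — here, a Thai-style cohort
genotyped on an array and imputed — raises three questions this package
answers quantitatively:

1. **How much of the score survives?** Each score's variants must be aligned
   to the target panel by genomic coordinates, rsIDs, and effect alleles,
   resolving allele swaps, strand flips and palindromic (A/T, C/G) ambiguity,
   after imputation-quality filtering (INFO ≥ 0.8, with 0.3 as the permissive
   alternative). *Simple SNP retention* is the fraction of score variants
   matched; *weighted retention* is the fraction of cumulative |w_j| they
   carry. Scores below 50% simple retention are gated out.
2. **Does the score predict at baseline?** Binary traits: logistic regression
   adjusted for age, sex and PC1–10, reporting OR per PRS standard deviation,
   AUC (DeLong CI), incremental Nagelkerke pseudo-R², and liability-scale R²
   via the transformation of observed-scale R² under an assumed population
   prevalence K (with t = Φ⁻¹(1−K), z = φ(t):
   R²_liab = c·R²_obs / (1 + c·θ·R²_obs)). Continuous traits: adjusted linear
   regression with incremental adjusted R². Benjamini–Hochberg FDR runs
   separately per trait; the best significant score per trait is selected by
   AUC or R².
3. **Does it stratify and persist?** Quartile odds ratios against the lowest
   quartile with a Cochran–Armitage trend test, decile trait gradients,
   Kaplan–Meier/Cox models of incident disease by quartile, and linear mixed
   models (random intercepts and slopes) of repeated trait measurements by
   quintile over six years of follow-up.

Because real genotype–phenotype cohorts of this kind are access-restricted,
the package ships a first-class synthetic module: genotypes in Hardy–Weinberg
proportions with configurable allele frequencies and INFO scores, disease
from a liability-threshold model with configurable prevalence and
liability-scale R², continuous traits with configurable PRS-attributable
variance, corruptible scoring files with an exact match-status truth ledger,
and six-year follow-up with incident events and repeated measurements. Every
stage of the pipeline is validated by recovering this ground truth.

## Worked example

The `analysis/` scripts run the whole sequence on a synthetic cohort
(n = 1000, 8 traits, one emulated published score each):

```bash
python analysis/01_simulate_cohort.py      # cohort + scoring files under results/cohort/
python analysis/02_qc_harmonize.py         # QC cascade + SNP retention
python analysis/03_evaluate_scores.py      # adjusted models + per-trait FDR
python analysis/04_stratify_risk.py        # quartile ORs / decile gradients
python analysis/05_followup_validation.py  # Cox by quartile, LMM trajectories
```

Step 02 prints, for example:

```
SNP retention per score (gate: simple retention >= 0.5):
   pgs_id trait  n_matched  n_variants  simple_retention  weighted_retention
PGSSYN000   t2d         87         120          0.725000            0.714348
PGSSYN005   ldl         87         120          0.725000            0.781034
```

87 of 120 score variants survived INFO filtering and allele harmonization
(72.5% simple retention); those 87 carry 71.4% of the score's total absolute
weight. Step 03 then reports the adjusted association models:

```
   pgs_id trait  effect    auc  nagelkerke_r2  incremental_r2      p   fdr_q
PGSSYN000   t2d  2.3000 0.7298         0.1114             NaN 0.0000  0.0000
PGSSYN005   ldl  8.9841    NaN            NaN          0.0884 0.0000  0.0000
```

i.e. one PRS standard deviation multiplies the odds of disease by 2.30, the
full adjusted model discriminates cases at AUC 0.73, and the LDL-C score
explains 8.8% of trait variance beyond covariates — close to the configured
9.8% generative value. Step 05 closes the loop longitudinally: hazard ratios
for incident disease rise across PRS quartiles (Q3: 3.75, Q4: 3.24 vs Q1)
and mixed-model lipid trajectories stay separated by quintile across six
years.

The same stages are scriptable via the `prsport` CLI (`prsport simulate`,
`prsport qc`, `prsport harmonize`, `prsport score`, `prsport run --config …`)
or the library API (`prsport.io_formats`, `harmonize`, `scoring`, `evaluate`,
`stratify`, `longitudinal`, `synthetic`, `pipeline`).

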