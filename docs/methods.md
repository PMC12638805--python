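# Methods

## Harmonization model

A scoring-file variant is matched to the genotype panel with the precedence
(1) chromosome + position with exact allele-pair agreement, (2) the same
after reverse-complementing the score alleles, (3) rsID with the same allele
logic. Coordinates take precedence over rsIDs because coordinate matches are
build-anchored; rsIDs serve only as a fallback for records whose coordinates
are absent or stale. The orientation flag records whether the effect allele
is the panel's alt or ref column; a ref-oriented ("swapped") match scores
2 − alt dosage, which leaves the standardized score identical to the
alt-oriented representation with negated weight (the swap-negate identity
the tests assert).

Palindromic variants (A/T or C/G pairs) cannot be strand-resolved from
allele labels. The default policy keeps them only when the panel
minor-allele frequency is below 0.40 — below that the effect-allele
frequency disambiguates strand with high probability — and otherwise books
them as `dropped_palindromic`; `drop` (always) and `keep` are available.
Records lacking an `other_allele` match on effect allele ∈ {ref, alt} and
never strand-flip (the flip would be unverifiable). Each panel column is
consumed at most once, candidates taken in position order, so the ledger is
deterministic.

Retention is reported two ways: *simple* (matched / total score variants)
and *weighted* (Σ|w| matched / Σ|w| total). Weighted retention answers
whether the lost variants were the influential ones; when all |w| are equal
the two coincide. Scores below 50% simple retention at INFO ≥ 0.8 are
reported but not evaluated, mirroring standard practice for imputed panels.

## Scoring

The raw score is the plain weighted sum of effect-allele dosages — no
allele-frequency centering, since the cohort z-transform absorbs location
and scale, and odds/hazard ratios are reported per cohort SD.
Standardization happens over the full analysis cohort after sample QC and
before any case/control subsetting. Missing dosages default to mean
imputation (2 × effect-allele frequency), which preserves the cohort mean;
`zero` and `drop_variant` are available. Dosage scoring is the default
(hard-call scoring is available by reading the VCF with
`dosage_field_policy="genotype_only"`), the natural choice for imputed data.

## Quality control

Filter order is fixed — variant call rate ≥ 0.90, sample call rate ≥ 0.97,
HWE exact p ≥ 1e−6, MAF ≥ 1%, INFO ≥ 0.8 — so removal counts are
reproducible. The HWE test is the two-sided exact test on hard-called
genotypes (dosages rounded to the nearest integer), computed by enumerating
the conditional distribution of heterozygote counts with a numerically
stable recurrence; the tests verify it against exact-arithmetic enumeration.
Multi-allelic VCF records are skipped rather than split (scoring files are
biallelic) and logged. For treated individuals, measured TC and LDL-C are
divided by 0.8 and 0.7 respectively to undo the expected pharmacologic
reduction before any lipid model is fitted.

## Evaluation models

Binary traits use maximum-likelihood logistic regression of status on the
standardized PRS plus age, sex and PC1–10, with Wald CIs and p-values
(matching common reporting; likelihood-ratio inference would differ only in
small samples). AUC is reported for the full adjusted model, with the
PRS-only AUC also emitted, because published AUCs of this kind are rarely
explicit about covariates; both are computed by the rank-based concordance
formula with a DeLong normal CI. Pseudo-R² is incremental Nagelkerke,
R²_CS = 1 − exp(−2(ℓ₁−ℓ₀)/n) scaled by 1 − exp(2ℓ₀/n), with ℓ₀ the
covariate-only likelihood; the full-model value is also emitted.

### Liability-scale R² and a calibration caveat

The liability transformation with prevalence K, case fraction P,
t = Φ⁻¹(1−K), z = φ(t), i = z/K,

c = K(1−K)/z² · K(1−K)/(P(1−P)),  θ = i·(P−K)/(K(1−K)) · (i·(P−K)/(K(1−K)) − t),
R²_liab = c·R²_obs / (1 + c·θ·R²_obs),

is derived for the *observed-scale* R² of a linear regression of 0/1 status
on the predictor. `liability_r2_from_status` implements exactly that route,
and on liability-threshold simulations it recovers the generative value to
within sampling error (the recovery tests hold it to ±0.03 at n = 5000 over
20 seeds). Feeding Nagelkerke's pseudo-R² through the same transformation —
as applied PRS reports sometimes do — systematically overstates liability R²
(roughly two-fold in our simulations at K ≈ 0.1), because Nagelkerke R²
exceeds the observed-scale R² for the same fit. The evaluation report
follows the published convention (transforming the incremental Nagelkerke
value) so its columns are comparable with the literature, while the
calibrated estimator is used wherever ground-truth recovery is asserted.
Under random cohort sampling P ≈ K and the θ correction is negligible; it
matters only for case-enriched designs. The correction is on by default and
switchable.

Continuous traits use OLS with the same covariates; the headline metric is
incremental adjusted R² (full minus covariate-only). BH-FDR is applied
separately per trait across scores (step-up q-values, significance at
q < 0.05); the best score per trait is the significant one with maximal AUC
(binary) or incremental R² (continuous), ties broken by smaller p then
lexicographic id.

Per-variant association scans fit one adjusted regression per dosage with
BH-FDR over the tested set and flags at p < 5×10⁻⁸ (genome-wide) and
p < 10⁻⁵ (suggestive). Relatedness uses the KING-robust estimator
φ̂ = (N_Aa,Aa − 2·N_AA,aa)/(N_Aa(i) + N_Aa(j)) on hard calls, with greedy
pruning above φ > 0.086 (second degree), dropping the highest-degree sample
first, ties lexicographic.

## Stratification and follow-up

Quantiles are rank-based equal-count bins (ties broken by sample id, larger
bins first), so assignment is deterministic and invariant under monotone
transforms of the score: quartiles for binary outcomes, deciles for
continuous gradients, quintiles for trajectory plots. Quartile ORs come from
one logistic model with Q1-reference indicators plus covariates (not
separate pairwise models); the unadjusted two-bin case reduces exactly to
the contingency cross-product. The Cochran–Armitage trend test uses integer
scores 1..g; its statistic is algebraically the score test of logistic
regression on those group scores, and the tests also check it against a
10⁵-draw permutation null.

Survival uses Cox partial likelihood with Efron tie handling (the modern
default) on quartile indicators, lowest quartile as reference, adjusted as
above; follow-up time starts at baseline, and samples with prevalent disease
at baseline are excluded from incident analyses. Non-events are
administratively censored at the follow-up horizon. Kaplan–Meier curves are
reported per quartile. Proportional-hazards diagnostics are out of scope.

Trajectories use a linear mixed model
y ~ quintile + time + quintile×time + covariates with per-sample random
intercepts and time slopes, fitted by REML. A singular random-effects
covariance triggers a documented fallback to random intercepts only.
Predicted quintile means are evaluated on the integer-year grid 0–6 with
covariates at cohort means; their CIs use the fixed-effect covariance only
(random-effect and residual variance describe individual scatter, not the
mean curve).

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
defaults set to the study conditions: 4879 samples; T2D prevalence 0.102
with liability-scale R² 0.1383 and CVD prevalence 0.057 with 0.2573; lipid
and glycemic traits at the variance fractions the best published scores
explained (TG 0.0347, TC 0.0776, HDL-C 0.0533, LDL-C 0.0982, FBS 0.0096,
HbA1c 0.0222) in plausible units (e.g. LDL-C 109 ± 31 mg/dL); sex fraction
0.23 male; modest age/sex effects on continuous traits (0.1/0.05 SD); an 8%
lipid-medication rate whose observed TC/LDL-C are multiplied by 0.8/0.7; and
six annual follow-up visits with exponential incident events whose
log-hazard is linear in the PRS (default log 1.6 per SD for T2D).

Variants are independent (LD blocks deliberately not emulated: none of the
evaluation statistics require LD, and independence gives closed-form
expectations for the tests). Hard calls are binomial(2, maf), so HWE holds
by construction; imputed dosages shrink the hard calls linearly toward
2·maf by √INFO, which makes the empirical dosage-variance ratio — the INFO
definition — equal the target exactly. This is an approximation to real
imputation noise: it is deterministic given the hard calls and preserves
genotype ordering, whereas real imputation error is stochastic.

Scoring files sample m panel variants with N(0, 0.1²) weights and apply
labelled corruptions — allele swap (effect listed as ref, weight negated:
an equivalent representation), strand complement, conversion to a
palindromic A/T pair, replacement with an off-panel variant — returning a
truth ledger of intended match statuses; harmonization must reproduce the
ledger exactly, which is the backbone of the acceptance suite.

What passing these tests does *not* show about real data: no LD, no
ancestry structure or allele-frequency mismatch between discovery and
target populations, no genotyping batch effects, no informative censoring
or visit irregularity, and traits are Gaussian with only mild covariate
confounding. The generator validates the *machinery*, not transferability
itself.

## Problem sizes and numerical choices

Recovery tests run at the sizes where their error bounds are meaningful:
prevalence at n = 10⁵ (±0.003), liability R² at n = 5000 averaged over 20
seeds (±0.03), continuous R² at n = 10⁴ over 10 seeds (±0.02), Cox log-HR
within 3 SE in ≥95% of 20 seeds; the analysis drivers use n = 1000 as a
desk-scale illustration. Quantile ties break on sample id; zero score
variance, single-class outcomes, empty quantiles, separation, and
monomorphic variants all raise explicit errors rather than returning
degenerate numbers. The pipeline hashes its config and checksums every
output so reruns are verifiably identical.
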