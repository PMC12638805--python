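"""Score the cohort and evaluate every PRS cross-sectionally.

Computes standardized PRS values from the harmonized variants, then fits the
adjusted models (age, sex, PC1–10): logistic for disease traits — OR per SD,
AUC, incremental Nagelkerke R² and its liability-scale transformation at the
assumed prevalences (10.2% T2D, 5.7% CVD) — and linear for continuous traits
with incremental adjusted R². TC/LDL-C of treated samples are divided by
0.8/0.7 first. Benjamini–Hochberg FDR runs separately per trait; the best
significant score per trait is recorded for the stratification and follow-up
steps. Writes results/evaluation.tsv and results/best_scores.tsv.

Run after 02_qc_harmonize.py.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from prsport.evaluate import (bh_fdr, fit_binary_model, fit_continuous_model,
                              select_best_prs)
from prsport.harmonize import match_variants, simple_retention, weighted_retention
from prsport.io_formats import (COVARIATE_COLUMNS, adjust_lipids_for_medication,
                                apply_variant_qc, parse_scoring_file,
                                read_genotypes, read_phenotypes)
from prsport.scoring import compute_prs

COHORT = Path("results/cohort")
OUT = Path("results")
PREVALENCE = {"t2d": 0.102, "cvd": 0.057}

g = read_genotypes(COHORT / "genotypes.vcf")
g, _ = apply_variant_qc(g, info_min=0.8)
pheno = read_phenotypes(COHORT / "phenotypes_baseline.csv")
base = pheno.baseline.loc[g.sample_ids].copy()
base["tc"], base["ldl"] = adjust_lipids_for_medication(
    base["tc"], base["ldl"], base["lipid_medication"])
covars = base[COVARIATE_COLUMNS].reset_index(drop=True)

results, vectors = [], {}
for path in sorted(COHORT.glob("PGSSYN*.txt")):
    score = parse_scoring_file(path)
    result = match_variants(score, g)
    vec = compute_prs(g, result, score)
    vectors[score.pgs_id] = vec
    trait = score.trait_label
    if f"status_{trait}" in base.columns:
        res = fit_binary_model(vec, base[f"status_{trait}"].to_numpy(), covars,
                               trait=trait, prevalence=PREVALENCE.get(trait))
    else:
        res = fit_continuous_model(vec, base[trait].to_numpy(), covars, trait=trait)
    res.simple_retention = simple_retention(result)
    res.weighted_retention = weighted_retention(result, score)
    results.append(res)

qs = bh_fdr([r.p for r in results], [r.trait for r in results])
for r, q in zip(results, qs):
    r.fdr_q = float(q)

table = pd.DataFrame([dataclasses.asdict(r) for r in results])
table.to_csv(OUT / "evaluation.tsv", sep="\t", index=False)
cols = ["pgs_id", "trait", "effect", "auc", "nagelkerke_r2", "liability_r2",
        "incremental_r2", "p", "fdr_q"]
print("cross-sectional evaluation (adjusted for age, sex, PC1-10):")
print(table[cols].round(4).to_string(index=False))

best_rows = []
for trait in sorted({r.trait for r in results}):
    pick = select_best_prs([r for r in results if r.trait == trait])
    best_rows.append(dict(trait=trait, best_pgs_id=pick or "none"))
best = pd.DataFrame(best_rows)
best.to_csv(OUT / "best_scores.tsv", sep="\t", index=False)
print("\nbest score per trait (max AUC / incremental R² among FDR<0.05):")
print(best.to_string(index=False))
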