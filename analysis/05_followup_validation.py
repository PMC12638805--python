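"""Six-year follow-up validation of the best scores.

Disease traits: Kaplan–Meier curves and Cox proportional-hazards models of
incident events by PRS quartile (prevalent cases excluded, lowest quartile
as reference, adjusted for age, sex, PC1–10). Continuous traits: linear
mixed models of repeated measurements across PRS quintiles with random
intercepts and slopes, yielding predicted trajectories at years 0–6.
Writes results/survival_<trait>.tsv and results/trajectories_<trait>.tsv.

Run after 04_stratify_risk.py.
"""

from pathlib import Path

import pandas as pd

from prsport.harmonize import match_variants
from prsport.io_formats import (COVARIATE_COLUMNS, apply_variant_qc,
                                parse_scoring_file, read_genotypes, read_phenotypes)
from prsport.longitudinal import cox_by_quantile, lmm_trajectories
from prsport.scoring import compute_prs
from prsport.stratify import assign_quantiles

COHORT = Path("results/cohort")
OUT = Path("results")

g = read_genotypes(COHORT / "genotypes.vcf")
g, _ = apply_variant_qc(g, info_min=0.8)
pheno = read_phenotypes(COHORT / "phenotypes_baseline.csv",
                        visits_path=COHORT / "phenotypes_visits.csv",
                        survival_path=COHORT / "phenotypes_survival.csv")
base = pheno.baseline.loc[g.sample_ids]
covars = base[COVARIATE_COLUMNS]
best = pd.read_csv(OUT / "best_scores.tsv", sep="\t").set_index("trait")["best_pgs_id"]

for trait, pgs_id in best.items():
    if pgs_id == "none":
        continue
    score = parse_scoring_file(COHORT / f"{pgs_id}.txt")
    vec = compute_prs(g, match_variants(score, g), score)

    if f"status_{trait}" in base.columns:
        surv = pheno.survival.query("trait == @trait")
        surv = surv[surv["sample_id"].isin(base.index)]
        if surv["event"].sum() == 0:
            print(f"{trait}: no incident events; skipped")
            continue
        labels = pd.Series(assign_quantiles(vec, 4), index=vec.sample_ids)
        idx = surv["sample_id"].to_numpy()
        res = cox_by_quantile(surv["time"].to_numpy(), surv["event"].to_numpy(),
                              labels.loc[idx].to_numpy(),
                              covars.loc[idx].reset_index(drop=True))
        res.hr_table.to_csv(OUT / f"survival_{trait}.tsv", sep="\t", index=False)
        print(f"\n{trait} ({pgs_id}): hazard ratios vs lowest quartile "
              f"({int(surv['event'].sum())} incident events)")
        print(res.hr_table.round(3).to_string(index=False))
    else:
        quint = pd.Series(assign_quantiles(vec, 5), index=vec.sample_ids)
        traj = lmm_trajectories(pheno.visits[pheno.visits["sample_id"].isin(base.index)],
                                quint, covars, outcome=trait,
                                years=(0, 2, 4, 6))
        traj.predictions.to_csv(OUT / f"trajectories_{trait}.tsv", sep="\t",
                                index=False)
        wide = traj.predictions.pivot(index="year", columns="quintile",
                                      values="predicted")
        print(f"\n{trait} ({pgs_id}): predicted means by PRS quintile "
              f"(random slopes: {traj.random_slope})")
        print(wide.round(1).to_string())
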