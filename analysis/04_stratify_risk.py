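"""Risk stratification by PRS quantile.

Disease traits: quartile odds ratios against the lowest quartile (adjusted
models) plus the Cochran–Armitage trend test on quartile case proportions.
Continuous traits: decile medians/IQRs with a Spearman gradient diagnostic.
Writes results/strata_<trait>.tsv.

Run after 03_evaluate_scores.py.
"""

from pathlib import Path

import pandas as pd

from prsport.harmonize import match_variants
from prsport.io_formats import (COVARIATE_COLUMNS, adjust_lipids_for_medication,
                                apply_variant_qc, parse_scoring_file,
                                read_genotypes, read_phenotypes)
from prsport.scoring import compute_prs
from prsport.stratify import (assign_quantiles, quantile_odds_ratios,
                              quantile_trait_summary)

COHORT = Path("results/cohort")
OUT = Path("results")

g = read_genotypes(COHORT / "genotypes.vcf")
g, _ = apply_variant_qc(g, info_min=0.8)
base = read_phenotypes(COHORT / "phenotypes_baseline.csv").baseline.loc[g.sample_ids].copy()
base["tc"], base["ldl"] = adjust_lipids_for_medication(
    base["tc"], base["ldl"], base["lipid_medication"])
covars = base[COVARIATE_COLUMNS].reset_index(drop=True)
best = pd.read_csv(OUT / "best_scores.tsv", sep="\t").set_index("trait")["best_pgs_id"]

for trait, pgs_id in best.items():
    if pgs_id == "none":
        print(f"{trait}: no significant score; skipped")
        continue
    score = parse_scoring_file(COHORT / f"{pgs_id}.txt")
    vec = compute_prs(g, match_variants(score, g), score)
    if f"status_{trait}" in base.columns:
        labels = assign_quantiles(vec, 4)
        strata = quantile_odds_ratios(labels, base[f"status_{trait}"].to_numpy(),
                                      covars)
        table = strata.table.copy()
        table["trend_p"] = strata.trend_p
        print(f"\n{trait} ({pgs_id}): quartile odds ratios vs Q1, "
              f"Cochran-Armitage trend p = {strata.trend_p:.2g}")
        print(table.round(3).to_string(index=False))
    else:
        labels = assign_quantiles(vec, 10)
        table = quantile_trait_summary(labels, base[trait].to_numpy())
        rho = table.attrs["spearman_rho"]
        table["spearman_rho"] = rho
        print(f"\n{trait} ({pgs_id}): decile medians, Spearman rho = {rho:.3f}")
        print(table.round(2).to_string(index=False))
    table.to_csv(OUT / f"strata_{trait}.tsv", sep="\t", index=False)
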