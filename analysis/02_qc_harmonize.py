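"""QC the genotype panel and harmonize every scoring file against it.

Applies the array-QC cascade (call rate, HWE, MAF, INFO ≥ 0.8), matches each
score's variants by coordinates/alleles with strand-flip and palindromic
resolution, and tabulates simple and |weight|-weighted SNP retention — the
two metrics used to judge how much of each published score survives in the
target panel. Writes results/retention.tsv and per-score match ledgers.

Run after 01_simulate_cohort.py.
"""

from pathlib import Path

import pandas as pd

from prsport.harmonize import match_variants, simple_retention, weighted_retention
from prsport.io_formats import apply_variant_qc, parse_scoring_file, read_genotypes

COHORT = Path("results/cohort")
OUT = Path("results")

g = read_genotypes(COHORT / "genotypes.vcf")
g, report = apply_variant_qc(g, info_min=0.8)
print("QC removals by criterion:")
print(report.to_frame().to_string(index=False))
print(f"panel after QC: {g.n_samples} samples x {g.n_variants} variants")
report.to_frame().to_csv(OUT / "qc_report.tsv", sep="\t", index=False)

rows = []
for path in sorted(COHORT.glob("PGSSYN*.txt")):
    score = parse_scoring_file(path)
    result = match_variants(score, g)
    result.to_frame(score).to_csv(OUT / f"harmonization_{score.pgs_id}.tsv",
                                  sep="\t", index=False)
    rows.append(dict(pgs_id=score.pgs_id, trait=score.trait_label,
                     n_variants=len(score), n_matched=result.n_matched,
                     simple_retention=simple_retention(result),
                     weighted_retention=weighted_retention(result, score),
                     **result.status_counts()))
table = pd.DataFrame(rows)
table.to_csv(OUT / "retention.tsv", sep="\t", index=False)
print("\nSNP retention per score (gate: simple retention >= 0.5):")
print(table[["pgs_id", "trait", "n_matched", "n_variants",
             "simple_retention", "weighted_retention"]].to_string(index=False))
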