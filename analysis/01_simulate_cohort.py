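"""Simulate the study-shaped cohort and emit its files.

Generates a genotype panel in Hardy–Weinberg proportions with imputation-style
dosages, one published-score emulation per trait (with realistic allele-swap,
strand-flip and off-panel corruptions), liability-model disease status for
T2D/CVD, lipid/glycemic traits at the variance fractions the best published
scores explain, and six years of follow-up. Everything is written under
results/cohort/ in the same formats real data would arrive in (VCF, scoring
files, phenotype CSVs).

Run from the repository root: python analysis/01_simulate_cohort.py [seed]
"""

import sys
from pathlib import Path

from prsport.synthetic import (CorruptionRates, SimulationConfig, generate_cohort,
                               generate_followup, generate_phenotypes,
                               generate_scoring_file, write_cohort_files)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
OUT = Path("results/cohort")

# a desk-scale cohort: study-shaped trait structure at n=1000 so the whole
# analysis sequence (including eight mixed-model fits) runs in a few minutes
cfg = SimulationConfig(n_samples=1000, n_variants=300, seed=SEED,
                       info_range=(0.75, 1.0))
cfg.followup.visit_times = (0.0, 3.0, 6.0)

g = generate_cohort(cfg)
print(f"cohort: {g.n_samples} samples x {g.n_variants} variants, "
      f"mean INFO {g.variant_meta['info_score'].mean():.2f}")

scores, smap = [], {}
corr = CorruptionRates(swap=0.10, strand_flip=0.08, palindromic=0.04, absent=0.10)
for i, trait in enumerate(list(cfg.binary_traits) + list(cfg.continuous_traits)):
    s, ledger = generate_scoring_file(g, m=120, seed=SEED + 10 + i,
                                      pgs_id=f"PGSSYN{i:03d}", trait_label=trait,
                                      corruption=corr)
    scores.append(s)
    smap[trait] = s
    frac = ledger["expected_status"].str.startswith("matched").mean()
    print(f"  {s.pgs_id} ({trait}): {len(s)} variants, "
          f"{frac:.0%} matchable by construction")

pheno = generate_phenotypes(g, smap, cfg)
pheno = generate_followup(pheno, cfg)
for trait in cfg.binary_traits:
    frac = pheno.baseline[f"status_{trait}"].mean()
    print(f"  {trait}: baseline prevalence {frac:.1%}")
print(f"  follow-up: {pheno.survival['event'].sum()} incident events, "
      f"{len(pheno.visits)} visit records")

paths = write_cohort_files(OUT, g, pheno, scores)
print(f"wrote {len(paths)} files under {OUT}/")
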