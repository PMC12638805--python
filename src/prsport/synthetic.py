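"""Synthetic cohorts with the statistical structure the pipeline assumes.

Genotypes are independent biallelic variants in Hardy–Weinberg proportions
with configurable allele frequencies and imputation quality; binary disease
arises from a liability-threshold model with configurable prevalence and
liability-scale R²; continuous traits carry a configurable PRS-attributable
variance fraction; follow-up adds exponential incident events with a
log-hazard linear in the PRS and repeated measurements with per-sample random
intercepts and slopes. Scoring files are derived from the panel with labelled
corruptions (allele swap, strand flip, palindromic conversion, off-panel
replacement) so harmonization can be validated against an exact truth ledger.

Every generator is deterministic given its seed, and emits the same file
formats the readers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import COMPLEMENT, match_variants
from .io_formats import (GenotypeMatrix, PhenotypeTable, ScoreVariant, ScoringFile,
                         write_scoring_file, write_vcf)
from .scoring import compute_prs

_BASES = np.array(list("ACGT"))


@dataclass
class BinaryTraitSpec:
    """Liability-threshold disease: prevalence K and liability-scale R²."""

    prevalence: float
    liability_r2: float
    log_hr_per_sd: float = float(np.log(1.6))
    baseline_hazard: float = 0.01  # events per person-year at PRS mean


@dataclass
class ContinuousTraitSpec:
    """Continuous trait with a PRS-attributable variance fraction h2_prs.

    ``mean``/``sd`` give the reporting units (e.g. mg/dL); covariate betas are
    on the standardized scale. ``slope_per_year`` drifts the trait during
    follow-up; ``quintile_time_slope`` adds an extra per-quintile-step drift.
    """

    h2_prs: float
    mean: float = 0.0
    sd: float = 1.0
    age_beta: float = 0.1
    sex_beta: float = 0.05
    slope_per_year: float = 0.0
    quintile_time_slope: float = 0.0


@dataclass
class CorruptionRates:
    """Fractions of score variants given each labelled corruption."""

    swap: float = 0.0
    strand_flip: float = 0.0
    palindromic: float = 0.0
    absent: float = 0.0

    def __post_init__(self):
        total = self.swap + self.strand_flip + self.palindromic + self.absent
        if total > 1.0 + 1e-12:
            raise ValueError(f"corruption rates sum to {total} > 1")


@dataclass
class FollowupConfig:
    years: float = 6.0
    visit_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    random_intercept_sd: float = 0.3  # in trait SD units
    random_slope_sd: float = 0.05
    residual_sd: float = 0.3


@dataclass
class SimulationConfig:
    """Study-shaped defaults: a 4879-sample cohort, T2D/CVD under the
    liability model at the assumed prevalences, and lipid/glycemic traits at
    the variance fractions the best-performing scores explained."""

    n_samples: int = 4879
    n_variants: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    info_range: tuple[float, float] = (0.6, 1.0)
    seed: int = 0
    binary_traits: dict[str, BinaryTraitSpec] = field(default_factory=lambda: {
        "t2d": BinaryTraitSpec(prevalence=0.102, liability_r2=0.1383),
        "cvd": BinaryTraitSpec(prevalence=0.057, liability_r2=0.2573,
                               log_hr_per_sd=0.0, baseline_hazard=0.002),
    })
    continuous_traits: dict[str, ContinuousTraitSpec] = field(default_factory=lambda: {
        "tg": ContinuousTraitSpec(h2_prs=0.0347, mean=95.0, sd=55.0),
        "tc": ContinuousTraitSpec(h2_prs=0.0776, mean=190.0, sd=33.0),
        "hdl": ContinuousTraitSpec(h2_prs=0.0533, mean=60.0, sd=16.0),
        "ldl": ContinuousTraitSpec(h2_prs=0.0982, mean=109.0, sd=31.0),
        "fbs": ContinuousTraitSpec(h2_prs=0.0096, mean=88.0, sd=12.0),
        "hba1c": ContinuousTraitSpec(h2_prs=0.0222, mean=5.5, sd=0.5),
    })
    lipid_medication_rate: float = 0.08
    followup: FollowupConfig = field(default_factory=FollowupConfig)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def generate_cohort(cfg: SimulationConfig) -> GenotypeMatrix:
    """Draw a genotype panel in Hardy–Weinberg proportions.

    Hard calls are binomial(2, maf) per variant; imputed dosages are the hard
    calls shrunk linearly toward 2·maf by √INFO, which makes the empirical
    dosage-variance ratio (the INFO definition) match the target exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.n_variants
    maf = rng.uniform(*cfg.maf_range, size=m)
    info = rng.uniform(*cfg.info_range, size=m)
    hard = rng.binomial(2, maf[None, :], size=(n, m)).astype(float)
    dosage = 2.0 * maf[None, :] + np.sqrt(info)[None, :] * (hard - 2.0 * maf[None, :])
    dosage = np.clip(dosage, 0.0, 2.0)

    ref = _BASES[rng.integers(0, 4, size=m)]
    # alt drawn from the remaining bases, avoiding a palindromic panel pair
    alt = np.array([rng.choice([b for b in "ACGT" if b != r and b != COMPLEMENT[r]])
                    for r in ref])
    monomorphic = maf == 0.0
    meta = pd.DataFrame({
        "chromosome": np.repeat("1", m),
        "position": np.arange(1, m + 1) * 1000,
        "rsid": [f"rs{j + 1}" for j in range(m)],
        "ref_allele": ref,
        "alt_allele": alt,
        "info_score": info,
        "monomorphic": monomorphic,
    })
    g = GenotypeMatrix(
        sample_ids=[f"S{i:06d}" for i in range(n)],
        variant_meta=meta,
        dosage=dosage,
        missing=np.zeros((n, m), dtype=bool),
    )
    g.recompute_frequencies()
    return g


# ---------------------------------------------------------------------------
# Scoring files
# ---------------------------------------------------------------------------

def generate_scoring_file(g: GenotypeMatrix, m: int, weight_sd: float = 0.1,
                          corruption: CorruptionRates = CorruptionRates(),
                          seed: int = 0, pgs_id: str = "PGSSYN001",
                          trait_label: str = "") -> tuple[ScoringFile, pd.DataFrame]:
    """Sample a scoring file from the panel with labelled corruptions.

    Returns the file plus a truth ledger (one row per score variant) stating
    the panel column it came from and the match status harmonization should
    assign: corrupted-to-palindromic variants expect ``dropped_palindromic``
    under a drop policy, off-panel replacements expect ``unmatched``, swaps
    and strand flips stay matchable with known orientation.
    """
    if m > g.n_variants:
        raise ValueError(f"m={m} exceeds panel size {g.n_variants}")
    rng = np.random.default_rng(seed)
    cols = np.sort(rng.choice(g.n_variants, size=m, replace=False))
    weights = rng.normal(0.0, weight_sd, size=m)

    n_swap = int(round(corruption.swap * m))
    n_flip = int(round(corruption.strand_flip * m))
    n_pal = int(round(corruption.palindromic * m))
    n_abs = int(round(corruption.absent * m))
    kinds = np.array(["clean"] * m, dtype=object)
    shuffled = rng.permutation(m)
    start = 0
    for kind, count in (("swap", n_swap), ("strand_flip", n_flip),
                        ("palindromic", n_pal), ("absent", n_abs)):
        kinds[shuffled[start:start + count]] = kind
        start += count

    variants = []
    ledger_rows = []
    max_pos = int(g.variant_meta["position"].max())
    for i, (col, w, kind) in enumerate(zip(cols, weights, kinds)):
        row = g.variant_meta.iloc[int(col)]
        chrom, pos = str(row["chromosome"]), int(row["position"])
        rsid = str(row["rsid"])
        ref, alt = row["ref_allele"], row["alt_allele"]
        effect, other = alt, ref
        expected = "matched_direct"
        if kind == "swap":
            # equivalent representation: effect allele listed as ref, weight negated
            effect, other = ref, alt
            w = -w
            expected = "matched_swapped"
        elif kind == "strand_flip":
            effect, other = COMPLEMENT[alt], COMPLEMENT[ref]
            expected = "matched_strand_flipped"
        elif kind == "palindromic":
            effect, other = "A", "T"
            expected = "dropped_palindromic"
        elif kind == "absent":
            pos = max_pos + 1000 * (i + 1)
            rsid = f"rsabsent{i}"
            expected = "unmatched"
        variants.append(ScoreVariant(chromosome=chrom, position=pos, rsid=rsid,
                                     effect_allele=effect, other_allele=other, weight=w))
        ledger_rows.append(dict(index=i, panel_column=int(col) if kind != "absent" else -1,
                                corruption=kind, expected_status=expected, weight=w))
    score = ScoringFile(pgs_id=pgs_id, trait_label=trait_label, genome_build="GRCh38",
                        variants=variants)
    return score, pd.DataFrame(ledger_rows)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _true_z(g: GenotypeMatrix, score: ScoringFile) -> np.ndarray:
    from .harmonize import PalindromicPolicy
    result = match_variants(score, g, palindromic_policy=PalindromicPolicy.keep())
    return compute_prs(g, result, score).z


def generate_phenotypes(g: GenotypeMatrix, scores: ScoringFile | Mapping[str, ScoringFile],
                        cfg: SimulationConfig, seed: Optional[int] = None) -> PhenotypeTable:
    """Generate baseline outcomes and covariates driven by the true PRS.

    Binary traits: liability L = √R²·z + √(1−R²)·ε with case iff
    L > Φ⁻¹(1−K). Continuous traits: standardized y = √h²·z + covariate terms
    + noise scaled to unit variance, then rescaled to trait units. Observed
    TC/LDL-C are multiplied by (0.8, 0.7) for samples flagged as on
    lipid-lowering medication (the adjusted analysis divides them back). The
    standardized PRS per trait is stored as column ``prs_z_<trait>``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = g.n_samples
    trait_names = list(cfg.binary_traits) + list(cfg.continuous_traits)
    if isinstance(scores, ScoringFile):
        z_by_trait = {t: _true_z(g, scores) for t in trait_names}
    else:
        z_by_trait = {t: _true_z(g, s) for t, s in scores.items()}

    base = pd.DataFrame(index=pd.Index(g.sample_ids, name="sample_id"))
    base["age"] = np.clip(rng.normal(37.0, 9.0, size=n), 20, 80)
    base["sex"] = rng.binomial(1, 0.23, size=n)  # 1 = male, cohort-typical fraction
    for k in range(1, 11):
        base[f"pc{k}"] = rng.normal(0.0, 1.0, size=n)
    age_std = (base["age"] - base["age"].mean()) / base["age"].std()

    for name, spec in cfg.binary_traits.items():
        if name not in z_by_trait:
            continue
        z = z_by_trait[name]
        r2 = spec.liability_r2
        liability = np.sqrt(r2) * z + np.sqrt(1.0 - r2) * rng.normal(size=n)
        base[f"status_{name}"] = (liability > stats.norm.ppf(1.0 - spec.prevalence)).astype(int)
        base[f"prs_z_{name}"] = z

    base["lipid_medication"] = rng.binomial(1, cfg.lipid_medication_rate, size=n)
    for name, spec in cfg.continuous_traits.items():
        if name not in z_by_trait:
            continue
        z = z_by_trait[name]
        h2 = spec.h2_prs
        var_cov = spec.age_beta ** 2 + spec.sex_beta ** 2
        resid = 1.0 - h2 - var_cov
        if resid < 0:
            raise ValueError(f"{name}: h2_prs + covariate variance exceeds 1")
        y_std = (np.sqrt(h2) * z + spec.age_beta * age_std
                 + spec.sex_beta * (base["sex"] - base["sex"].mean())
                 + np.sqrt(resid) * rng.normal(size=n))
        y = np.maximum(spec.mean + spec.sd * y_std, 0.0)  # trait units are non-negative
        if name in ("tc", "ldl"):  # medication masks the underlying value
            factor = 0.8 if name == "tc" else 0.7
            y = np.where(base["lipid_medication"] == 1, y * factor, y)
        base[name] = y
        base[f"prs_z_{name}"] = z

    visits = base.reset_index()[["sample_id"] + list(cfg.continuous_traits)].copy()
    visits["visit_time"] = 0.0
    return PhenotypeTable(baseline=base, visits=visits)


def generate_followup(pheno: PhenotypeTable, cfg: SimulationConfig,
                      seed: Optional[int] = None) -> PhenotypeTable:
    """Add incident events and repeated measurements to a baseline table.

    Event times for baseline non-cases are exponential with rate
    λ₀·exp(β·z), administratively censored at the follow-up horizon.
    Repeated trait values follow per-sample random intercepts and time
    slopes plus any configured quintile×time drift.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    base = pheno.baseline
    n = len(base)
    fu = cfg.followup

    surv_rows = []
    for name, spec in cfg.binary_traits.items():
        col = f"status_{name}"
        if col not in base.columns:
            continue
        z = base[f"prs_z_{name}"].to_numpy()
        at_risk = base[col].to_numpy() == 0  # prevalent cases carry no incident row
        rate = spec.baseline_hazard * np.exp(spec.log_hr_per_sd * z)
        times = np.where(rate > 0, rng.exponential(1.0 / np.maximum(rate, 1e-300)), np.inf)
        event = (times <= fu.years).astype(int)
        obs_time = np.minimum(times, fu.years)
        for sid, t, e, risk in zip(base.index, obs_time, event, at_risk):
            if risk:
                surv_rows.append(dict(sample_id=sid, trait=name, time=float(t),
                                      event=int(e)))

    visit_rows = {"sample_id": [], "visit_time": []}
    trait_names = [t for t in cfg.continuous_traits if t in base.columns]
    for t in trait_names:
        visit_rows[t] = []
    for name in trait_names:
        spec = cfg.continuous_traits[name]
        z = base[f"prs_z_{name}"].to_numpy()
        quint = np.clip(np.searchsorted(np.quantile(z, [0.2, 0.4, 0.6, 0.8]), z,
                                        side="right") + 1, 1, 5)
        b0 = rng.normal(0.0, fu.random_intercept_sd * spec.sd, size=n)
        b1 = rng.normal(0.0, fu.random_slope_sd * spec.sd, size=n)
        baseline_vals = base[name].to_numpy()
        for t in fu.visit_times:
            drift = (spec.slope_per_year + spec.quintile_time_slope * (quint - 3)) * t
            noise = rng.normal(0.0, fu.residual_sd * spec.sd, size=n)
            vals = baseline_vals + b0 * (t > 0) + b1 * t + drift * spec.sd + noise * (t > 0)
            if name == trait_names[0]:
                visit_rows["sample_id"].extend(base.index)
                visit_rows["visit_time"].extend([float(t)] * n)
            visit_rows[name].extend(vals)
    visits = pd.DataFrame(visit_rows)
    return PhenotypeTable(baseline=base.copy(), visits=visits,
                          survival=pd.DataFrame(surv_rows,
                                                columns=["sample_id", "trait", "time", "event"]))


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_cohort_files(outdir: str | Path, g: GenotypeMatrix, pheno: PhenotypeTable,
                       scores: Sequence[ScoringFile] = ()) -> dict[str, Path]:
    """Write the cohort in the formats the pipeline readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": outdir / "genotypes.vcf",
             "baseline": outdir / "phenotypes_baseline.csv",
             "visits": outdir / "phenotypes_visits.csv",
             "survival": outdir / "phenotypes_survival.csv"}
    write_vcf(g, paths["vcf"])
    pheno.baseline.reset_index().to_csv(paths["baseline"], index=False)
    pheno.visits.to_csv(paths["visits"], index=False)
    pheno.survival.to_csv(paths["survival"], index=False)
    for s in scores:
        p = outdir / f"{s.pgs_id}.txt"
        write_scoring_file(s, p)
        paths[s.pgs_id] = p
    return paths
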