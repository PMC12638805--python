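"""Readers, writers, and quality control for the pipeline's file formats.

Covers PGS-Catalog-style scoring files, VCF genotype panels with per-sample
dosages and per-variant imputation quality (INFO), delimited phenotype tables
with longitudinal follow-up, the cohort/variant QC filters, and the lipid
medication adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .hwe import hwe_exact_test

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class EmptyScoreError(ValueError):
    """A scoring file yielded zero usable variant records."""


class EmptyPanelError(ValueError):
    """All variants (or samples) were removed by quality control."""


def normalize_chromosome(chrom: str) -> str:
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


# ---------------------------------------------------------------------------
# Scoring files
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreVariant:
    """One weighted variant of a published polygenic score."""

    chromosome: Optional[str]
    position: Optional[int]
    effect_allele: str
    weight: float
    other_allele: Optional[str] = None
    rsid: Optional[str] = None

    def __post_init__(self):
        if self.position is not None and self.position <= 0:
            raise ValueError(f"position must be positive, got {self.position}")
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele is not None:
            if self.other_allele not in VALID_ALLELES:
                raise ValueError(f"invalid other allele {self.other_allele!r}")
            if self.other_allele == self.effect_allele:
                raise ValueError("effect and other allele identical")
        if not np.isfinite(self.weight):
            raise ValueError("weight must be finite")

    @property
    def has_coordinates(self) -> bool:
        return self.chromosome is not None and self.position is not None


@dataclass
class ScoringFile:
    """A published PRS: ordered variant records plus provenance metadata."""

    pgs_id: str
    variants: list[ScoreVariant]
    trait_label: str = ""
    genome_build: str = ""

    def __post_init__(self):
        if not self.pgs_id:
            raise ValueError("pgs_id must be non-empty")
        if not self.variants:
            raise EmptyScoreError(f"{self.pgs_id}: scoring file has no variants")
        seen = set()
        for v in self.variants:
            if v.has_coordinates and v.other_allele is not None:
                key = (v.chromosome, v.position, frozenset((v.effect_allele, v.other_allele)))
                if key in seen:
                    raise ValueError(f"{self.pgs_id}: duplicate variant {key}")
                seen.add(key)

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.weight for v in self.variants])


_SCORE_COLUMNS = {
    "rsid": ("rsID", "rsid"),
    "chromosome": ("chr_name", "chromosome", "chr"),
    "position": ("chr_position", "position", "pos"),
    "effect_allele": ("effect_allele",),
    "other_allele": ("other_allele", "reference_allele"),
    "weight": ("effect_weight",),
}


def parse_scoring_file(path: str | Path) -> ScoringFile:
    """Parse a PGS-Catalog-style tab-separated scoring file.

    Lines starting with ``#`` are ``key=value`` metadata; the first
    non-comment line is the column header. Records lacking both genomic
    coordinates and an rsID are dropped with a logged count.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t", dtype=str)

    cols: dict[str, Optional[str]] = {}
    for role, names in _SCORE_COLUMNS.items():
        cols[role] = next((n for n in names if n in table.columns), None)
    if cols["effect_allele"] is None or cols["weight"] is None:
        raise FormatError(f"{path}: missing effect_allele or effect_weight column")
    has_coords = cols["chromosome"] is not None and cols["position"] is not None
    if not has_coords and cols["rsid"] is None:
        raise FormatError(f"{path}: neither coordinate columns nor rsID column present")

    variants: list[ScoreVariant] = []
    n_dropped = 0
    for _, row in table.iterrows():
        chrom = pos_ = rsid = other = None
        if has_coords:
            c, p = row[cols["chromosome"]], row[cols["position"]]
            if pd.notna(c) and pd.notna(p):
                chrom = normalize_chromosome(c)
                pos_ = int(float(p))
        if cols["rsid"] is not None and pd.notna(row[cols["rsid"]]):
            rsid = str(row[cols["rsid"]]).strip() or None
        if pos_ is None and rsid is None:
            n_dropped += 1
            continue
        if cols["other_allele"] is not None and pd.notna(row[cols["other_allele"]]):
            other = str(row[cols["other_allele"]]).strip().upper()
        variants.append(ScoreVariant(
            chromosome=chrom, position=pos_, rsid=rsid,
            effect_allele=str(row[cols["effect_allele"]]).strip().upper(),
            other_allele=other,
            weight=float(row[cols["weight"]]),
        ))
    if n_dropped:
        logger.info("%s: dropped %d records lacking coordinates and rsID", path, n_dropped)
    if not variants:
        raise EmptyScoreError(f"{path}: no parseable variant records")
    return ScoringFile(
        pgs_id=meta.get("pgs_id", path.stem),
        trait_label=meta.get("trait_reported", ""),
        genome_build=meta.get("genome_build", ""),
        variants=variants,
    )


def write_scoring_file(score: ScoringFile, path: str | Path) -> None:
    """Write a ScoringFile in the PGS-Catalog text layout (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write(f"#pgs_id={score.pgs_id}\n")
        fh.write(f"#trait_reported={score.trait_label}\n")
        fh.write(f"#genome_build={score.genome_build}\n")
        fh.write("rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n")
        for v in score.variants:
            fh.write("\t".join([
                v.rsid or "",
                v.chromosome or "",
                "" if v.position is None else str(v.position),
                v.effect_allele,
                v.other_allele or "",
                repr(float(v.weight)),
            ]) + "\n")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele dosage panel with per-variant metadata.

    ``dosage`` counts alt alleles in [0, 2]; entries where ``missing`` is True
    carry no information (the dosage value there is arbitrary). ``variant_meta``
    has columns chromosome, position, rsid, ref_allele, alt_allele, info_score,
    alt_frequency, call_rate.
    """

    sample_ids: list[str]
    variant_meta: pd.DataFrame
    dosage: np.ndarray
    missing: np.ndarray

    def __post_init__(self):
        n, m = self.dosage.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if len(self.variant_meta) != m:
            raise ValueError("variant_meta length mismatch")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if self.missing.shape != self.dosage.shape:
            raise ValueError("missing mask shape mismatch")
        ok = self.dosage[~self.missing]
        if ok.size and (ok.min() < -1e-9 or ok.max() > 2 + 1e-9):
            raise ValueError("dosages outside [0, 2]")
        self.variant_meta = self.variant_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def recompute_frequencies(self) -> None:
        """Refresh alt_frequency and call_rate from the dosage matrix."""
        valid = ~self.missing
        n_valid = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            af = np.where(n_valid > 0,
                          np.where(valid, self.dosage, 0.0).sum(axis=0) / (2.0 * np.maximum(n_valid, 1)),
                          np.nan)
        self.variant_meta["alt_frequency"] = af
        self.variant_meta["call_rate"] = n_valid / self.n_samples

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_meta=self.variant_meta.loc[np.asarray(keep)].reset_index(drop=True),
            dosage=self.dosage[:, keep],
            missing=self.missing[:, keep],
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            sample_ids=[s for s, k in zip(self.sample_ids, keep) if k],
            variant_meta=self.variant_meta.copy(),
            dosage=self.dosage[keep],
            missing=self.missing[keep],
        )

    def hard_calls(self) -> np.ndarray:
        """Dosages rounded to {0,1,2}; missing entries are -1."""
        calls = np.rint(np.clip(self.dosage, 0, 2)).astype(np.int8)
        calls[self.missing] = -1
        return calls


def read_genotypes(path: str | Path, dosage_field_policy: str = "prefer_dosage",
                   info_key: str = "INFO", info_fallbacks: Sequence[str] = ("R2", "DR2"),
                   ) -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix.

    Dosages come from the per-sample DS field when present and
    ``dosage_field_policy`` is ``prefer_dosage``; otherwise the alt-allele
    count is taken from hard genotypes. Multi-allelic records are skipped with
    a logged count; per-variant imputation quality is read from the INFO-field
    key ``info_key`` (with fallbacks), defaulting to 1.0 when absent.
    """
    from cyvcf2 import VCF

    if dosage_field_policy not in ("prefer_dosage", "genotype_only"):
        raise ValueError(f"unknown policy {dosage_field_policy!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no samples")

    rows = []
    dosages = []
    missings = []
    n_multi = n_bad = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        try:
            info_score = None
            for key in (info_key, *info_fallbacks):
                val = rec.INFO.get(key)
                if val is not None:
                    info_score = float(val)
                    break
            if info_score is None:
                info_score = 1.0
            ds = None
            if dosage_field_policy == "prefer_dosage":
                try:
                    ds = rec.format("DS")
                except KeyError:
                    ds = None
            if ds is not None:
                d = np.asarray(ds, dtype=float).reshape(-1)
                miss = ~np.isfinite(d)
            else:
                gts = np.asarray(rec.genotype.array())[:, :2]
                miss = (gts < 0).any(axis=1)
                d = np.clip(gts, 0, None).sum(axis=1).astype(float)
            d = np.where(miss, 0.0, np.clip(d, 0.0, 2.0))
        except Exception as exc:  # malformed record: warn and skip
            n_bad += 1
            logger.warning("%s: skipping malformed record at %s:%s (%s)",
                           path, rec.CHROM, rec.POS, exc)
            continue
        rows.append(dict(chromosome=normalize_chromosome(rec.CHROM), position=rec.POS,
                         rsid=rec.ID, ref_allele=rec.REF, alt_allele=rec.ALT[0],
                         info_score=info_score))
        dosages.append(d)
        missings.append(miss)
    if n_multi:
        logger.info("%s: skipped %d multi-allelic records", path, n_multi)
    if not rows:
        raise FormatError(f"{path}: no usable biallelic records")

    g = GenotypeMatrix(
        sample_ids=samples,
        variant_meta=pd.DataFrame(rows),
        dosage=np.column_stack(dosages),
        missing=np.column_stack(missings),
    )
    g.recompute_frequencies()
    return g


def write_vcf(g: GenotypeMatrix, path: str | Path, info_key: str = "INFO") -> None:
    """Write the panel as an uncompressed VCF 4.2 with GT and DS fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.variant_meta["chromosome"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(f'##INFO=<ID={info_key},Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        calls = g.hard_calls()
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for j in range(g.n_variants):
            row = g.variant_meta.iloc[j]
            fields = [str(row["chromosome"]), str(int(row["position"])),
                      str(row["rsid"]) if pd.notna(row["rsid"]) else ".",
                      row["ref_allele"], row["alt_allele"], ".", "PASS",
                      f"{info_key}={row['info_score']:.4f}", "GT:DS"]
            for i in range(g.n_samples):
                if g.missing[i, j]:
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_strings[int(calls[i, j])]}:{g.dosage[i, j]:.4g}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Removal counts per criterion, in application order."""

    n_variants_in: int
    n_samples_in: int
    removed_variant_call: int = 0
    removed_sample_call: int = 0
    removed_hwe: int = 0
    removed_maf: int = 0
    removed_info: int = 0

    @property
    def n_variants_out(self) -> int:
        return (self.n_variants_in - self.removed_variant_call
                - self.removed_hwe - self.removed_maf - self.removed_info)

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.removed_sample_call

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            ("variant_call_rate", self.removed_variant_call),
            ("sample_call_rate", self.removed_sample_call),
            ("hwe", self.removed_hwe),
            ("maf", self.removed_maf),
            ("info", self.removed_info),
        ], columns=["criterion", "n_removed"])


def apply_variant_qc(g: GenotypeMatrix, variant_call_min: float = 0.90,
                     sample_call_min: float = 0.97, hwe_p_min: float = 1e-6,
                     maf_min: float = 0.01, info_min: float = 0.8,
                     ) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the standard array-QC filter cascade.

    Order is fixed (variant call rate, sample call rate, HWE exact test on
    hard calls, MAF, INFO) so the report counts are reproducible. Frequencies
    and call rates are recomputed after the sample filter.
    """
    if g.n_variants == 0 or g.n_samples == 0:
        raise EmptyPanelError("empty genotype matrix")
    report = QCReport(n_variants_in=g.n_variants, n_samples_in=g.n_samples)

    g = GenotypeMatrix(list(g.sample_ids), g.variant_meta.copy(), g.dosage.copy(),
                       g.missing.copy())
    g.recompute_frequencies()
    keep = g.variant_meta["call_rate"].to_numpy() >= variant_call_min
    report.removed_variant_call = int((~keep).sum())
    g = g.subset_variants(keep)
    if g.n_variants == 0:
        raise EmptyPanelError("all variants removed by call-rate filter")

    sample_call = (~g.missing).mean(axis=1)
    keep_s = sample_call >= sample_call_min
    report.removed_sample_call = int((~keep_s).sum())
    g = g.subset_samples(keep_s)
    if g.n_samples == 0:
        raise EmptyPanelError("all samples removed by call-rate filter")
    g.recompute_frequencies()

    calls = g.hard_calls()
    hwe_p = np.empty(g.n_variants)
    for j in range(g.n_variants):
        c = calls[:, j]
        c = c[c >= 0]
        hwe_p[j] = hwe_exact_test(int((c == 0).sum()), int((c == 1).sum()),
                                  int((c == 2).sum())) if c.size else 1.0
    keep = hwe_p >= hwe_p_min
    report.removed_hwe = int((~keep).sum())
    g = g.subset_variants(keep)

    af = g.variant_meta["alt_frequency"].to_numpy()
    maf = np.minimum(af, 1.0 - af)
    keep = maf >= maf_min
    report.removed_maf = int((~keep).sum())
    g = g.subset_variants(keep)

    keep = g.variant_meta["info_score"].to_numpy() >= info_min
    report.removed_info = int((~keep).sum())
    g = g.subset_variants(keep)
    if g.n_variants == 0:
        raise EmptyPanelError("all variants removed by QC")
    return g, report


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def adjust_lipids_for_medication(tc, ldl, on_medication):
    """Undo the expected pharmacologic reduction in treated individuals.

    Measured total cholesterol is divided by 0.8 and LDL-C by 0.7 for samples
    flagged as on lipid-lowering medication; untreated values pass through.
    Accepts scalars or arrays.
    """
    tc = np.asarray(tc, dtype=float)
    ldl = np.asarray(ldl, dtype=float)
    on = np.asarray(on_medication, dtype=bool)
    if (tc < 0).any() or (ldl < 0).any():
        raise ValueError("lipid values must be non-negative")
    tc_adj = np.where(on, tc / 0.8, tc)
    ldl_adj = np.where(on, ldl / 0.7, ldl)
    if tc_adj.ndim == 0:
        return float(tc_adj), float(ldl_adj)
    return tc_adj, ldl_adj


COVARIATE_COLUMNS = ["age", "sex"] + [f"pc{i}" for i in range(1, 11)]


@dataclass
class PhenotypeTable:
    """Per-sample outcomes, covariates, and longitudinal follow-up.

    ``baseline`` is indexed by sample id and holds disease status columns
    (``status_<trait>``), continuous trait values, age, sex (0/1), pc1..pc10,
    and medication flags. ``visits`` is a long table (sample_id, visit_time,
    trait columns) including the baseline visit at time 0. ``survival`` holds
    one row per sample per disease trait: (sample_id, trait, time, event).
    """

    baseline: pd.DataFrame
    visits: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["sample_id", "visit_time"]))
    survival: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["sample_id", "trait", "time", "event"]))

    def __post_init__(self):
        if self.baseline.index.has_duplicates:
            raise ValueError("duplicate sample ids in baseline table")
        if len(self.visits):
            if self.visits.duplicated(["sample_id", "visit_time"]).any():
                raise ValueError("duplicate (sample, visit) rows")
            if (self.visits["visit_time"] < 0).any():
                raise ValueError("negative visit time")
            self.visits = self.visits.sort_values(["sample_id", "visit_time"]).reset_index(drop=True)
        if len(self.survival):
            if (self.survival["time"] < 0).any():
                raise ValueError("negative follow-up time")
            if not self.survival["event"].isin([0, 1]).all():
                raise ValueError("event indicator must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.baseline.index)

    def covariates(self) -> pd.DataFrame:
        return self.baseline[COVARIATE_COLUMNS].astype(float)


def read_phenotypes(baseline_path: str | Path, schema: Optional[Mapping[str, str]] = None,
                    visits_path: Optional[str | Path] = None,
                    survival_path: Optional[str | Path] = None,
                    sex_codes: Optional[Mapping[str, int]] = None) -> PhenotypeTable:
    """Load a baseline covariate/outcome CSV plus optional long follow-up tables.

    ``schema`` maps file column names to canonical roles (sample_id, age, sex,
    pc1..pc10, status_<trait>, trait names, lipid_medication); identity mapping
    by default. ``sex_codes`` optionally maps string sex labels to {0,1}.
    """
    baseline = pd.read_csv(baseline_path)
    if schema:
        baseline = baseline.rename(columns=dict(schema))
    required = ["sample_id", "age", "sex"] + [f"pc{i}" for i in range(1, 11)]
    missing_cols = [c for c in required if c not in baseline.columns]
    if missing_cols:
        raise FormatError(f"phenotype table missing required columns: {missing_cols}")
    if sex_codes and baseline["sex"].dtype == object:
        baseline["sex"] = baseline["sex"].map(sex_codes)
    baseline["sample_id"] = baseline["sample_id"].astype(str)
    if baseline["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in baseline table")
    baseline = baseline.set_index("sample_id")

    if visits_path is not None:
        visits = pd.read_csv(visits_path)
        if schema:
            visits = visits.rename(columns=dict(schema))
        visits["sample_id"] = visits["sample_id"].astype(str)
    else:
        trait_cols = [c for c in baseline.columns
                      if c not in required and not c.startswith(("status_", "pc"))
                      and c not in ("sex", "age", "lipid_medication")]
        visits = baseline.reset_index()[["sample_id"] + trait_cols].copy()
        visits["visit_time"] = 0.0

    if survival_path is not None:
        survival = pd.read_csv(survival_path)
        if schema:
            survival = survival.rename(columns=dict(schema))
        survival["sample_id"] = survival["sample_id"].astype(str)
    else:
        survival = pd.DataFrame(columns=["sample_id", "trait", "time", "event"])

    return PhenotypeTable(baseline=baseline, visits=visits, survival=survival)
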