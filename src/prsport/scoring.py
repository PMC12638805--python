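"""Per-sample polygenic scores from harmonized variants.

The raw score is the plain weighted sum of effect-allele dosages (no allele
frequency centering); the z-score standardizes over the analysis cohort, which
is the scale on which odds/hazard ratios per SD are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .harmonize import HarmonizationResult
from .io_formats import GenotypeMatrix, ScoringFile

MISSING_POLICIES = ("mean_dosage", "zero", "drop_variant")


@dataclass
class ScoreVector:
    """PRS values for one scoring file over one cohort."""

    pgs_id: str
    sample_ids: list[str]
    raw: np.ndarray
    z: np.ndarray
    n_variants_used: int
    mean_imputed_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "pgs_id": self.pgs_id,
            "raw": self.raw,
            "z": self.z,
            "n_variants_used": self.n_variants_used,
        })


def compute_prs(g: GenotypeMatrix, result: HarmonizationResult, score: ScoringFile,
                missing_policy: str = "mean_dosage") -> ScoreVector:
    """Sum effect-allele dosages weighted by published effect sizes.

    Effect-allele dosage is the alt dosage, or 2 − alt dosage for swapped
    orientation. Missing dosages are filled with 2 × effect-allele frequency
    (``mean_dosage``, the default, which preserves the cohort mean), with 0,
    or the variant is dropped entirely (``drop_variant``).
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    matched = result.matched
    if not matched.any():
        raise ValueError(f"{score.pgs_id}: no matched variants to score")

    idx = np.flatnonzero(matched)
    cols = result.genotype_column[idx]
    weights = score.weights[idx]
    eff_alt = result.effect_is_alt[idx]

    dose = g.dosage[:, cols].copy()
    miss = g.missing[:, cols]
    af = g.variant_meta["alt_frequency"].to_numpy()[cols]

    if missing_policy == "drop_variant":
        keep = ~miss.any(axis=0)
        dose, miss, af = dose[:, keep], miss[:, keep], af[keep]
        weights, eff_alt = weights[keep], eff_alt[keep]
        if dose.shape[1] == 0:
            raise ValueError(f"{score.pgs_id}: every matched variant has missing calls")
    elif missing_policy == "mean_dosage":
        dose = np.where(miss, 2.0 * af, dose)
    else:  # zero
        dose = np.where(miss, 0.0, dose)

    # orient to effect allele: alt dosage, or 2 - alt dosage when effect = ref
    eff_dose = np.where(eff_alt[None, :], dose, 2.0 - dose)
    raw = eff_dose @ weights

    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError(f"{score.pgs_id}: zero score variance; z-score undefined "
                         f"({dose.shape[1]} variants used)")
    z = (raw - raw.mean()) / sd
    return ScoreVector(
        pgs_id=score.pgs_id,
        sample_ids=list(g.sample_ids),
        raw=raw,
        z=z,
        n_variants_used=int(dose.shape[1]),
        mean_imputed_fraction=float(miss.mean()) if miss.size else 0.0,
    )
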