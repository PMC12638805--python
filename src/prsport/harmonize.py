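"""Align a scoring file's variants to a genotype panel and quantify retention.

Matching resolves allele representation (effect allele on the alt or ref
column), strand flips via reverse complement, and palindromic (A/T, C/G)
ambiguity via a configurable policy. Retention is summarised two ways: the
simple fraction of score variants matched, and the fraction of cumulative
absolute effect weight carried by matched variants.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, ScoringFile

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class MatchStatus(enum.Enum):
    MATCHED_DIRECT = "matched_direct"
    MATCHED_SWAPPED = "matched_swapped"
    MATCHED_STRAND_FLIPPED = "matched_strand_flipped"
    DROPPED_PALINDROMIC = "dropped_palindromic"
    DROPPED_LOW_INFO = "dropped_low_info"
    UNMATCHED = "unmatched"


MATCHED_STATUSES = frozenset({MatchStatus.MATCHED_DIRECT, MatchStatus.MATCHED_SWAPPED,
                              MatchStatus.MATCHED_STRAND_FLIPPED})


class PalindromicPolicy(NamedTuple):
    """How to treat A/T and C/G score variants, whose strand is ambiguous.

    mode 'drop' removes them; 'drop_if_maf_above' keeps them only when the
    panel minor-allele frequency is informative (below ``maf_threshold``);
    'keep' matches them by allele labels with strand flips disabled.
    """

    mode: str = "drop_if_maf_above"
    maf_threshold: float = 0.40

    @classmethod
    def drop(cls) -> "PalindromicPolicy":
        return cls(mode="drop")

    @classmethod
    def keep(cls) -> "PalindromicPolicy":
        return cls(mode="keep")


def is_palindromic(a1: str, a2: Optional[str]) -> bool:
    return a2 is not None and COMPLEMENT.get(a1) == a2


@dataclass
class HarmonizationResult:
    """Per-score-variant match ledger binding a ScoringFile to a panel."""

    pgs_id: str
    statuses: list[MatchStatus]
    genotype_column: np.ndarray  # index into the panel, -1 when not matched
    effect_is_alt: np.ndarray  # True when effect-allele dosage = alt dosage

    def __post_init__(self):
        cols = self.genotype_column[self.genotype_column >= 0]
        if len(cols) != len(set(cols.tolist())):
            raise ValueError("matched score variants must map to distinct columns")

    @property
    def n_variants(self) -> int:
        return len(self.statuses)

    @property
    def matched(self) -> np.ndarray:
        return np.array([s in MATCHED_STATUSES for s in self.statuses])

    @property
    def n_matched(self) -> int:
        return int(self.matched.sum())

    def status_counts(self) -> dict[str, int]:
        counts = {s.value: 0 for s in MatchStatus}
        for s in self.statuses:
            counts[s.value] += 1
        return counts

    def to_frame(self, score: Optional[ScoringFile] = None) -> pd.DataFrame:
        rows = {
            "status": [s.value for s in self.statuses],
            "genotype_column": self.genotype_column,
            "effect_is_alt": self.effect_is_alt,
        }
        if score is not None:
            rows = {
                "chromosome": [v.chromosome for v in score.variants],
                "position": [v.position for v in score.variants],
                "rsid": [v.rsid for v in score.variants],
                "effect_allele": [v.effect_allele for v in score.variants],
                "weight": [v.weight for v in score.variants],
                **rows,
            }
        return pd.DataFrame(rows)


def _try_allele_match(effect: str, other: Optional[str], ref: str, alt: str):
    """Return effect_is_alt for an exact allele-pair match, else None."""
    if other is None:
        if effect == alt:
            return True
        if effect == ref:
            return False
        return None
    if effect == alt and other == ref:
        return True
    if effect == ref and other == alt:
        return False
    return None


def match_variants(score: ScoringFile, g: GenotypeMatrix,
                   palindromic_policy: PalindromicPolicy = PalindromicPolicy(),
                   allow_strand_flip: bool = True,
                   info_min: Optional[float] = None) -> HarmonizationResult:
    """Match score variants to panel columns.

    Precedence: (1) chromosome+position with exact allele-pair agreement,
    (2) the same after reverse-complementing the score alleles (non-palindromic
    only, when ``allow_strand_flip``), (3) rsID with the same allele logic.
    Score variants lacking an other_allele match on effect allele in
    {ref, alt} and never strand-flip. When ``info_min`` is given, variants
    whose only panel match fails the INFO threshold are booked as
    dropped_low_info. Each panel column is used at most once (first score
    variant in file order wins; candidates taken in position order).
    """
    if len(score) == 0:
        raise ValueError("scoring file with zero variants")

    meta = g.variant_meta
    order = np.lexsort((meta["position"].to_numpy(), meta["chromosome"].astype(str).to_numpy()))
    by_pos: dict[tuple[str, int], list[int]] = {}
    by_rsid: dict[str, list[int]] = {}
    for j in order:
        row = meta.iloc[int(j)]
        by_pos.setdefault((str(row["chromosome"]), int(row["position"])), []).append(int(j))
        if pd.notna(row["rsid"]) and row["rsid"]:
            by_rsid.setdefault(str(row["rsid"]), []).append(int(j))

    statuses: list[MatchStatus] = []
    columns = np.full(len(score), -1, dtype=int)
    orient = np.zeros(len(score), dtype=bool)
    used: set[int] = set()

    for i, v in enumerate(score.variants):
        candidates: list[int] = []
        if v.has_coordinates:
            candidates = by_pos.get((v.chromosome, v.position), [])
        rs_candidates = by_rsid.get(v.rsid, []) if v.rsid else []

        palindromic = is_palindromic(v.effect_allele, v.other_allele)
        if palindromic and palindromic_policy.mode == "drop":
            statuses.append(MatchStatus.DROPPED_PALINDROMIC)
            continue
        flip_allowed = allow_strand_flip and v.other_allele is not None and not palindromic

        status = MatchStatus.UNMATCHED
        col = -1
        eff_alt = False
        low_info_seen = False

        for source in (candidates, rs_candidates):
            if status in MATCHED_STATUSES or status is MatchStatus.DROPPED_PALINDROMIC:
                break
            for j in source:
                if j in used:
                    continue
                row = meta.iloc[j]
                ref, alt = row["ref_allele"], row["alt_allele"]
                m = _try_allele_match(v.effect_allele, v.other_allele, ref, alt)
                flipped = False
                if m is None and flip_allowed:
                    m = _try_allele_match(COMPLEMENT[v.effect_allele],
                                          COMPLEMENT[v.other_allele], ref, alt)
                    flipped = m is not None
                if m is None:
                    continue
                if palindromic and palindromic_policy.mode == "drop_if_maf_above":
                    af = float(row["alt_frequency"])
                    if min(af, 1.0 - af) > palindromic_policy.maf_threshold:
                        status = MatchStatus.DROPPED_PALINDROMIC
                        break
                if info_min is not None and float(row["info_score"]) < info_min:
                    low_info_seen = True
                    continue
                status = (MatchStatus.MATCHED_STRAND_FLIPPED if flipped
                          else (MatchStatus.MATCHED_DIRECT if m else MatchStatus.MATCHED_SWAPPED))
                col = j
                eff_alt = m
                break

        if status is MatchStatus.UNMATCHED and low_info_seen:
            status = MatchStatus.DROPPED_LOW_INFO
        if col >= 0:
            used.add(col)
        statuses.append(status)
        columns[i] = col
        orient[i] = eff_alt

    return HarmonizationResult(pgs_id=score.pgs_id, statuses=statuses,
                               genotype_column=columns, effect_is_alt=orient)


def simple_retention(result: HarmonizationResult) -> float:
    """Fraction of score variants matched to the panel."""
    return result.n_matched / result.n_variants


def weighted_retention(result: HarmonizationResult, score: ScoringFile) -> float:
    """Fraction of cumulative |effect weight| carried by matched variants."""
    w = np.abs(score.weights)
    total = w.sum()
    if total == 0:
        raise ValueError("all score weights are zero; weighted retention undefined")
    return float(w[result.matched].sum() / total)


def retention_performance_correlation(points: Sequence[tuple[float, float]]
                                      ) -> tuple[float, float]:
    """OLS of a performance metric on retention; returns (R², slope p-value)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 (retention, metric) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in retention")
    fit = stats.linregress(x, y)
    return float(fit.rvalue ** 2), float(fit.pvalue)
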