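"""Variant matching, retention metrics, and their invariances."""

import numpy as np
import pytest

from prsport.harmonize import (COMPLEMENT, HarmonizationResult, MatchStatus,
                               PalindromicPolicy, match_variants,
                               retention_performance_correlation, simple_retention,
                               weighted_retention)
from prsport.io_formats import ScoreVariant, ScoringFile
from prsport.scoring import compute_prs
from tests.conftest import make_panel


def sv(pos, effect, other=None, weight=0.1, chrom="1", rsid=None):
    return ScoreVariant(chromosome=chrom, position=pos, rsid=rsid,
                        effect_allele=effect, other_allele=other, weight=weight)


def score_of(*variants, pgs_id="PGSTEST"):
    return ScoringFile(pgs_id=pgs_id, variants=list(variants))


def statuses(result):
    return [s.value for s in result.statuses]


class TestMatchVariants:
    def test_direct_match_effect_is_alt(self, tiny_panel):
        r = match_variants(score_of(sv(100, "A", "G", 0.2)), tiny_panel)
        assert statuses(r) == ["matched_direct"]
        assert r.effect_is_alt[0]
        assert r.genotype_column[0] == 0

    def test_swapped_match_effect_is_ref(self, tiny_panel):
        r = match_variants(score_of(sv(100, "G", "A")), tiny_panel)
        assert statuses(r) == ["matched_swapped"]
        assert not r.effect_is_alt[0]

    def test_strand_flip_resolved_by_complement(self, tiny_panel):
        # panel at pos 200 is T/G; score C/A complements to G/T
        r = match_variants(score_of(sv(200, "C", "A")), tiny_panel)
        assert statuses(r) == ["matched_strand_flipped"]
        assert r.effect_is_alt[0]  # C complements to G = alt

    def test_strand_flip_disabled(self, tiny_panel):
        r = match_variants(score_of(sv(200, "C", "A")), tiny_panel,
                           allow_strand_flip=False)
        assert statuses(r) == ["unmatched"]

    def test_palindromic_dropped_above_maf_threshold(self, tiny_panel):
        # panel pos 300 is A/T with alt frequency 0.45 > 0.40
        r = match_variants(score_of(sv(300, "A", "T", chrom="2")), tiny_panel,
                           palindromic_policy=PalindromicPolicy("drop_if_maf_above", 0.40))
        assert statuses(r) == ["dropped_palindromic"]

    def test_palindromic_kept_when_maf_informative(self, tiny_panel):
        r = match_variants(score_of(sv(300, "A", "T", chrom="2")), tiny_panel,
                           palindromic_policy=PalindromicPolicy("drop_if_maf_above", 0.49))
        # panel lists ref=A, alt=T, so effect allele A is the ref column
        assert statuses(r) == ["matched_swapped"]
        assert not r.effect_is_alt[0]

    def test_rsid_fallback_when_coordinates_miss(self, tiny_panel):
        v = ScoreVariant(chromosome="9", position=999, rsid="rs2",
                         effect_allele="G", other_allele="T", weight=0.3)
        r = match_variants(score_of(v), tiny_panel)
        assert statuses(r) == ["matched_direct"]
        assert r.genotype_column[0] == 1

    def test_no_other_allele_matches_without_flip(self, tiny_panel):
        r = match_variants(score_of(sv(100, "A")), tiny_panel)
        assert statuses(r) == ["matched_direct"]
        # complement-only variant must not strand-flip when other allele unknown
        r2 = match_variants(score_of(sv(200, "C")), tiny_panel)
        assert statuses(r2) == ["unmatched"]

    def test_low_info_bookkeeping(self, tiny_panel):
        r = match_variants(score_of(sv(200, "G", "T")), tiny_panel, info_min=0.95)
        assert statuses(r) == ["dropped_low_info"]

    def test_each_panel_column_used_once(self, tiny_panel):
        # both score variants resolve to panel column 0 (one by coordinates,
        # one by rsID); the second must stay unmatched
        s = score_of(sv(100, "A", "G", 0.1),
                     ScoreVariant(chromosome="7", position=777, rsid="rs1",
                                  effect_allele="A", other_allele="G", weight=0.2))
        r = match_variants(s, tiny_panel)
        assert statuses(r) == ["matched_direct", "unmatched"]
        assert r.genotype_column[1] == -1


class TestRetention:
    @pytest.mark.parametrize("matched,total,expected", [
        (24, 35, 24 / 35), (0, 10, 0.0), (19, 19, 1.0),
    ])
    def test_simple_retention(self, matched, total, expected):
        sts = ([MatchStatus.MATCHED_DIRECT] * matched
               + [MatchStatus.UNMATCHED] * (total - matched))
        cols = np.where(np.arange(total) < matched, np.arange(total), -1)
        r = HarmonizationResult("P", sts, cols, np.ones(total, bool))
        assert simple_retention(r) == pytest.approx(expected)

    def test_weighted_retention_direct_sum(self):
        s = score_of(sv(100, "A", "G", 2.0), sv(200, "C", "G", 0.1),
                     sv(300, "T", "G", -0.1))
        sts = [MatchStatus.MATCHED_DIRECT, MatchStatus.UNMATCHED, MatchStatus.UNMATCHED]
        r = HarmonizationResult("P", sts, np.array([0, -1, -1]), np.ones(3, bool))
        assert weighted_retention(r, s) == pytest.approx(2.0 / 2.2)

    def test_weighted_equals_simple_under_equal_weights(self):
        s = score_of(*[sv(100 * (i + 1), "A", "G", 1.0) for i in range(4)])
        sts = [MatchStatus.MATCHED_DIRECT] * 3 + [MatchStatus.UNMATCHED]
        r = HarmonizationResult("P", sts, np.array([0, 1, 2, -1]), np.ones(4, bool))
        assert weighted_retention(r, s) == pytest.approx(simple_retention(r)) == 0.75

    def test_all_zero_weights_error(self):
        s = score_of(sv(100, "A", "G", 0.0))
        r = HarmonizationResult("P", [MatchStatus.MATCHED_DIRECT],
                                np.array([0]), np.ones(1, bool))
        with pytest.raises(ValueError, match="zero"):
            weighted_retention(r, s)

    def test_retention_monotone_in_panel_growth(self, tiny_panel):
        s = score_of(sv(100, "A", "G"), sv(200, "G", "T"), sv(500, "C", "G"))
        small = tiny_panel.subset_variants(np.array([True, False, False]))
        r_small = match_variants(s, small)
        r_full = match_variants(s, tiny_panel)
        assert simple_retention(r_full) >= simple_retention(r_small)
        assert weighted_retention(r_full, s) >= weighted_retention(r_small, s)


class TestInvariances:
    def test_strand_flip_invariance(self, tiny_panel):
        s = score_of(sv(100, "A", "G", 0.4), sv(200, "G", "T", -0.2))
        flipped = score_of(*[ScoreVariant(chromosome=v.chromosome, position=v.position,
                                          rsid=v.rsid,
                                          effect_allele=COMPLEMENT[v.effect_allele],
                                          other_allele=COMPLEMENT[v.other_allele],
                                          weight=v.weight) for v in s.variants])
        r, rf = match_variants(s, tiny_panel), match_variants(flipped, tiny_panel)
        relabel = {MatchStatus.MATCHED_DIRECT: MatchStatus.MATCHED_STRAND_FLIPPED,
                   MatchStatus.MATCHED_STRAND_FLIPPED: MatchStatus.MATCHED_DIRECT,
                   MatchStatus.MATCHED_SWAPPED: MatchStatus.MATCHED_STRAND_FLIPPED}
        assert np.array_equal(r.effect_is_alt, rf.effect_is_alt)
        assert np.array_equal(r.genotype_column, rf.genotype_column)
        z = compute_prs(tiny_panel, r, s).z
        zf = compute_prs(tiny_panel, rf, flipped).z
        np.testing.assert_allclose(z, zf)

    def test_swap_negate_invariance(self, tiny_panel):
        s = score_of(sv(100, "A", "G", 0.4), sv(200, "G", "T", -0.2))
        swapped = score_of(*[ScoreVariant(chromosome=v.chromosome, position=v.position,
                                          rsid=v.rsid, effect_allele=v.other_allele,
                                          other_allele=v.effect_allele,
                                          weight=-v.weight) for v in s.variants])
        r, rs = match_variants(s, tiny_panel), match_variants(swapped, tiny_panel)
        z = compute_prs(tiny_panel, r, s).z
        zs = compute_prs(tiny_panel, rs, swapped).z
        np.testing.assert_allclose(z, zs, atol=1e-12)


class TestRetentionPerformanceCorrelation:
    def test_collinear_points(self):
        pts = [(0.1, 1.0), (0.5, 5.0), (0.9, 9.0)]
        r2, p = retention_performance_correlation(pts)
        assert r2 == pytest.approx(1.0)

    def test_against_closed_form_ols(self):
        pts = [(0.2, 0.55), (0.4, 0.61), (0.5, 0.58), (0.7, 0.70), (0.9, 0.66)]
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        # normal-equations oracle
        beta = np.linalg.lstsq(np.column_stack([np.ones(5), x]), y, rcond=None)[0]
        resid = y - beta[0] - beta[1] * x
        r2_oracle = 1 - resid.var() / y.var()
        r2, p = retention_performance_correlation(pts)
        assert r2 == pytest.approx(r2_oracle, rel=1e-10)
        assert 0 < p < 1

    def test_null_is_near_zero(self):
        rng = np.random.default_rng(0)
        pts = list(zip(rng.uniform(0, 1, 5000), rng.normal(size=5000)))
        r2, p = retention_performance_correlation(pts)
        assert r2 < 0.01

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            retention_performance_correlation([(0.5, 1.0), (0.5, 2.0), (0.5, 3.0)])
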