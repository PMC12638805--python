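"""Association models, AUC, liability transformation, FDR, kinship."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prsport.evaluate import (EvalResult, SeparationError, auc_delong_ci,
                              auc_mann_whitney, bh_fdr, fit_binary_model,
                              fit_continuous_model, king_kinship, kinship_table,
                              liability_r2, liability_r2_from_status,
                              nagelkerke_r2, per_variant_association, prune_related,
                              select_best_prs)
from tests.conftest import make_panel


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc_pair_counting(scores, labels):
    """Brute-force concordant-pair oracle: count case>control pairs (+½ ties)."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    return wins / (len(cases) * len(controls))


def test_perfect_ranking_auc():
    scores = np.array([0.9, 0.8, 0.1, 0.2])
    labels = np.array([1, 1, 0, 0])
    assert auc_mann_whitney(scores, labels) == 1.0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_auc_equals_pair_counting(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=60).round(1)  # rounding forces ties
    labels = rng.integers(0, 2, size=60)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    expected = auc_pair_counting(scores, labels)
    assert auc_mann_whitney(scores, labels) == pytest.approx(expected, abs=1e-12)
    auc, lo, hi = auc_delong_ci(scores, labels)
    assert auc == pytest.approx(expected, abs=1e-12)
    assert lo <= auc <= hi


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(3)
    scores = rng.normal(size=200)
    labels = (rng.normal(size=200) + 0.5 * scores > 0).astype(int)
    assert auc_mann_whitney(scores, labels) == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12)


# ---------------------------------------------------------------------------
# binary model
# ---------------------------------------------------------------------------

def test_null_prs_has_or_near_one():
    rng = np.random.default_rng(11)
    n = 20000
    z = rng.normal(size=n)
    y = rng.binomial(1, 0.1, size=n)
    res = fit_binary_model(z, y, trait="t2d", prevalence=0.1)
    assert res.effect_ci[0] <= 1.0 <= res.effect_ci[1]
    assert res.auc_prs_only == pytest.approx(0.5, abs=0.02)
    assert res.nagelkerke_r2 < 0.005


def test_informative_prs_detected():
    rng = np.random.default_rng(12)
    n = 4000
    z = rng.normal(size=n)
    logit = -2.2 + 0.5 * z
    y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
    cov = pd.DataFrame({"age": rng.normal(40, 10, n)})
    res = fit_binary_model(z, y, cov, trait="t2d", prevalence=0.1)
    assert res.effect == pytest.approx(np.exp(0.5), rel=0.15)
    assert res.p < 1e-10
    assert res.auc > 0.55
    assert res.liability_r2 is not None and 0 < res.liability_r2 < 1


def test_single_class_outcome_is_error():
    with pytest.raises(ValueError):
        fit_binary_model(np.random.default_rng(0).normal(size=50), np.zeros(50))


def test_separation_flagged():
    z = np.linspace(-3, 3, 40)
    y = (z > 0).astype(int)
    with pytest.raises(SeparationError):
        fit_binary_model(z, y)


def test_nagelkerke_zero_when_no_improvement():
    assert nagelkerke_r2(-100.0, -100.0, 200) == 0.0


# ---------------------------------------------------------------------------
# liability transformation
# ---------------------------------------------------------------------------

def test_liability_zero_maps_to_zero():
    assert liability_r2(0.0, 0.1, 0.3) == 0.0


def test_no_ascertainment_limit_is_exact():
    K = 0.15
    t = stats.norm.ppf(1 - K)
    z = stats.norm.pdf(t)
    c = (K * (1 - K) / z ** 2) * (K * (1 - K) / (K * (1 - K)))
    # at P = K the correction term vanishes identically
    assert liability_r2(0.2, K, K) == pytest.approx(c * 0.2, rel=1e-12)
    assert liability_r2(0.2, K, K, ascertainment_correction=False) == \
        pytest.approx(c * 0.2, rel=1e-12)


def test_liability_monotone_in_r2_and_continuous_in_k_p():
    vals = [liability_r2(r2, 0.1, 0.3) for r2 in np.linspace(0.01, 0.5, 20)]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    base = liability_r2(0.1, 0.10, 0.30)
    assert abs(liability_r2(0.1, 0.10 + 1e-6, 0.30) - base) < 1e-4
    assert abs(liability_r2(0.1, 0.10, 0.30 + 1e-6) - base) < 1e-4


def test_liability_domain_errors():
    for bad in [(0.1, 0.0, 0.5), (0.1, 0.5, 1.0), (1.0, 0.1, 0.1), (-0.1, 0.1, 0.1)]:
        with pytest.raises(ValueError):
            liability_r2(*bad)


def test_liability_from_status_recovers_simulated_truth():
    # liability-threshold simulation: z explains r2_true of the latent scale
    rng = np.random.default_rng(42)
    n, K, r2_true = 60000, 0.1, 0.12
    z = rng.normal(size=n)
    liab = np.sqrt(r2_true) * z + np.sqrt(1 - r2_true) * rng.normal(size=n)
    y = (liab > stats.norm.ppf(1 - K)).astype(int)
    est = liability_r2_from_status(z, y, K)
    assert est == pytest.approx(r2_true, abs=0.02)


# ---------------------------------------------------------------------------
# continuous model
# ---------------------------------------------------------------------------

def test_exact_linear_relation():
    z = np.linspace(-2, 2, 50)
    res = fit_continuous_model(z, 2 * z, trait="ldl")
    assert res.effect == pytest.approx(2.0, abs=1e-10)
    assert res.incremental_r2 == pytest.approx(1.0, abs=1e-10)


def test_null_continuous():
    rng = np.random.default_rng(13)
    z = rng.normal(size=20000)
    y = rng.normal(size=20000)
    res = fit_continuous_model(z, y)
    assert abs(res.effect) < 0.05
    assert res.incremental_r2 == pytest.approx(0.0, abs=0.002)


def test_six_point_normal_equations_oracle():
    z = np.array([-1.2, -0.4, 0.1, 0.5, 1.1, 2.0])
    y = np.array([3.1, 2.0, 2.4, 2.9, 3.8, 4.4])
    X = np.column_stack([np.ones(6), z])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    res = fit_continuous_model(z, y)
    assert res.effect == pytest.approx(beta[1], rel=1e-10)


def test_collinear_covariates_reported():
    rng = np.random.default_rng(14)
    z = rng.normal(size=30)
    cov = pd.DataFrame({"a": np.arange(30.0), "b": 2 * np.arange(30.0)})
    with pytest.raises(ValueError, match="collinear"):
        fit_continuous_model(z, rng.normal(size=30), cov)


# ---------------------------------------------------------------------------
# FDR and selection
# ---------------------------------------------------------------------------

def bh_naive(p):
    """O(m²) step-up definition: q_i = min over p_(j) >= p_(i) of p_(j)·m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    for i in range(m):
        candidates = [p[order[j]] * m / (j + 1) for j in range(m)
                      if p[order[j]] >= p[i] - 1e-15]
        q[i] = min(min(candidates), 1.0)
    return q


def test_single_pvalue_identity():
    assert bh_fdr([0.03])[0] == pytest.approx(0.03)


def test_step_up_worked_example():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_matches_naive_step_up(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=rng.integers(5, 100))
    np.testing.assert_allclose(bh_fdr(p), bh_naive(p), atol=1e-12)


def test_groups_corrected_independently():
    p = [0.01, 0.8, 0.02, 0.5]
    g = ["a", "b", "a", "b"]
    q1 = bh_fdr(p, g)
    q2 = bh_fdr([0.01, 0.001, 0.02, 0.9], g)  # change only group b
    np.testing.assert_allclose(q1[[0, 2]], q2[[0, 2]])


def _res(pgs, auc=None, r2=None, p=0.01, q=0.01, kind="binary"):
    return EvalResult(pgs_id=pgs, trait="t", model_kind=kind, effect=1.5,
                      effect_ci=(1.2, 1.9), p=p, n=100, auc=auc,
                      incremental_r2=r2, fdr_q=q)


def test_select_best_by_auc():
    assert select_best_prs([_res("A", auc=0.70), _res("B", auc=0.65)]) == "A"


def test_select_none_when_nothing_significant():
    assert select_best_prs([_res("A", auc=0.70, q=0.2)]) is None


def test_select_tie_broken_by_p_then_id():
    assert select_best_prs([_res("B", auc=0.70, p=0.04),
                            _res("A", auc=0.70, p=0.01)]) == "A"
    assert select_best_prs([_res("B", auc=0.70, p=0.01),
                            _res("A", auc=0.70, p=0.01)]) == "A"


# ---------------------------------------------------------------------------
# per-variant association
# ---------------------------------------------------------------------------

def test_exact_dosage_relation_has_floor_p():
    rng = np.random.default_rng(15)
    d = rng.binomial(2, 0.4, size=(30, 1)).astype(float)
    g = make_panel([("1", 100, "rs0", "G", "A", 0.9, 0.4)], dosage=d)
    table = per_variant_association(g, d[:, 0], kind="continuous")
    assert table["effect"][0] == pytest.approx(1.0, abs=1e-10)
    assert table["p"][0] < 1e-200


def test_causal_variant_has_smallest_p():
    rng = np.random.default_rng(16)
    n, m = 2000, 25
    d = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    g = make_panel([("1", 100 * (j + 1), f"rs{j}", "G", "A", 0.9, 0.3)
                    for j in range(m)], dosage=d)
    y = 0.8 * d[:, 7] + rng.normal(size=n)
    table = per_variant_association(g, y, kind="continuous")
    assert table.loc[table["p"].idxmin(), "variant"] == 7
    assert table.loc[table["variant"] == 7, "genome_wide"].item()


def test_null_calibration():
    rng = np.random.default_rng(17)
    n, m = 500, 200
    d = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    g = make_panel([("1", 100 * (j + 1), f"rs{j}", "G", "A", 0.9, 0.3)
                    for j in range(m)], dosage=d)
    y = rng.normal(size=n)  # independent of every variant
    table = per_variant_association(g, y, kind="continuous")
    frac = (table["p"] < 0.05).mean()
    assert frac == pytest.approx(0.05, abs=0.035)


def test_all_monomorphic_is_error():
    g = make_panel([("1", 100, "rs0", "G", "A", 0.9, 0.0)],
                   dosage=np.zeros((20, 1)))
    with pytest.raises(ValueError, match="monomorphic"):
        per_variant_association(g, np.random.default_rng(0).normal(size=20))


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def test_duplicate_samples_have_phi_half():
    g = np.array([0, 1, 2, 1, 0, 1])
    assert king_kinship(g, g) == pytest.approx(0.5)


def test_unrelated_pair_phi_near_zero():
    rng = np.random.default_rng(18)
    maf = rng.uniform(0.1, 0.5, size=10000)
    a = rng.binomial(2, maf)
    b = rng.binomial(2, maf)
    assert abs(king_kinship(a, b)) < 0.02


def test_parent_offspring_phi_near_quarter():
    rng = np.random.default_rng(19)
    m = 10000
    maf = rng.uniform(0.1, 0.5, size=m)
    parent = rng.binomial(2, maf)
    # one allele transmitted from the parent, one drawn from the population
    transmitted = np.where(parent == 1, rng.integers(0, 2, m), parent // 2)
    offspring = transmitted + rng.binomial(1, maf)
    assert king_kinship(parent, offspring) == pytest.approx(0.25, abs=0.02)


def test_no_heterozygotes_is_error():
    with pytest.raises(ValueError):
        king_kinship(np.array([0, 2, 0]), np.array([2, 0, 2]))


def test_prune_nothing_below_threshold():
    k = pd.DataFrame({"id_i": ["a"], "id_j": ["b"], "phi": [0.05]})
    assert prune_related(k) == ["a", "b"]


def test_prune_duplicate_pair_removes_one():
    k = pd.DataFrame({"id_i": ["a"], "id_j": ["b"], "phi": [0.5]})
    assert len(prune_related(k)) == 1


def test_prune_triangle_greedy_trace():
    # three mutually related samples: greedy drops the max-degree sample
    # (ties lexicographic: 'a'), then one of the remaining pair ('b');
    # exactly one sample survives
    k = pd.DataFrame({"id_i": ["a", "a", "b"], "id_j": ["b", "c", "c"],
                      "phi": [0.3, 0.3, 0.3]})
    assert prune_related(k) == ["c"]
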