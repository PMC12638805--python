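"""Cross-sectional evaluation of polygenic scores.

Binary traits: logistic regression adjusted for age, sex, and ten principal
components, reporting the odds ratio per PRS standard deviation, AUC with
DeLong confidence interval, incremental Nagelkerke pseudo-R², and its
liability-scale transformation under an assumed population prevalence.
Continuous traits: adjusted linear regression with incremental R². Also
provides per-trait Benjamini–Hochberg FDR control, best-score selection,
per-variant association scans, and KING-robust relatedness pruning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_formats import GenotypeMatrix
from .scoring import ScoreVector

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-5


class SeparationError(RuntimeError):
    """Logistic fit failed to converge (e.g. quasi-complete separation)."""


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (concordance) AUC: P(score_case > score_control) + ½ ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc_delong_ci(scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05
                  ) -> tuple[float, float, float]:
    """AUC with DeLong variance-based normal CI, clipped to [0, 1]."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("AUC requires both classes")
    # placement values via midranks
    all_ranks = stats.rankdata(np.concatenate([x, y]))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    v10 = (all_ranks[:m] - rx) / n          # per-case placements
    v01 = 1.0 - (all_ranks[m:] - ry) / m    # per-control placements
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return auc, max(0.0, auc - zcrit * se), min(1.0, auc + zcrit * se)


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """Per-PRS performance record for one trait."""

    pgs_id: str
    trait: str
    model_kind: str  # "binary" | "continuous"
    effect: float  # OR per SD (binary) or beta (continuous)
    effect_ci: tuple[float, float]
    p: float
    n: int
    auc: Optional[float] = None
    auc_ci: Optional[tuple[float, float]] = None
    auc_prs_only: Optional[float] = None
    nagelkerke_r2: Optional[float] = None
    nagelkerke_r2_full: Optional[float] = None
    liability_r2: Optional[float] = None
    incremental_r2: Optional[float] = None
    fdr_q: Optional[float] = None
    simple_retention: Optional[float] = None
    weighted_retention: Optional[float] = None

    def __post_init__(self):
        lo, hi = self.effect_ci
        if not (lo <= self.effect <= hi):
            raise ValueError("CI does not contain point estimate")


def _design(z: np.ndarray, covariates: Optional[pd.DataFrame]) -> pd.DataFrame:
    X = pd.DataFrame({"prs_z": np.asarray(z, float)})
    if covariates is not None:
        cov = covariates.reset_index(drop=True).astype(float)
        X = pd.concat([X, cov], axis=1)
    return sm.add_constant(X)


def nagelkerke_r2(ll_full: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R² from two log-likelihoods.

    R²_CS = 1 − exp(−2(ℓ₁−ℓ₀)/n), scaled by its maximum 1 − exp(2ℓ₀/n).
    """
    r2_cs = 1.0 - np.exp(-2.0 * (ll_full - ll_null) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    if max_cs <= 0:
        return 0.0
    return float(max(0.0, r2_cs / max_cs))


def fit_binary_model(z: ScoreVector | np.ndarray, status: np.ndarray,
                     covariates: Optional[pd.DataFrame] = None,
                     trait: str = "", prevalence: Optional[float] = None) -> EvalResult:
    """Logistic evaluation of a PRS against a binary outcome.

    Reports the OR per PRS SD with Wald 95% CI and p, the AUC of the full
    adjusted model (and of the PRS alone), incremental Nagelkerke pseudo-R²
    (full vs covariate-only likelihoods), and — when ``prevalence`` is given —
    its liability-scale transformation at the sample case fraction.
    """
    pgs_id = z.pgs_id if isinstance(z, ScoreVector) else ""
    zv = z.z if isinstance(z, ScoreVector) else np.asarray(z, float)
    y = np.asarray(status, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("status must be 0/1")
    if y.min() == y.max():
        raise ValueError("single-class outcome")
    n = len(y)
    X_full = _design(zv, covariates)
    if n <= X_full.shape[1]:
        raise ValueError("more parameters than observations")

    try:
        full = sm.Logit(y, X_full).fit(disp=0, maxiter=200)
        X_null = X_full.drop(columns="prs_z")
        null = sm.Logit(y, X_null).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not (full.mle_retvals.get("converged", True) and null.mle_retvals.get("converged", True)):
        raise SeparationError("logistic fit did not converge (possible separation)")

    beta = float(full.params["prs_z"])
    se = float(full.bse["prs_z"])
    zcrit = stats.norm.ppf(0.975)
    auc_full, lo, hi = auc_delong_ci(full.predict(X_full), y)
    r2_inc = nagelkerke_r2(full.llf, null.llf, n)
    r2_full = nagelkerke_r2(full.llf, float(sm.Logit(y, np.ones((n, 1))).fit(disp=0).llf), n)
    liab = None
    if prevalence is not None:
        liab = liability_r2(r2_inc, K=prevalence, P=float(y.mean()))
    return EvalResult(
        pgs_id=pgs_id, trait=trait, model_kind="binary",
        effect=float(np.exp(beta)),
        effect_ci=(float(np.exp(beta - zcrit * se)), float(np.exp(beta + zcrit * se))),
        p=float(full.pvalues["prs_z"]), n=n,
        auc=auc_full, auc_ci=(lo, hi),
        auc_prs_only=auc_mann_whitney(zv, y),
        nagelkerke_r2=r2_inc, nagelkerke_r2_full=r2_full, liability_r2=liab,
    )


def liability_r2(r2_obs: float, K: float, P: float,
                 ascertainment_correction: bool = True) -> float:
    """Transform an observed-scale R² to the liability scale.

    Under a liability-threshold model with population prevalence ``K`` and
    sample case fraction ``P``: with t = Φ⁻¹(1−K), z = φ(t), i = z/K,
    c = K(1−K)/z² · K(1−K)/(P(1−P)) and
    θ = i·(P−K)/(K(1−K)) · (i·(P−K)/(K(1−K)) − t), returns
    c·R² / (1 + c·θ·R²); without the ascertainment correction, c·R².
    """
    if not (0.0 < K < 1.0) or not (0.0 < P < 1.0):
        raise ValueError("K and P must lie in (0, 1)")
    if not (0.0 <= r2_obs < 1.0):
        raise ValueError("r2_obs must lie in [0, 1)")
    t = stats.norm.ppf(1.0 - K)
    z = stats.norm.pdf(t)
    i = z / K
    c = (K * (1.0 - K) / z ** 2) * (K * (1.0 - K) / (P * (1.0 - P)))
    if not ascertainment_correction:
        return float(c * r2_obs)
    a = i * (P - K) / (K * (1.0 - K))
    theta = a * (a - t)
    return float(c * r2_obs / (1.0 + c * theta * r2_obs))


def liability_r2_from_status(z: np.ndarray, status: np.ndarray, K: float,
                             ascertainment_correction: bool = True) -> float:
    """Liability-scale R² of a predictor, from the observed 0/1 scale.

    Computes the linear-regression R² of status on the predictor — the
    observed-scale quantity the liability transformation is derived for —
    and maps it to the liability scale at the sample case fraction. (Feeding
    Nagelkerke's pseudo-R² through the same transformation systematically
    overstates liability R²; see the methods note.)
    """
    y = np.asarray(status, float)
    r2_obs = float(sm.OLS(y, sm.add_constant(np.asarray(z, float))).fit().rsquared)
    return liability_r2(r2_obs, K=K, P=float(y.mean()),
                        ascertainment_correction=ascertainment_correction)


def fit_continuous_model(z: ScoreVector | np.ndarray, y: np.ndarray,
                         covariates: Optional[pd.DataFrame] = None,
                         trait: str = "") -> EvalResult:
    """Linear evaluation of a PRS against a continuous trait.

    Reports β per unit standardized PRS with 95% CI and t-test p, and the
    incremental adjusted R² (full model minus covariate-only model).
    """
    pgs_id = z.pgs_id if isinstance(z, ScoreVector) else ""
    zv = z.z if isinstance(z, ScoreVector) else np.asarray(z, float)
    y = np.asarray(y, float)
    if y.std() == 0:
        raise ValueError("outcome has zero variance")
    X_full = _design(zv, covariates)
    n = len(y)
    if n <= X_full.shape[1]:
        raise ValueError("more parameters than observations")
    rank = np.linalg.matrix_rank(X_full.to_numpy())
    if rank < X_full.shape[1]:
        corr = X_full.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"collinear covariates (e.g. {worst[0]} vs {worst[1]})")

    full = sm.OLS(y, X_full).fit()
    if covariates is not None and covariates.shape[1] > 0:
        null = sm.OLS(y, X_full.drop(columns="prs_z")).fit()
        inc_r2 = float(full.rsquared_adj - null.rsquared_adj)
    else:
        inc_r2 = float(full.rsquared_adj)
    ci = full.conf_int().loc["prs_z"]
    return EvalResult(
        pgs_id=pgs_id, trait=trait, model_kind="continuous",
        effect=float(full.params["prs_z"]), effect_ci=(float(ci[0]), float(ci[1])),
        p=float(full.pvalues["prs_z"]), n=n, incremental_r2=inc_r2,
    )


# ---------------------------------------------------------------------------
# Multiple testing and model selection
# ---------------------------------------------------------------------------

def bh_fdr(pvalues: Sequence[float], grouping: Optional[Sequence] = None) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, applied separately per group."""
    p = np.asarray(pvalues, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.empty_like(p)
    groups = np.zeros(len(p)) if grouping is None else np.asarray(grouping)
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        pg = p[idx]
        m = len(pg)
        order = np.argsort(pg, kind="stable")
        adj = pg[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        qg = np.empty(m)
        qg[order] = np.minimum(adj, 1.0)
        q[idx] = qg
    return q


def select_best_prs(results: Sequence[EvalResult], alpha: float = 0.05) -> Optional[str]:
    """Pick the best FDR-significant score for one trait.

    Maximum AUC (binary) or incremental R² (continuous); ties broken by
    smaller p, then lexicographic pgs_id. None when nothing is significant.
    """
    if not results:
        raise ValueError("no results supplied")
    kinds = {r.model_kind for r in results}
    if len(kinds) > 1:
        raise ValueError("mixed model kinds for one trait")
    sig = [r for r in results if r.fdr_q is not None and r.fdr_q < alpha]
    if not sig:
        return None
    metric = (lambda r: r.auc) if kinds == {"binary"} else (lambda r: r.incremental_r2)
    return min(sig, key=lambda r: (-metric(r), r.p, r.pgs_id)).pgs_id


# ---------------------------------------------------------------------------
# Per-variant association
# ---------------------------------------------------------------------------

def per_variant_association(g: GenotypeMatrix, outcome: np.ndarray,
                            covariates: Optional[pd.DataFrame] = None,
                            kind: str = "continuous") -> pd.DataFrame:
    """One adjusted regression per variant dosage; BH-FDR over the tested set.

    Monomorphic variants are skipped with a log line. Output columns include
    genome-wide (p < 5e-8) and suggestive (p < 1e-5) significance flags.
    """
    if kind not in ("binary", "continuous"):
        raise ValueError(f"unknown kind {kind!r}")
    y = np.asarray(outcome, float)
    rows = []
    n_skipped = 0
    for j in range(g.n_variants):
        d = g.dosage[:, j].copy()
        miss = g.missing[:, j]
        if miss.any():
            af = g.variant_meta["alt_frequency"].iloc[j]
            d[miss] = 2.0 * af
        if d.std() == 0:
            n_skipped += 1
            continue
        X = _design(d, covariates)
        try:
            if kind == "binary":
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            else:
                fit = sm.OLS(y, X).fit()
        except Exception:
            n_skipped += 1
            continue
        rows.append(dict(
            variant=j,
            chromosome=g.variant_meta["chromosome"].iloc[j],
            position=g.variant_meta["position"].iloc[j],
            rsid=g.variant_meta["rsid"].iloc[j],
            effect=float(fit.params["prs_z"]),
            p=float(fit.pvalues["prs_z"]),
        ))
    if n_skipped:
        logger.info("per-variant scan: skipped %d monomorphic/failed variants", n_skipped)
    if not rows:
        raise ValueError("all variants monomorphic; nothing to test")
    table = pd.DataFrame(rows)
    table["fdr_q"] = bh_fdr(table["p"].to_numpy())
    table["genome_wide"] = table["p"] < GENOME_WIDE_P
    table["suggestive"] = table["p"] < SUGGESTIVE_P
    return table


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------

def king_kinship(gi: np.ndarray, gj: np.ndarray) -> float:
    """KING-robust kinship coefficient from two hard-call genotype vectors.

    φ̂ = (N_Aa,Aa − 2·N_AA,aa) / (N_Aa(i) + N_Aa(j)) over shared non-missing
    sites (missing encoded as negative values).
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    shared = (gi >= 0) & (gj >= 0)
    a, b = gi[shared], gj[shared]
    het_i = int((a == 1).sum())
    het_j = int((b == 1).sum())
    if het_i + het_j == 0:
        raise ValueError("kinship undefined: no heterozygous sites in either sample")
    n_hh = int(((a == 1) & (b == 1)).sum())
    n_opp = int((np.abs(a - b) == 2).sum())
    return float((n_hh - 2.0 * n_opp) / (het_i + het_j))


def kinship_table(g: GenotypeMatrix) -> pd.DataFrame:
    """All pairwise KING-robust estimates (small cohorts only: O(n²) pairs)."""
    calls = g.hard_calls()
    rows = []
    for i in range(g.n_samples):
        for j in range(i + 1, g.n_samples):
            rows.append(dict(id_i=g.sample_ids[i], id_j=g.sample_ids[j],
                             phi=king_kinship(calls[i], calls[j])))
    return pd.DataFrame(rows, columns=["id_i", "id_j", "phi"])


def prune_related(kinship: pd.DataFrame, threshold: float = 0.086) -> list[str]:
    """Greedy relatedness pruning.

    Iteratively drops the sample participating in the most pairs with
    φ > ``threshold`` (ties by lexicographic id) until no such pair remains;
    returns the retained sample ids (sorted).
    """
    samples = sorted(set(kinship["id_i"]) | set(kinship["id_j"]))
    pairs = {(r.id_i, r.id_j) for r in kinship.itertuples() if r.phi > threshold}
    removed: set[str] = set()
    while True:
        active = [p for p in pairs if p[0] not in removed and p[1] not in removed]
        if not active:
            break
        degree: dict[str, int] = {}
        for a, b in active:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        worst = min(degree, key=lambda s: (-degree[s], s))
        removed.add(worst)
    return [s for s in samples if s not in removed]
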