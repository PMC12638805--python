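"""Quantile-based risk stratification.

Samples are split into equal-count PRS bins (quartiles for binary outcomes,
deciles for continuous traits); binary outcomes get per-quantile odds ratios
against the lowest bin and a Cochran–Armitage trend test on case proportions,
continuous traits get per-quantile medians/IQRs with a rank-correlation
gradient diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .scoring import ScoreVector


def assign_quantiles(z: ScoreVector | np.ndarray, q: int,
                     sample_ids: Optional[Sequence[str]] = None) -> np.ndarray:
    """Rank-based equal-count quantile labels 1..q.

    Samples are sorted by score with stable tie-breaking on sample id; bin
    sizes differ by at most one, with the larger bins taken first so n = 10,
    q = 4 gives sizes (3, 3, 2, 2). Lower scores go to lower quantiles.
    """
    if isinstance(z, ScoreVector):
        sample_ids = z.sample_ids
        z = z.z
    z = np.asarray(z, float)
    n = len(z)
    if q < 2:
        raise ValueError("q must be at least 2")
    if q > n:
        raise ValueError(f"q={q} exceeds n={n}")
    ids = np.asarray(sample_ids if sample_ids is not None else np.arange(n).astype(str))
    order = np.lexsort((ids, z))
    base, extra = divmod(n, q)
    sizes = [base + 1 if k < extra else base for k in range(q)]
    labels = np.empty(n, dtype=int)
    start = 0
    for k, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = k
        start += size
    return labels


@dataclass
class StrataResult:
    """Per-quantile outcome summary with ORs vs the lowest quantile."""

    labels: np.ndarray
    table: pd.DataFrame  # quantile, n, cases, case_fraction, odds_ratio, ci_low, ci_high, p
    trend_z: Optional[float] = None
    trend_p: Optional[float] = None


def quantile_odds_ratios(labels: np.ndarray, status: np.ndarray,
                         covariates: Optional[pd.DataFrame] = None) -> StrataResult:
    """Logistic regression of status on quantile indicators (Q1 reference).

    Appends the Cochran–Armitage trend test over per-quantile case counts.
    Quantiles containing a single outcome class are flagged unstable (NaN OR).
    """
    labels = np.asarray(labels)
    y = np.asarray(status, float)
    qs = np.sort(np.unique(labels))
    counts = pd.Series(y).groupby(labels).agg(["size", "sum"])
    if (counts["size"] == 0).any():
        raise ValueError("empty quantile")

    X = pd.DataFrame({f"q{k}": (labels == k).astype(float) for k in qs[1:]})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True).astype(float)], axis=1)
    X = sm.add_constant(X)
    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    ci = fit.conf_int()

    rows = [dict(quantile=int(qs[0]), n=int(counts.loc[qs[0], "size"]),
                 cases=int(counts.loc[qs[0], "sum"]),
                 case_fraction=float(counts.loc[qs[0], "sum"] / counts.loc[qs[0], "size"]),
                 odds_ratio=1.0, ci_low=1.0, ci_high=1.0, p=np.nan)]
    for k in qs[1:]:
        name = f"q{k}"
        unstable = y[labels == k].min() == y[labels == k].max()
        rows.append(dict(
            quantile=int(k), n=int(counts.loc[k, "size"]), cases=int(counts.loc[k, "sum"]),
            case_fraction=float(counts.loc[k, "sum"] / counts.loc[k, "size"]),
            odds_ratio=np.nan if unstable else float(np.exp(fit.params[name])),
            ci_low=np.nan if unstable else float(np.exp(ci.loc[name, 0])),
            ci_high=np.nan if unstable else float(np.exp(ci.loc[name, 1])),
            p=np.nan if unstable else float(fit.pvalues[name]),
        ))
    table = pd.DataFrame(rows)
    tz, tp = cochran_armitage_trend(table["n"].to_list(), table["cases"].to_list())
    return StrataResult(labels=labels, table=table, trend_z=tz, trend_p=tp)


def cochran_armitage_trend(n_per_group: Sequence[int], cases_per_group: Sequence[int],
                           scores: Optional[Sequence[float]] = None) -> tuple[float, float]:
    """Cochran–Armitage test for trend in proportions across ordered groups.

    T = Σ x_k (r_k − n_k p̄), Var(T) = p̄(1−p̄)[Σ n_k x_k² − (Σ n_k x_k)²/N];
    returns (z, two-sided normal p). Scores default to 1..g.
    """
    n = np.asarray(n_per_group, float)
    r = np.asarray(cases_per_group, float)
    if len(n) < 2:
        raise ValueError("need at least 2 groups")
    if (r > n).any() or (r < 0).any():
        raise ValueError("case counts must lie in [0, n]")
    x = np.arange(1, len(n) + 1, dtype=float) if scores is None else np.asarray(scores, float)
    N = n.sum()
    pbar = r.sum() / N
    if pbar in (0.0, 1.0):
        raise ValueError("degenerate table: all cases or all controls")
    t = float((x * (r - n * pbar)).sum())
    var = pbar * (1 - pbar) * ((n * x ** 2).sum() - (n * x).sum() ** 2 / N)
    if var <= 0:
        raise ValueError("zero trend variance (constant scores)")
    z = t / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def quantile_trait_summary(labels: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Per-quantile median/IQR/mean plus a Spearman gradient diagnostic.

    The Spearman correlation of quantile index with the trait is attached as
    frame attribute ``spearman_rho`` / ``spearman_p``; it is 0 when the trait
    is constant.
    """
    labels = np.asarray(labels)
    y = np.asarray(y, float)
    rows = []
    for k in np.sort(np.unique(labels)):
        vals = y[labels == k]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(dict(quantile=int(k), n=len(vals), median=float(med),
                         iqr_low=float(q1), iqr_high=float(q3), mean=float(vals.mean())))
    out = pd.DataFrame(rows)
    if np.ptp(y) == 0:
        rho, p = 0.0, 1.0
    else:
        rho, p = stats.spearmanr(labels, y)
    out.attrs["spearman_rho"] = float(rho)
    out.attrs["spearman_p"] = float(p)
    return out
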