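"""Follow-up validation: survival by PRS quartile and trait trajectories.

Kaplan–Meier curves and Cox proportional-hazards models (Efron tie handling,
lowest quartile as reference) for incident disease, and linear mixed models
with per-sample random intercepts and time slopes for repeated continuous
trait measurements across PRS quintiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

logger = logging.getLogger(__name__)


def kaplan_meier(time: np.ndarray, event: np.ndarray,
                 groups: Optional[np.ndarray] = None) -> dict[object, pd.DataFrame]:
    """Product-limit survival curves, one per group.

    Censored observations leave the risk set at their time without a drop.
    Returns, per group, a frame with columns time, survival, at_risk.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if (time < 0).any():
        raise ValueError("negative times")
    groups = np.zeros(len(time), dtype=int) if groups is None else np.asarray(groups)
    curves = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        km = KaplanMeierFitter()
        km.fit(time[mask], event[mask])
        tbl = km.event_table
        curves[g] = pd.DataFrame({
            "time": km.survival_function_.index.to_numpy(),
            "survival": km.survival_function_["KM_estimate"].to_numpy(),
            "at_risk": tbl["at_risk"].reindex(km.survival_function_.index).to_numpy(),
        })
    return curves


@dataclass
class SurvivalResult:
    """Hazard ratios vs the lowest quantile plus the KM curves behind them."""

    hr_table: pd.DataFrame  # quantile, hazard_ratio, ci_low, ci_high, p, n, events
    curves: dict[object, pd.DataFrame]


def cox_by_quantile(time: np.ndarray, event: np.ndarray, labels: np.ndarray,
                    covariates: Optional[pd.DataFrame] = None) -> SurvivalResult:
    """Cox model of event hazard on quantile indicators (Q1 reference).

    Partial likelihood with Efron handling of tied event times; Wald CIs.
    Quantiles with no events are flagged (NaN hazard ratio).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    labels = np.asarray(labels)
    if event.sum() == 0:
        raise ValueError("no events")
    qs = np.sort(np.unique(labels))
    df = pd.DataFrame({"time": time, "event": event})
    for k in qs[1:]:
        df[f"q{k}"] = (labels == k).astype(float)
    if covariates is not None:
        df = pd.concat([df, covariates.reset_index(drop=True).astype(float)], axis=1)

    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")  # lifelines uses Efron ties
    if event[labels == qs[0]].sum() == 0:
        logger.warning("no events in reference quantile; hazard ratios unstable")

    summary = cph.summary
    rows = [dict(quantile=int(qs[0]), hazard_ratio=1.0, ci_low=1.0, ci_high=1.0,
                 p=np.nan, n=int((labels == qs[0]).sum()),
                 events=int(event[labels == qs[0]].sum()))]
    for k in qs[1:]:
        name = f"q{k}"
        no_events = event[labels == k].sum() == 0
        rows.append(dict(
            quantile=int(k),
            hazard_ratio=np.nan if no_events else float(np.exp(summary.loc[name, "coef"])),
            ci_low=np.nan if no_events else float(np.exp(summary.loc[name, "coef lower 95%"])),
            ci_high=np.nan if no_events else float(np.exp(summary.loc[name, "coef upper 95%"])),
            p=np.nan if no_events else float(summary.loc[name, "p"]),
            n=int((labels == k).sum()), events=int(event[labels == k].sum()),
        ))
    curves = kaplan_meier(time, event, labels)
    return SurvivalResult(hr_table=pd.DataFrame(rows), curves=curves)


@dataclass
class TrajectoryResult:
    """Mixed-model fixed effects and predicted quintile trajectories."""

    fixed_effects: pd.DataFrame  # term, estimate, ci_low, ci_high, p
    predictions: pd.DataFrame  # quintile, year, predicted, ci_low, ci_high
    random_slope: bool  # False when the fit fell back to intercept-only


def lmm_trajectories(visits: pd.DataFrame, quintiles: pd.Series,
                     covariates: Optional[pd.DataFrame] = None,
                     outcome: str = "y", years: Sequence[float] = tuple(range(7)),
                     ) -> TrajectoryResult:
    """Fit trait ~ quintile + time + quintile×time + covariates with random
    intercepts and time slopes per sample (REML).

    ``visits`` is long (sample_id, visit_time, <outcome>); ``quintiles`` and
    ``covariates`` are per-sample (indexed by sample id). A singular
    random-effects covariance triggers a random-intercept-only refit with a
    warning. Predicted quintile means are evaluated at ``years`` with
    covariates fixed at their cohort means; CIs use the fixed-effect
    covariance only.
    """
    data = visits[["sample_id", "visit_time", outcome]].dropna().copy()
    data["quintile"] = data["sample_id"].map(quintiles).astype(int)
    cov_cols: list[str] = []
    if covariates is not None:
        for c in covariates.columns:
            data[c] = data["sample_id"].map(covariates[c]).astype(float)
            cov_cols.append(c)
    data = data.rename(columns={"visit_time": "time", outcome: "yvar"})

    n_visits = data.groupby("sample_id").size()
    if (n_visits < 2).all():
        raise ValueError("every sample has a single visit; no trajectory to fit")

    formula = "yvar ~ C(quintile) * time"
    if cov_cols:
        formula += " + " + " + ".join(cov_cols)

    random_slope = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["sample_id"], re_formula="~time")
        try:
            fit = model.fit(reml=True)
            cov_re = np.asarray(fit.cov_re)
            if not np.all(np.linalg.eigvalsh(cov_re) > 1e-10):
                raise np.linalg.LinAlgError("singular random-effects covariance")
        except (np.linalg.LinAlgError, ValueError):
            random_slope = False
            logger.warning("random-slope covariance singular; refitting with "
                           "random intercepts only")
            model = smf.mixedlm(formula, data, groups=data["sample_id"])
            fit = model.fit(reml=True)

    fe_names = list(fit.fe_params.index)
    fe = fit.fe_params
    fe_cov = fit.cov_params().loc[fe_names, fe_names]
    se = np.sqrt(np.diag(fe_cov))
    zcrit = stats.norm.ppf(0.975)
    fixed = pd.DataFrame({
        "term": fe_names,
        "estimate": fe.to_numpy(),
        "ci_low": fe.to_numpy() - zcrit * se,
        "ci_high": fe.to_numpy() + zcrit * se,
        "p": fit.pvalues[fe_names].to_numpy(),
    })

    cov_means = {c: float(data[c].mean()) for c in cov_cols}
    rows = []
    for q in sorted(data["quintile"].unique()):
        for t in years:
            x = np.zeros(len(fe_names))
            for idx, name in enumerate(fe_names):
                if name == "Intercept":
                    x[idx] = 1.0
                elif name == "time":
                    x[idx] = t
                elif name == f"C(quintile)[T.{q}]":
                    x[idx] = 1.0
                elif name == f"C(quintile)[T.{q}]:time":
                    x[idx] = t
                elif name in cov_means:
                    x[idx] = cov_means[name]
            pred = float(x @ fe.to_numpy())
            var = float(x @ fe_cov.to_numpy() @ x)
            half = zcrit * np.sqrt(max(var, 0.0))
            rows.append(dict(quintile=int(q), year=float(t), predicted=pred,
                             ci_low=pred - half, ci_high=pred + half))
    return TrajectoryResult(fixed_effects=fixed, predictions=pd.DataFrame(rows),
                            random_slope=random_slope)
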