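"""End-to-end pipeline: load → QC → harmonize → gate → score → evaluate →
stratify → follow-up, with deterministic, checksummed outputs.

Scoring files are matched to phenotypes via their reported trait label: a
``status_<trait>`` column in the baseline table marks the trait binary,
otherwise a column named after the trait is treated as continuous.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import evaluate, harmonize, io_formats, longitudinal, scoring, stratify

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    scoring_dir: str
    vcf_path: str
    baseline_path: str
    visits_path: Optional[str] = None
    survival_path: Optional[str] = None
    out_dir: str = "pipeline_out"
    info_min: float = 0.8  # 0.3 is the permissive alternative threshold
    retention_min: float = 0.5
    fdr_alpha: float = 0.05
    kinship_threshold: float = 0.086
    trait_prevalence: dict[str, float] = field(default_factory=lambda: {
        "t2d": 0.102, "cvd": 0.057})
    binary_quantiles: int = 4
    continuous_quantiles: int = 10
    longitudinal_quantiles: int = 5
    lipid_traits: tuple[str, str] = ("tc", "ldl")
    missing_policy: str = "mean_dosage"
    seed: int = 0

    def __post_init__(self):
        for name, val in (("info_min", self.info_min), ("retention_min", self.retention_min),
                          ("fdr_alpha", self.fdr_alpha)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} out of range: {val}")
        for t, k in self.trait_prevalence.items():
            if not 0.0 < k < 1.0:
                raise ValueError(f"prevalence for {t} out of (0, 1): {k}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns a manifest dict (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        _write(df, path)
        written.append(path)

    try:
        stage = "load_qc"
        g = io_formats.read_genotypes(cfg.vcf_path)
        g, qc_report = io_formats.apply_variant_qc(g, info_min=cfg.info_min)
        emit(qc_report.to_frame(), "qc_report.tsv")
        pheno = io_formats.read_phenotypes(cfg.baseline_path, visits_path=cfg.visits_path,
                                           survival_path=cfg.survival_path)
        shared = [s for s in g.sample_ids if s in pheno.baseline.index]
        g = g.subset_samples(np.isin(g.sample_ids, shared))
        base = pheno.baseline.loc[shared].copy()
        tc_col, ldl_col = cfg.lipid_traits
        if "lipid_medication" in base.columns and tc_col in base.columns:
            base[tc_col], base[ldl_col] = io_formats.adjust_lipids_for_medication(
                base[tc_col], base[ldl_col], base["lipid_medication"])
        covars = base[io_formats.COVARIATE_COLUMNS].astype(float).reset_index(drop=True)
        manifest["stages"][stage] = {"n_samples": len(shared), "n_variants": g.n_variants}

        stage = "harmonize"
        score_paths = sorted(Path(cfg.scoring_dir).glob("*.txt"))
        if not score_paths:
            raise FileNotFoundError(f"no scoring files in {cfg.scoring_dir}")
        gate_rows, kept = [], []
        for path in score_paths:
            score = io_formats.parse_scoring_file(path)
            result = harmonize.match_variants(score, g)
            sr = harmonize.simple_retention(result)
            wr = harmonize.weighted_retention(result, score)
            emit(result.to_frame(score), f"harmonization_{score.pgs_id}.tsv")
            passed = sr >= cfg.retention_min
            gate_rows.append(dict(pgs_id=score.pgs_id, trait=score.trait_label,
                                  n_variants=len(score), n_matched=result.n_matched,
                                  simple_retention=sr, weighted_retention=wr,
                                  passed_gate=passed))
            if passed:
                kept.append((score, result, sr, wr))
        emit(pd.DataFrame(gate_rows), "retention_gate.tsv")
        manifest["stages"][stage] = {"n_scores": len(score_paths), "n_passed": len(kept)}
        if not kept:
            raise ValueError(f"no score reached retention ≥ {cfg.retention_min}")

        stage = "score"
        vectors = {}
        score_frames = []
        for score, result, sr, wr in kept:
            vec = scoring.compute_prs(g, result, score, missing_policy=cfg.missing_policy)
            vectors[score.pgs_id] = (vec, score, sr, wr)
            score_frames.append(vec.to_frame())
        emit(pd.concat(score_frames, ignore_index=True), "scores.tsv")

        stage = "evaluate"
        results: list[evaluate.EvalResult] = []
        for pgs_id, (vec, score, sr, wr) in vectors.items():
            trait = score.trait_label
            if f"status_{trait}" in base.columns:
                res = evaluate.fit_binary_model(
                    vec, base[f"status_{trait}"].to_numpy(), covars, trait=trait,
                    prevalence=cfg.trait_prevalence.get(trait))
            elif trait in base.columns:
                res = evaluate.fit_continuous_model(
                    vec, base[trait].to_numpy(), covars, trait=trait)
            else:
                logger.warning("%s: trait %r absent from phenotypes; skipped", pgs_id, trait)
                continue
            res.simple_retention, res.weighted_retention = sr, wr
            results.append(res)
        if not results:
            raise ValueError("no score could be evaluated against the phenotypes")
        qs = evaluate.bh_fdr([r.p for r in results], [r.trait for r in results])
        for r, q in zip(results, qs):
            r.fdr_q = float(q)
        eval_table = pd.DataFrame([dataclasses.asdict(r) for r in results])
        emit(eval_table, "evaluation.tsv")

        best: dict[str, str] = {}
        for trait in sorted({r.trait for r in results}):
            choice = evaluate.select_best_prs([r for r in results if r.trait == trait],
                                              alpha=cfg.fdr_alpha)
            if choice is not None:
                best[trait] = choice
        manifest["stages"][stage] = {"n_evaluated": len(results), "best": best}

        stage = "stratify"
        for trait, pgs_id in best.items():
            vec = vectors[pgs_id][0]
            if f"status_{trait}" in base.columns:
                labels = stratify.assign_quantiles(vec, cfg.binary_quantiles)
                strata = stratify.quantile_odds_ratios(
                    labels, base[f"status_{trait}"].to_numpy(), covars)
                table = strata.table.copy()
                table["trend_z"], table["trend_p"] = strata.trend_z, strata.trend_p
            else:
                labels = stratify.assign_quantiles(vec, cfg.continuous_quantiles)
                table = stratify.quantile_trait_summary(labels, base[trait].to_numpy())
                table["spearman_rho"] = table.attrs["spearman_rho"]
            emit(table, f"strata_{trait}.tsv")

        stage = "longitudinal"
        if pheno.survival is not None and len(pheno.survival):
            for trait, pgs_id in best.items():
                surv = pheno.survival[pheno.survival["trait"] == trait]
                surv = surv[surv["sample_id"].isin(base.index)]
                if not len(surv) or surv["event"].sum() == 0:
                    continue
                vec = vectors[pgs_id][0]
                zmap = pd.Series(vec.z, index=vec.sample_ids)
                labels_all = pd.Series(
                    stratify.assign_quantiles(vec, cfg.binary_quantiles),
                    index=vec.sample_ids)
                idx = surv["sample_id"].to_numpy()
                res = longitudinal.cox_by_quantile(
                    surv["time"].to_numpy(), surv["event"].to_numpy(),
                    labels_all.loc[idx].to_numpy(),
                    covars.set_axis(base.index).loc[idx].reset_index(drop=True))
                emit(res.hr_table, f"survival_{trait}.tsv")
        if cfg.visits_path is not None:
            multi = pheno.visits.groupby("sample_id").size().max() if len(pheno.visits) else 0
            for trait, pgs_id in best.items():
                if trait not in pheno.visits.columns or multi < 2:
                    continue
                vec = vectors[pgs_id][0]
                quint = pd.Series(
                    stratify.assign_quantiles(vec, cfg.longitudinal_quantiles),
                    index=vec.sample_ids)
                traj = longitudinal.lmm_trajectories(
                    pheno.visits[pheno.visits["sample_id"].isin(base.index)],
                    quint, base[io_formats.COVARIATE_COLUMNS], outcome=trait)
                emit(traj.predictions, f"trajectories_{trait}.tsv")
                emit(traj.fixed_effects, f"trajectory_effects_{trait}.tsv")

        stage = "retention_correlation"
        corr_rows = []
        for trait in sorted({r.trait for r in results}):
            trs = [r for r in results if r.trait == trait]
            if len(trs) < 3:
                continue
            metric = [(r.auc if r.model_kind == "binary" else r.incremental_r2) for r in trs]
            for kind, ret in (("simple", [r.simple_retention for r in trs]),
                              ("weighted", [r.weighted_retention for r in trs])):
                try:
                    r2, p = harmonize.retention_performance_correlation(
                        list(zip(ret, metric)))
                except ValueError:
                    continue
                corr_rows.append(dict(trait=trait, retention_kind=kind, r_squared=r2, p=p))
        if corr_rows:
            emit(pd.DataFrame(corr_rows), "retention_correlation.tsv")
    except StageError:
        raise
    except Exception as exc:
        for path in written:  # remove partial outputs so reruns start clean
            path.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc

    manifest["outputs"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(written)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
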