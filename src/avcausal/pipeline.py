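"""Seeded end-to-end orchestration of the synthetic analysis pipeline.

``run_pipeline`` executes: simulate both experiments -> extract sequence
features -> fit psychometric functions per cell -> cue-combination
predictions and classification -> random-effects model selection ->
causal-judgement GLMM with integration boundary -> cross-correlogram
difference analysis -> group-level splits.  Every stage draws its
randomness from a named substream of one master seed, so any stage can be
re-run in isolation and the whole bundle is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as avio
from .synthetic import (ObserverSpec, CausalObserverSpec,
                        simulate_exp1_dataset, simulate_exp2_dataset)
from .psychometrics import (fit_all_cells, z_transform, split_fit_switch,
                            split_fit_duration, split_fit_causal)
from .cue_combination import predict_integration, classify_integration, \
    compare_unisensory
from .model_comparison import model_evidence, rfx_bms
from .ccg_analysis import permutation_bounds
from .glmm import (fit_causal_glmm, bootstrap_pvalues, integration_boundary,
                   feature_correlations)

log = logging.getLogger("avcausal.pipeline")


@dataclass
class PipelineConfig:
    """Everything a full synthetic run needs, serializable to JSON."""

    seed: int = 0
    out_dir: str = "avcausal_run"
    # stage toggles
    run_exp1: bool = True
    run_exp2: bool = True
    run_ccg: bool = True
    run_splits: bool = True
    # exp 1 design
    n_subjects_exp1: int = 6
    n_per_cell: int = 10
    sigma_A: float = 2.0
    sigma_V: float = 2.5
    strategy: str = "optimal"
    counting_weight: float = 0.0
    # exp 2 design
    n_subjects_exp2: int = 6
    sessions: int = 1
    n_conflict_per_rate: int = 25
    n_noconflict_per_rate: int = 5
    # fit parameters
    mcmc_samples: int = 2000
    mcmc_burn: int = 2000
    n_perm: int = 1000
    n_boot: int = 200
    boundary_from: str = "reduced"  # reduced (intercept+offset) model

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _stage_seed(master: int, name: str) -> int:
    """Stable per-stage substream seed derived from the master seed."""
    h = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; write artifacts under ``config.out_dir``.

    Returns a report dict (also written as ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"config_hash": config.config_hash(), "seed": config.seed,
              "stages": {}}
    (out / "config.json").write_text(config.to_json())

    mcmc_kw = dict(n_samples=config.mcmc_samples, n_burn=config.mcmc_burn)
    stage = "simulate-exp1"
    try:
        if config.run_exp1:
            log.info("stage %s", stage)
            spec = ObserverSpec(sigma_A=config.sigma_A,
                                sigma_V=config.sigma_V,
                                strategy=config.strategy,
                                counting_weight=config.counting_weight)
            observers = {f"s{i:02d}": spec
                         for i in range(config.n_subjects_exp1)}
            trials = simulate_exp1_dataset(
                observers, n_per_cell=config.n_per_cell,
                seed=_stage_seed(config.seed, stage))
            avio.write_trial_table(trials, out / "exp1_trials.csv")
            report["stages"][stage] = {"n_trials": len(trials)}

            stage = "fit-psychometric"
            fits = fit_all_cells(trials,
                                 seed=_stage_seed(config.seed, stage),
                                 **mcmc_kw)
            avio.write_json({"|".join(map(str, k)): v.to_json_dict()
                             for k, v in fits.items()},
                            out / "psychometric_fits.json")
            report["stages"][stage] = {"n_cells": len(fits)}

            stage = "cue-combination"
            rng = np.random.default_rng(_stage_seed(config.seed, stage))
            class_rows = []
            sigA, sigV = [], []
            log_ev = []
            for subj in sorted({k[0] for k in fits}):
                for cond in sorted({k[1] for k in fits
                                    if k[0] == subj}):
                    postA = fits[(subj, cond, "A")]
                    postV = fits[(subj, cond, "V")]
                    postAV = fits[(subj, cond, "AV")]
                    pred = predict_integration(postA, postV, rng=rng)
                    label = classify_integration(postAV, pred)
                    class_rows.append((subj, cond, label,
                                       postAV.sigma_hat,
                                       pred.sigma_opt_post.point,
                                       pred.sigma_best_post.point))
                    sigA.append(postA.sigma_hat)
                    sigV.append(postV.sigma_hat)
                    av = trials[(trials.subject == subj)
                                & (trials.condition == cond)
                                & (trials.modality == "AV")]
                    x = av["rate_diff"].to_numpy()
                    y = av["response_faster"].to_numpy()
                    log_ev.append([
                        model_evidence(y, x, pred.mu_best,
                                       pred.sigma_best_post.point),
                        model_evidence(y, x, 0.0,
                                       pred.sigma_opt_post.point),
                    ])
            class_df = pd.DataFrame(class_rows, columns=[
                "subject", "condition", "classification", "sigma_AV",
                "sigma_opt", "sigma_best"])
            class_df.to_csv(out / "integration_classification.csv",
                            index=False)
            t, df_, p = compare_unisensory(sigA, sigV)
            report["stages"][stage] = {
                "classification_counts":
                    class_df["classification"].value_counts().to_dict(),
                "unisensory_paired_t": {"t": t, "df": df_, "p": p},
            }

            stage = "model-selection"
            bms = rfx_bms(np.asarray(log_ev))
            avio.write_json(bms.to_json_dict(), out / "bms.json")
            report["stages"][stage] = {
                "exceedance_best_cue": bms.exceedance[0],
                "exceedance_optimal": bms.exceedance[1]}

            if config.run_splits:
                stage = "group-splits"
                ztr = z_transform(trials, fits)
                s_stay, s_switch = split_fit_switch(
                    ztr, seed=_stage_seed(config.seed, stage), **mcmc_kw)
                dur = split_fit_duration(
                    ztr, seed=_stage_seed(config.seed, stage + "-dur"),
                    **mcmc_kw)
                slope = float(dur["regression"].params[1])
                report["stages"][stage] = {
                    "sigma_stay": s_stay.sigma_hat,
                    "sigma_switch": s_switch.sigma_hat,
                    "pse_vs_jitter_slope_per_ms": slope,
                    "sigma_short": dur["short"].sigma_hat,
                    "sigma_long": dur["long"].sigma_hat,
                }
                dur["pse_by_jitter"].to_csv(out / "pse_by_jitter.csv",
                                            index=False)
    except Exception as e:  # noqa: BLE001 - stage-tagged abort
        _finish(out, report)
        raise StageError(stage, e) from e

    stage = "simulate-exp2"
    try:
        if config.run_exp2:
            log.info("stage %s", stage)
            pairs, table = simulate_exp2_dataset(
                CausalObserverSpec(),
                n_subjects=config.n_subjects_exp2,
                sessions=config.sessions,
                seed=_stage_seed(config.seed, stage),
                n_conflict=config.n_conflict_per_rate,
                n_noconflict=config.n_noconflict_per_rate)
            avio.write_causal_table(table, out / "exp2_trials.csv")
            report["stages"][stage] = {"n_trials": len(table)}

            stage = "causal-glmm"
            conflict = table[table.temporal_conflict].reset_index(drop=True)
            full = fit_causal_glmm(conflict)
            full = bootstrap_pvalues(full, conflict, n_boot=config.n_boot,
                                     seed=_stage_seed(config.seed, stage))
            avio.write_glmm_fit(full, out / "glmm_full.json")
            reduced = fit_causal_glmm(conflict, include_sync=False,
                                      include_interaction=False)
            avio.write_glmm_fit(reduced, out / "glmm_reduced.json")
            src = reduced if config.boundary_from == "reduced" else full
            boundary = integration_boundary(src)
            corr = feature_correlations(conflict)
            corr.to_csv(out / "cue_correlations.csv", index=False)
            report["stages"][stage] = {
                "beta": full.beta, "bootstrap_p": full.bootstrap_p,
                "integration_boundary_ms": boundary,
                "cue_correlations": corr.to_dict("records"),
            }

            if config.run_ccg:
                stage = "ccg"
                mask = table["temporal_conflict"].to_numpy()
                cpairs = [p for p, m in zip(pairs, mask) if m]
                resp = conflict["response_common"].to_numpy()
                res = permutation_bounds(
                    cpairs, resp, n_perm=config.n_perm,
                    seed=_stage_seed(config.seed, stage))
                avio.write_ccg_table(res, out / "ccg_difference.csv")
                runs = res.significant_runs()
                report["stages"][stage] = {
                    "n_significant_lags": int(np.sum(res.significant != 0)),
                    "positive_run_lengths": runs[1],
                    "negative_run_lengths": runs[-1],
                }

            if config.run_splits and config.run_exp1:
                stage = "causal-split"
                # reuse the exp 1 z-scored AV temporal-conflict trials with
                # per-trial offsets sampled from the exp 2 feature pool
                rng = np.random.default_rng(
                    _stage_seed(config.seed, stage))
                ztr = z_transform(trials, fits)
                av = ztr[(ztr.modality == "AV")
                         & (ztr.condition == "temporal")]
                offs = rng.choice(
                    conflict["max_offset_ms"].to_numpy(), size=len(av))
                common_fit, sep_fit = split_fit_causal(
                    av, offs, boundary_ms=boundary,
                    seed=_stage_seed(config.seed, stage + "-fit"),
                    **mcmc_kw)
                report["stages"][stage] = {
                    "sigma_common": common_fit.sigma_hat,
                    "sigma_separate": sep_fit.sigma_hat,
                    "n_common": int(np.sum(offs <= boundary)),
                    "n_separate": int(np.sum(offs > boundary)),
                }
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        _finish(out, report)
        raise StageError(stage, e) from e

    _finish(out, report)
    return report


def _finish(out: Path, report: dict):
    avio.write_json(report, out / "report.json")
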