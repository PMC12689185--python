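"""End-to-end orchestration: data → doses → contrasts → pairwise → NMA →
dose-response → classification, with a deterministic artifact layout.

Artifacts written under ``RunConfig.out_dir``:

    study.csv, truth.json (generator runs only)
    doses.csv, contrasts.csv, adherence.csv
    pairwise.csv, egger.json, funnel.csv
    league.csv, sucra.csv, nodesplit.csv, dic.json, basic_params.csv,
    prediction_intervals.csv, adherence_or.csv
    curves/<stratum>.csv, curves/modality_<m>.csv, thresholds.json,
    dose_table.csv, modality_table.csv, intensity.json
    classification.csv, run.log
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .data import network_geometry, read_study_table, write_study_table
from .dose import classify_bmi, classify_intensity, dose_to_minutes, weekly_dose
from .dose_response import (
    BMI_REPRESENTATIVE,
    McmcSpec,
    find_thresholds,
    fit_dose_response,
    fit_intensity_model,
    observations_from_arms,
    per_modality_curves,
    predict_curve,
    predict_intensity,
)
from .effects import adherence_table, build_contrasts
from .framework import classify_interventions
from .nma import (
    NmaSpec,
    adherence_network,
    classify_tau2,
    fit_consistency,
    fit_ume,
    league_table,
    node_split,
    prediction_interval,
    splittable_comparisons,
    sucra,
)
from .pairwise import egger_test, funnel_data, pool_all_comparisons
from .simulate import GeneratorConfig, generate_network

__all__ = ["PipelineError", "run_all"]

log = logging.getLogger("exdose")


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are kept on disk."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - report stage then re-raise
                raise PipelineError(name, e) from e
            log.info("stage %s done in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


@_stage("data")
def _load_data(cfg: RunConfig, out: Path):
    if cfg.input_csv:
        arms, metas = read_study_table(cfg.input_csv)
        ledger = None
    else:
        gen = GeneratorConfig(**cfg.generator)
        arms, metas, ledger = generate_network(gen, seed=cfg.seed)
        write_study_table(arms, metas, out / "study.csv")
        ledger.to_json(out / "truth.json")
    geometry = network_geometry(arms)
    if not geometry.connected:
        raise ValueError("disconnected treatment network")
    return arms, metas, ledger


@_stage("dose")
def _dose_stage(cfg: RunConfig, arms, metas, out: Path) -> pd.DataFrame:
    meta_by_id = {m.study_id: m for m in metas}
    rows = []
    for arm in arms:
        dose = 0.0 if arm.prescription is None else weekly_dose(arm.prescription)
        mets = 0.0
        if arm.prescription is not None:
            minutes = sum(p.minutes for p in arm.prescription.phases)
            mets = (
                sum(p.mets * p.minutes for p in arm.prescription.phases) / minutes
                if minutes
                else 0.0
            )
        meta = meta_by_id.get(arm.study_id)
        rows.append(
            {
                "study_id": arm.study_id,
                "modality": arm.modality,
                "dose_mets_min_wk": dose,
                "intensity_class": classify_intensity(mets) if mets > 0 else "",
                "bmi_class": classify_bmi(meta.baseline_bmi)
                if meta and meta.baseline_bmi
                else "",
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "doses.csv", index=False)
    return frame


@_stage("prepare")
def _prepare_stage(cfg: RunConfig, arms, out: Path):
    by_study: dict[str, list] = {}
    for a in arms:
        by_study.setdefault(a.study_id, []).append(a)
    contrasts = []
    for sid in sorted(by_study):
        contrasts.extend(build_contrasts(by_study[sid], r=cfg.r))
    pd.DataFrame(
        [
            {
                "study_id": c.study_id, "treatment": c.treatment,
                "reference": c.reference, "md": c.md, "se": c.se,
                "n_t": c.n_t, "n_r": c.n_r, "ref_var": c.ref_var,
            }
            for c in contrasts
        ]
    ).to_csv(out / "contrasts.csv", index=False)
    adherence = adherence_table(arms)
    adherence.to_csv(out / "adherence.csv", index=False)
    return contrasts, adherence


@_stage("pairwise")
def _pairwise_stage(cfg: RunConfig, contrasts, out: Path):
    pooled = pool_all_comparisons(contrasts)
    pd.DataFrame(
        [
            {
                "comparison": f"{c[0]} vs {c[1]}", "md": p.md,
                "ci_low": p.ci_low, "ci_high": p.ci_high,
                "tau2": p.tau2, "k": p.k,
            }
            for c, p in pooled.items()
        ]
    ).to_csv(out / "pairwise.csv", index=False)
    vs_uc = [c for c in contrasts if c.reference == "UC"]
    funnel_data(vs_uc).to_csv(out / "funnel.csv", index=False)
    egger = egger_test(vs_uc)
    (out / "egger.json").write_text(
        json.dumps(
            {
                "intercept": egger.intercept,
                "se_intercept": egger.se_intercept,
                "p_value": egger.p_value,
                "k": egger.k,
            },
            indent=2,
        )
    )
    return pooled, egger


@_stage("nma")
def _nma_stage(cfg: RunConfig, contrasts, adherence, out: Path):
    spec = NmaSpec(
        chains=cfg.chains, draws=cfg.draws, warmup=cfg.warmup, seed=cfg.seed
    )
    post = fit_consistency(contrasts, spec)
    ume = fit_ume(contrasts, spec)
    post.basic_summary().to_csv(out / "basic_params.csv", index=False)
    league_table(post).to_frame().to_csv(out / "league.csv")
    scores = sucra(post)
    scores.to_frame().to_csv(out / "sucra.csv")
    prediction_interval(post, seed=cfg.seed).to_csv(
        out / "prediction_intervals.csv", index=False
    )
    rows = []
    for comp in splittable_comparisons(contrasts):
        ns = node_split(contrasts, spec, comp)
        rows.append(
            {
                "comparison": f"{comp[0]} vs {comp[1]}",
                "direct": float(np.mean(ns.direct)),
                "indirect": float(np.mean(ns.indirect)),
                "difference": float(np.mean(ns.difference)),
                "p_value": ns.p_value,
            }
        )
    pd.DataFrame(rows, columns=["comparison", "direct", "indirect",
                                "difference", "p_value"]).to_csv(
        out / "nodesplit.csv", index=False
    )
    tau2 = float(np.mean(post.tau_flat() ** 2))
    (out / "dic.json").write_text(
        json.dumps(
            {
                "consistency": {"dic": post.dic, "pD": post.pD,
                                "mean_deviance": post.mean_deviance},
                "ume": {"dic": ume.dic, "pD": ume.pD,
                        "mean_deviance": ume.mean_deviance},
                "tau2_posterior_mean": tau2,
                "tau2_class": classify_tau2(tau2),
            },
            indent=2,
        )
    )
    if len(adherence):
        adherence_network(adherence, spec).to_csv(
            out / "adherence_or.csv", index=False
        )
    return post, ume, scores


@_stage("doseresponse")
def _dose_response_stage(cfg: RunConfig, arms, metas, out: Path):
    mcmc = McmcSpec(
        chains=cfg.chains, draws=cfg.draws, warmup=cfg.warmup, seed=cfg.seed
    )
    obs = observations_from_arms(arms, metas, r=cfg.r)
    post = fit_dose_response(obs, mcmc=mcmc)
    grid = np.arange(0.0, cfg.grid_max + 1, cfg.grid_step)
    curves_dir = out / "curves"
    curves_dir.mkdir(exist_ok=True)
    thresholds = {}
    dose_rows = []
    for stratum in ("overall", *BMI_REPRESENTATIVE):
        bmi = None if stratum == "overall" else stratum
        curve = predict_curve(post, grid=grid, bmi=bmi, stratum=stratum)
        curve.frame.to_csv(curves_dir / f"{stratum}.csv", index=False)
        th = find_thresholds(curve, mcid=cfg.mcid)
        thresholds[stratum] = {
            "optimal": th.optimal,
            "minimal_statistical": th.minimal_statistical,
            "minimal_clinical": th.minimal_clinical,
        }
        for label, dose in (("minimal", th.minimal_clinical), ("optimal", th.optimal)):
            if dose is None:
                continue
            i = int(np.where(grid == dose)[0][0])
            dose_rows.append(
                {
                    "stratum": stratum, "dose_kind": label, "dose": dose,
                    "mcfb": curve.frame["mean"].iloc[i],
                    "cri_low": curve.frame["cri_low"].iloc[i],
                    "cri_high": curve.frame["cri_high"].iloc[i],
                    "min_per_week_light": dose_to_minutes(dose, 2.25),
                    "min_per_week_moderate": dose_to_minutes(dose, 4.5),
                    "min_per_week_vigorous": dose_to_minutes(dose, 6.0),
                }
            )
    pd.DataFrame(dose_rows).to_csv(out / "dose_table.csv", index=False)
    (out / "thresholds.json").write_text(json.dumps(thresholds, indent=2))
    # per-modality curves and Table-5-shaped summary
    per_mod = per_modality_curves(obs, mcmc=mcmc, grid=grid, mcid=cfg.mcid)
    mod_rows = []
    for m, res in per_mod.items():
        res["curve"].frame.to_csv(curves_dir / f"modality_{m}.csv", index=False)
        th = res["thresholds"]
        frame = res["curve"].frame
        row = {"modality": m, "optimal": th.optimal,
               "minimal_clinical": th.minimal_clinical}
        for kind, dose in (("minimal", th.minimal_clinical), ("optimal", th.optimal)):
            if dose is None:
                continue
            i = int(np.where(grid == dose)[0][0])
            row[f"{kind}_mcfb"] = frame["mean"].iloc[i]
            row[f"{kind}_cri_low"] = frame["cri_low"].iloc[i]
            row[f"{kind}_cri_high"] = frame["cri_high"].iloc[i]
        mod_rows.append(row)
    pd.DataFrame(mod_rows).to_csv(out / "modality_table.csv", index=False)
    intensity = fit_intensity_model(obs, mcmc=mcmc)
    sweep = predict_intensity(intensity, duration=150.0, mcid=cfg.mcid)
    sweep["curve"].to_csv(out / "intensity_curve.csv", index=False)
    (out / "intensity.json").write_text(
        json.dumps(
            {
                "duration_min_per_week": sweep["duration"],
                "min_significant_mets": sweep["min_significant_mets"],
                "min_clinical_mets": sweep["min_clinical_mets"],
                "bands": sweep["bands"],
            },
            indent=2,
        )
    )
    return thresholds, per_mod


@_stage("classify")
def _classify_stage(cfg: RunConfig, post, scores, out: Path):
    dd = post.d_flat()
    effects = {}
    for i, t in enumerate(post.treatments):
        effects[t] = (
            float(dd[:, i].mean()),
            float(np.quantile(dd[:, i], 0.025)),
            float(np.quantile(dd[:, i], 0.975)),
        )
    table = classify_interventions(
        effects, scores.sucra, cfg.certainty, mcid=cfg.mcid
    )
    table.to_csv(out / "classification.csv", index=False)
    return table


def run_all(cfg: RunConfig) -> dict:
    """Run every stage and return the in-memory result bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    filelog = logging.FileHandler(out / "run.log", mode="w")
    filelog.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(filelog)
    try:
        log.info("exdose %s; seed=%d chains=%d draws=%d",
                 __version__, cfg.seed, cfg.chains, cfg.draws)
        arms, metas, ledger = _load_data(cfg, out)
        doses = _dose_stage(cfg, arms, metas, out)
        contrasts, adherence = _prepare_stage(cfg, arms, out)
        pooled, egger = _pairwise_stage(cfg, contrasts, out)
        post, ume, scores = _nma_stage(cfg, contrasts, adherence, out)
        thresholds, per_mod = _dose_response_stage(cfg, arms, metas, out)
        table = _classify_stage(cfg, post, scores, out)
        log.info("run complete: %s", out)
        return {
            "arms": arms,
            "metas": metas,
            "ledger": ledger,
            "doses": doses,
            "contrasts": contrasts,
            "pairwise": pooled,
            "egger": egger,
            "nma": post,
            "ume": ume,
            "sucra": scores,
            "thresholds": thresholds,
            "per_modality": per_mod,
            "classification": table,
        }
    finally:
        log.removeHandler(filelog)
        log.removeHandler(handler)
        filelog.close()
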