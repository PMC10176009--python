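"""End-to-end synthetic pipeline: design -> simulate -> fit -> recover -> analyze.

Everything is driven by one RunConfig and one seed; per-stage seeds are
spawned hierarchically so any stage is reproducible in isolation and
adding subjects does not perturb existing ones.  Every artifact is a
CSV or JSON file; the manifest records paths, checksums and stage
seeds.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import agents as ag
from . import behavior as bh
from . import fitting as ft
from . import io as pio
from . import task_design as td

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "peirs_run"
    n_subjects: int = 8
    recovery_subjects: int = 8
    em_max_iter: int = 30
    n_starts: int = 5
    experience: td.ExperienceConfig = field(default_factory=td.ExperienceConfig)
    description: td.DescriptionConfig = field(default_factory=td.DescriptionConfig)
    fit_models: tuple = ("rw", "peirs")
    conditions: tuple = ("sated", "hungry")

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("experience"), dict):
            d["experience"] = td.ExperienceConfig(**d["experience"])
        if isinstance(d.get("description"), dict):
            d["description"] = td.DescriptionConfig(**d["description"])
        for k in ("fit_models", "conditions"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


_POPS = {"sated": ag.DEFAULT_SATED, "hungry": ag.DEFAULT_HUNGRY}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and persist) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = {name: int(np.random.default_rng(seq).integers(2**31))
             for name, seq in zip(
                 ("design", "simulate", "fit", "recover", "analyze"),
                 root.spawn(5))}
    manifest: Dict = {"config": config.to_json(), "seed": config.seed,
                      "stage_seeds": seeds, "stages": {}, "artifacts": {}}

    def record(stage: str, name: str, path: Path):
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(out)), "sha256": pio.file_sha256(path)}
        manifest["stages"].setdefault(stage, []).append(name)

    # --- design -----------------------------------------------------------
    t0 = time.time()
    exp_sched = td.make_experience_schedule(config.experience, seed=seeds["design"])
    desc_sched, gambles = td.make_description_schedule(
        config.description, seed=seeds["design"])
    record("design", "experience_schedule",
           pio.write_trials(exp_sched, out / "experience_schedule.csv"))
    record("design", "description_schedule",
           pio.write_trials(desc_sched, out / "description_schedule.csv"))
    record("design", "design_sidecar", pio.write_json({
        "seed": seeds["design"],
        "stimulus_sets": pio.stimulus_sets_to_json(td.default_stimulus_sets()),
        "gambles": pio.gambles_to_json(gambles),
    }, out / "design.json"))

    # --- simulate (paired within-subject conditions) ----------------------
    base, other = (_POPS[c] for c in config.conditions)
    p_base, p_other, u_base, u_other = ag.sample_paired_conditions(
        base, other, seed=seeds["simulate"], n_subjects=config.n_subjects)
    cohorts: Dict[str, List[ag.SimulatedDataset]] = {}
    for cond, plist, offset in ((config.conditions[0], p_base, 0),
                                (config.conditions[1], p_other, 1)):
        cohorts[cond] = ag.simulate_cohort(
            _POPS[cond], seed=seeds["simulate"] + offset,
            n_subjects=config.n_subjects, config=config.experience,
            params_list=plist)
        frames = []
        for ds in cohorts[cond]:
            f = ds.trials.copy()
            f.insert(0, "subject", ds.subject)
            frames.append(f)
        record("simulate", f"trials_{cond}",
               pio.write_trials(pd.concat(frames), out / f"trials_{cond}.csv"))
        record("simulate", f"true_params_{cond}", pio.write_json(
            [pio.params_to_dict(p) for p in plist],
            out / f"true_params_{cond}.json"))

    # --- fit (per condition, per model) -----------------------------------
    fit_cfg = ft.FitConfig(n_starts=config.n_starts,
                           max_em_iter=config.em_max_iter, seed=seeds["fit"])
    fit_summary: Dict[str, Dict] = {}
    for cond in config.conditions:
        fit_summary[cond] = {}
        fits_by_model = {}
        for model in config.fit_models:
            prior, fits = ft.em_fit_population(cohorts[cond], model, fit_cfg)
            fits_by_model[model] = fits
            fit_summary[cond][model] = {
                "prior_mean": prior.mean, "prior_var": prior.var,
                "n_iter": prior.n_iter, "converged": prior.converged,
                "subjects": [{
                    "subject": f.subject, "map": f.map_unconstrained,
                    "loglik": f.loglik, "bic": f.bic,
                    "n_choice_trials": f.n_choice_trials} for f in fits],
            }
        if set(("rw", "peirs")) <= set(config.fit_models):
            cmpres = ft.compare_models(fits_by_model["rw"], fits_by_model["peirs"])
            fit_summary[cond]["comparison"] = {
                "n_prefer_peirs": cmpres.n_prefer_peirs,
                "n_subjects": cmpres.n_subjects,
                "total_bic_rw": cmpres.total_bic_rw,
                "total_bic_peirs": cmpres.total_bic_peirs,
            }
    record("fit", "fits", pio.write_json(fit_summary, out / "fits.json"))

    # --- recover ----------------------------------------------------------
    rec = ft.parameter_recovery(
        n_subjects=config.recovery_subjects, seed=seeds["recover"],
        schedule_config=config.experience,
        fit_config=ft.FitConfig(n_starts=config.n_starts,
                                max_em_iter=config.em_max_iter))
    record("recover", "recovery", pio.write_json({
        "param_names": list(rec.param_names),
        "r_matrix": rec.r_matrix,
        "diagonal": rec.diagonal,
        "max_abs_off_diagonal": rec.max_abs_off_diagonal,
        "n_subjects": rec.n_subjects,
    }, out / "recovery.json"))
    pd.DataFrame(rec.r_matrix, index=rec.param_names,
                 columns=rec.param_names).to_csv(out / "recovery_matrix.csv")
    record("recover", "recovery_matrix", out / "recovery_matrix.csv")

    # --- analyze ----------------------------------------------------------
    prefs = []
    for cond in config.conditions:
        for ds in cohorts[cond]:
            rp = bh.risk_preference_experience(
                ds.trials, ds.stimuli, subject=ds.subject, condition=cond)
            prefs.append(dataclasses.asdict(rp))
    prefs_df = pd.DataFrame(prefs)
    record("analyze", "risk_preferences",
           pio.write_trials(prefs_df, out / "risk_preferences.csv"))
    cells = np.empty((config.n_subjects, 2, 2))
    for i in range(config.n_subjects):
        for a, cond in enumerate(config.conditions):
            row = prefs_df[(prefs_df.subject == i) & (prefs_df.condition == cond)]
            cells[i, a, 0] = row.p_risky_high.iloc[0]
            cells[i, a, 1] = row.p_risky_low.iloc[0]
    anova = bh.rm_anova_2x2(cells, factor_names=("condition", "context"))
    record("analyze", "anova", pio.write_json(
        [dataclasses.asdict(a) for a in anova], out / "anova.json"))

    # --- report -----------------------------------------------------------
    report = {
        "comparison": {c: fit_summary[c].get("comparison") for c in config.conditions},
        "recovery_diagonal": rec.diagonal,
        "recovery_max_abs_off_diagonal": rec.max_abs_off_diagonal,
        "anova": [dataclasses.asdict(a) for a in anova],
        "mean_p_risky": {
            cond: {
                "high": float(prefs_df[prefs_df.condition == cond].p_risky_high.mean()),
                "low": float(prefs_df[prefs_df.condition == cond].p_risky_low.mean()),
            } for cond in config.conditions},
    }
    record("report", "report", pio.write_json(report, out / "report.json"))

    manifest["n_stages"] = len(manifest["stages"])
    pio.write_json(manifest, out / "manifest.json")
    return manifest
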