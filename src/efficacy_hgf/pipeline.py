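"""End-to-end pipeline driver: simulate -> fit -> select -> GLM -> associate.

Mirrors the analysis sequence: a synthetic cohort is generated, every
candidate model is fitted to every subject, random-effects model selection
picks the winning architecture, the winning model's trajectories build the
uncertainty (SE-U) parametric-modulation GLMs on synthetic region time
series, and the per-subject contrast values are related to the psychometric
battery by sparse PLS with confirmatory and stepwise regressions.

Every stage seed is derived by hashing (master seed, stage name, subject),
and a manifest with per-file checksums makes reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bms import bms
from .cohort import CohortConfig, generate_cohort
from .fitting import FitOptions, fit_map, per_trial_diagnostics
from .glm import ScanParams, build_design, fit_first_level, simulate_bold
from .hgf import filter_session
from .io import (write_evidence_csv, write_json, write_session_tsv,
                 write_trajectories_csv)
from .models import MODEL_REGISTRY, get_model

__all__ = ["PipelineConfig", "derive_seed", "run_pipeline"]

DEFAULT_SPLS_Y = ["phq9_total", "gcos_autonomy", "gcos_control",
                  "gcos_impersonal", "pcass_perceived_choice",
                  "pcass_awareness_of_self", "brs"]


def derive_seed(master_seed: int, stage: str, subject=None) -> int:
    """Deterministic per-stage (and per-subject) seed below 2**31."""
    key = f"{master_seed}:{stage}:{subject}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    models: tuple[str, ...] = tuple(MODEL_REGISTRY)
    fit_options: FitOptions = field(default_factory=FitOptions)
    scan: ScanParams | None = None  # None: sized to the longest session
    n_regions: int = 4
    active_regions: tuple[int, ...] = (0, 1)
    glm_effect: float = 1.0  # baseline SE-U effect in active regions
    glm_effect_gain: float = 1.0  # per-SD-of-brain-statistic modulation
    glm_noise_sd: float = 1.0
    glm_ar1_phi: float = 0.3
    spls_components_grid: tuple[int, ...] = (1, 2)
    spls_keep_x_grid: tuple[int, ...] | None = (2,)
    spls_keep_y_grid: tuple[int, ...] | None = (3,)
    spls_folds: int = 4
    spls_repeats: int = 100
    stability_threshold: float = 0.8
    chance_threshold: float = 0.55
    drop_chance_failures: bool = False
    master_seed: int = 0

    def __post_init__(self) -> None:
        unknown = [m for m in self.models if m not in MODEL_REGISTRY]
        if unknown:
            raise ValueError(
                f"unknown model name(s) {unknown}; registry: "
                f"{sorted(MODEL_REGISTRY)}")
        if max(self.active_regions, default=-1) >= self.n_regions:
            raise ValueError("active_regions out of range")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage, writing intermediates under ``outdir``.

    Returns the manifest (also written as ``manifest.json``): stage seeds,
    artifact checksums, the winning model, chance-criterion reports and the
    association results.  Fully reproducible given the config.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    master = config.master_seed
    manifest: dict = {"version": __version__, "master_seed": master,
                      "stages": {}, "files": {}}

    # --- simulate -----------------------------------------------------
    cohort_cfg = config.cohort
    cohort_seed = derive_seed(master, "cohort")
    cohort_cfg = CohortConfig(**{**cohort_cfg.__dict__, "seed": cohort_seed})
    cohort = generate_cohort(cohort_cfg)
    n_sub = cohort_cfg.n_subjects
    sess_dir = out / "sessions"
    sess_dir.mkdir(exist_ok=True)
    for s, session in enumerate(cohort.sessions):
        write_session_tsv(session, sess_dir / f"sub-{s:02d}_events.tsv")
    cohort.psychometrics.to_csv(out / "psychometrics.csv")
    manifest["stages"]["simulate"] = {"seed": cohort_seed, "n_subjects": n_sub}

    # --- fit all models ----------------------------------------------
    lme = np.zeros((n_sub, len(config.models)))
    fits = {}
    for s, session in enumerate(cohort.sessions):
        for j, name in enumerate(config.models):
            opts = FitOptions(**{**config.fit_options.__dict__,
                                 "seed": derive_seed(master, f"fit:{name}", s)})
            fit = fit_map(session, get_model(name), opts)
            lme[s, j] = fit.log_evidence
            fits[(s, name)] = fit
    write_evidence_csv(lme, config.models, out / "evidence.csv")
    fit_rows = [
        {"subject": s, "model": name,
         "log_evidence": fits[(s, name)].log_evidence,
         "geometric_mean_likelihood": fits[(s, name)].geometric_mean_likelihood,
         **{f"map_{k}": v for k, v in fits[(s, name)].map_estimates.items()}}
        for s in range(n_sub) for name in config.models
    ]
    pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)
    manifest["stages"]["fit"] = {"models": list(config.models)}

    # --- model selection ---------------------------------------------
    bms_seed = derive_seed(master, "bms")
    sel = bms(lme, n_mc_samples=100_000, seed=bms_seed,
              model_names=config.models)
    winner = config.models[sel.winner()]
    write_json({"model_names": list(config.models),
                "dirichlet_alpha": sel.dirichlet_alpha,
                "expected_freq": sel.expected_freq, "xp": sel.xp,
                "bor": sel.bor, "pxp": sel.pxp, "winner": winner},
               out / "bms.json")
    manifest["stages"]["bms"] = {"seed": bms_seed, "winner": winner,
                                 "pxp": sel.pxp.tolist()}

    # --- chance criterion on the winning model ------------------------
    chance = [per_trial_diagnostics(fits[(s, winner)], config.chance_threshold)
              for s in range(n_sub)]
    failures = [s for s, c in enumerate(chance)
                if not c["exceeds_chance_criterion"]]
    manifest["stages"]["chance_criterion"] = {
        "threshold": config.chance_threshold,
        "median_per_trial_likelihood": float(np.median(
            [c["geometric_mean_likelihood"] for c in chance])),
        "failures": failures,
    }
    keep = [s for s in range(n_sub)
            if not (config.drop_chance_failures and s in failures)]

    # --- winning-model trajectories and SE-U GLMs ---------------------
    winner_spec = get_model(winner)
    scan = config.scan
    if scan is None:
        longest = max(sess.total_duration_s for sess in cohort.sessions)
        tr = ScanParams().tr_s
        scan = ScanParams(tr_s=tr, n_volumes=int(np.ceil(longest / tr)) + 8)
    traj_dir = out / "trajectories"
    traj_dir.mkdir(exist_ok=True)
    sd = cohort.brain_stat.std()
    brain_z = (cohort.brain_stat - cohort.brain_stat.mean()) / (sd if sd > 0 else 1)
    contrasts = np.zeros((len(keep), config.n_regions))
    for row, s in enumerate(keep):
        fit = fits[(s, winner)]
        if winner_spec.perceptual == "rw":
            from .hgf import HGFParams
            beliefs = filter_session(cohort.sessions[s], HGFParams())
        else:
            agent, _ = winner_spec.build_agent(fit.map_estimates)
            beliefs = filter_session(cohort.sessions[s], agent["Choice"],
                                     agent["noChoice"])
        write_trajectories_csv(beliefs, traj_dir / f"sub-{s:02d}_traj.csv")
        design = build_design(cohort.sessions[s], beliefs, "sigma", scan)
        for r in range(config.n_regions):
            betas = {"cue_Choice": 1.0, "cue_noChoice": 1.0,
                     "selection": 0.5, "outcome": 0.5}
            if r in config.active_regions:
                betas["cue_Choice_x_sigma"] = (
                    config.glm_effect + config.glm_effect_gain * brain_z[s])
            bold = simulate_bold(
                design, betas, config.glm_noise_sd, config.glm_ar1_phi,
                seed=derive_seed(master, f"bold:{r}", s))
            contrasts[row, r] = fit_first_level(bold, design).contrast_value
    region_names = [f"region_{r}" for r in range(config.n_regions)]
    pd.DataFrame(contrasts, columns=region_names,
                 index=pd.Index(keep, name="subject")).to_csv(
                     out / "seu_contrasts.csv")
    manifest["stages"]["glm"] = {"n_regions": config.n_regions,
                                 "scan_volumes": scan.n_volumes}

    # --- associations -------------------------------------------------
    from .associations import (confirmatory_ols, stepwise_backward_aic,
                               tune_spls)
    Y = cohort.psychometrics.loc[keep, DEFAULT_SPLS_Y]
    X = pd.DataFrame(contrasts, columns=region_names, index=keep)
    tuning = tune_spls(
        X, Y, components_grid=config.spls_components_grid,
        keep_x_grid=config.spls_keep_x_grid,
        keep_y_grid=config.spls_keep_y_grid,
        folds=config.spls_folds, repeats=config.spls_repeats,
        stability_threshold=config.stability_threshold,
        seed=derive_seed(master, "spls"))
    assoc: dict = {"tuning": {k: v for k, v in tuning.items() if k != "cv_mse"}}
    if tuning["stable_X"] and tuning["stable_Y"]:
        x0 = tuning["stable_X"][0]
        ols = confirmatory_ols(Y[tuning["stable_Y"][0]], X[[x0]])
        assoc["confirmatory"] = {
            "response": tuning["stable_Y"][0], "predictor": x0,
            "table": ols.to_dict(orient="index"),
        }
        items = cohort.psychometrics.loc[keep,
                                         [f"phq9_item_{i}" for i in range(1, 10)]]
        step = stepwise_backward_aic(X[x0], items)
        assoc["stepwise"] = {
            "predictor_of": x0, "retained": step.retained,
            "final_aic": step.final_aic, "full_aic": step.full_aic,
        }
    write_json(assoc, out / "associations.json")
    manifest["stages"]["associate"] = {
        "stable_X": tuning["stable_X"], "stable_Y": tuning["stable_Y"]}

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out))] = _checksum(f)
    write_json(manifest, out / "manifest.json")
    return manifest
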