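"""Synthetic cohorts: agents, sessions, and psychometric batteries.

A cohort draws per-subject model parameters from population distributions,
plays each agent through a fresh task schedule, and generates a psychometric
battery whose measures load on latent traits — one of which is tied to a
designated model-derived brain statistic (by default the subject's mean
uncertainty difference, sigma_self - sigma_other), so that the downstream
association stage has recoverable structure.  Scale means and spreads for
the battery follow values typical of a moderately depressed young-adult
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hgf import NonPositivePrecisionError, filter_session
from .models import get_model
from .task import Session, TaskConfig, generate_schedule, simulate_session

__all__ = [
    "CohortConfig",
    "CohortDataset",
    "PSYCHOMETRIC_COLUMNS",
    "default_loading",
    "zero_loading",
    "generate_cohort",
    "planted_association_data",
]

PHQ9_ITEMS = [f"phq9_item_{i}" for i in range(1, 10)]
SCALES = ["gcos_autonomy", "gcos_control", "gcos_impersonal",
          "pcass_perceived_choice", "pcass_awareness_of_self", "brs"]
PSYCHOMETRIC_COLUMNS = PHQ9_ITEMS + ["phq9_total"] + SCALES

# (population mean, SD, lower bound, upper bound) per continuous scale
_SCALE_DIST = {
    "gcos_autonomy": (43.7, 5.33, 12, 84),
    "gcos_control": (25.1, 7.08, 12, 84),
    "gcos_impersonal": (30.5, 6.76, 12, 84),
    "pcass_perceived_choice": (15.8, 4.30, 5, 25),
    "pcass_awareness_of_self": (14.4, 4.93, 5, 25),
    "brs": (3.17, 0.32, 1, 5),
}


def default_loading() -> pd.DataFrame:
    """Measure x latent loading matrix: columns (brain, depression).

    The brain latent (the designated model-derived statistic) loads on the
    depressive items, perceived choice (negatively) and the impersonal
    orientation; an independent depression latent supplies the usual
    covariance among symptom and trait measures.
    """
    w = pd.DataFrame(0.0, index=PHQ9_ITEMS + SCALES, columns=["brain", "depression"])
    w.loc[PHQ9_ITEMS, "brain"] = 0.4
    w.loc[PHQ9_ITEMS, "depression"] = 0.6
    w.loc["pcass_perceived_choice", "brain"] = -0.6
    w.loc["gcos_impersonal", "brain"] = 0.5
    w.loc["gcos_autonomy", "depression"] = -0.4
    w.loc["pcass_awareness_of_self", "depression"] = -0.4
    w.loc["brs", "depression"] = -0.4
    return w


def zero_loading() -> pd.DataFrame:
    """Null structure: psychometrics independent of the brain statistic."""
    w = default_loading()
    w[:] = 0.0
    return w


@dataclass
class CohortConfig:
    """Population distributions and plumbing for a synthetic cohort.

    Evolution rates are drawn per subject and condition from Gaussians;
    decision noise for softmax agents is log-normal.  ``loading`` maps each
    psychometric measure to weights on the (brain, depression) latents.
    """

    n_subjects: int = 21
    task: TaskConfig = field(default_factory=TaskConfig)
    model: str = "3L_us"
    omega2_choice: tuple[float, float] = (-6.10, 2.21)
    omega2_nochoice: tuple[float, float] = (-6.33, 0.978)
    omega3: tuple[float, float] = (-6.00, 0.019)
    log_beta: tuple[float, float] = (np.log(4.0), 0.5)
    logit_alpha: tuple[float, float] = (0.0, 0.5)
    loading: pd.DataFrame | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("omega2_choice", "omega2_nochoice", "omega3",
                     "log_beta", "logit_alpha"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} SD must be >= 0")
        if self.loading is not None and not np.all(np.isfinite(self.loading.to_numpy())):
            raise ValueError("loading matrix must be finite")
        get_model(self.model)  # raises on unknown model


@dataclass
class CohortDataset:
    config: CohortConfig
    sessions: list[Session]
    subject_params: list[dict]
    brain_stat: np.ndarray  # mean sigma_self - sigma_other per subject
    psychometrics: pd.DataFrame


def _draw_subject_values(cfg: CohortConfig, model, rng) -> dict[str, float]:
    values: dict[str, float] = {}
    for name in model.param_names:
        if name == "omega2_choice":
            m, s = cfg.omega2_choice
        elif name == "omega2_nochoice":
            m, s = cfg.omega2_nochoice
        elif name in ("omega3_choice", "omega3_nochoice"):
            m, s = cfg.omega3
        elif name.startswith("beta"):
            m, s = cfg.log_beta
        elif name == "alpha":
            m, s = cfg.logit_alpha
        else:  # pragma: no cover
            raise KeyError(name)
        draw = rng.normal(m, s)
        if name.startswith("beta"):
            draw = np.exp(draw)
        elif name == "alpha":
            draw = 1.0 / (1.0 + np.exp(-draw))
        values[name] = float(draw)
    return values


def _brain_statistic(session: Session, model, values) -> float:
    """Mean predictive uncertainty difference sigma_self - sigma_other."""
    if model.perceptual == "rw":
        # control agents carry no uncertainty; use a reference 3-level filter
        from .hgf import HGFParams
        pb = filter_session(session, HGFParams())
    else:
        agent, _ = model.build_agent(values)
        pb = filter_session(session, agent["Choice"], agent["noChoice"])
    return float(pb.sigma_self.mean() - pb.sigma_other.mean())


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Simulate a full cohort deterministically from ``config.seed``."""
    model = get_model(config.model)
    rng = np.random.default_rng(config.seed)
    loading = config.loading if config.loading is not None else default_loading()

    sessions, subject_params, stats = [], [], []
    for s in range(config.n_subjects):
        # The population is truncated to the numerically valid parameter
        # region: draws whose belief filter loses positive precision
        # mid-session are rejected and redrawn.
        for _ in range(100):
            values = _draw_subject_values(config, model, rng)
            agent, resp = model.build_agent(values)
            sched_seed, sim_seed = rng.integers(2**31, size=2)
            try:
                schedule = generate_schedule(config.task, int(sched_seed))
                session = simulate_session(schedule, agent, resp, model,
                                           int(sim_seed))
                stat = _brain_statistic(session, model, values)
            except NonPositivePrecisionError:
                continue
            break
        else:  # pragma: no cover
            raise RuntimeError("could not draw a valid agent in 100 attempts")
        sessions.append(session)
        subject_params.append(values)
        stats.append(stat)

    brain_stat = np.asarray(stats)
    sd = brain_stat.std()
    brain_z = (brain_stat - brain_stat.mean()) / (sd if sd > 0 else 1.0)
    dep = rng.standard_normal(config.n_subjects)

    rows = {}
    for m in PHQ9_ITEMS + SCALES:
        wb = float(loading.loc[m, "brain"]) if m in loading.index else 0.0
        wd = float(loading.loc[m, "depression"]) if m in loading.index else 0.0
        z = wb * brain_z + wd * dep + config.noise_sd * rng.standard_normal(
            config.n_subjects)
        if m in PHQ9_ITEMS:
            rows[m] = np.clip(np.round(1.2 + 0.9 * z), 0, 3).astype(int)
        else:
            mu, s_, lo, hi = _SCALE_DIST[m]
            vals = mu + s_ * z
            if m != "brs":
                vals = np.round(vals)
            rows[m] = np.clip(vals, lo, hi)
    psych = pd.DataFrame(rows, index=pd.RangeIndex(config.n_subjects, name="subject"))
    psych["phq9_total"] = psych[PHQ9_ITEMS].sum(axis=1)
    psych = psych[PSYCHOMETRIC_COLUMNS]

    return CohortDataset(
        config=config,
        sessions=sessions,
        subject_params=subject_params,
        brain_stat=brain_stat,
        psychometrics=psych,
    )


def planted_association_data(n: int = 21, p: int = 6, q: int = 10,
                             active_x=(0, 1), active_y=(0, 1, 2),
                             noise_sd: float = 0.3,
                             seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian X/Y matrices with a planted one-latent association.

    The active X and Y columns all load on a single standard-normal latent
    with unit weight plus ``noise_sd`` Gaussian noise; inactive columns are
    pure noise.  With the default noise level the planted structure is
    strong, mimicking a clear brain-behaviour axis.
    """
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n)
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, q))
    for j in active_x:
        X[:, j] = latent + noise_sd * rng.standard_normal(n)
    for j in active_y:
        Y[:, j] = latent + noise_sd * rng.standard_normal(n)
    return X, Y
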