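"""Tabular I/O: BIDS-events-like session TSVs, trajectory and evidence
tables, and YAML configuration."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hgf import ParallelBeliefs
from .task import Session, TaskConfig, TrialRecord

__all__ = [
    "session_to_frame",
    "write_session_tsv",
    "read_session_tsv",
    "trajectories_to_frame",
    "write_trajectories_csv",
    "write_evidence_csv",
    "read_evidence_csv",
    "load_yaml_config",
    "SchemaError",
]

SESSION_COLUMNS = ["onset", "duration", "trial_index", "phase", "condition",
                   "selected", "rewarded_stimulus", "reward", "agent_selected"]
_PHASES = ("cue", "selection", "outcome")


class SchemaError(ValueError):
    """A session table violates the expected schema or task invariants."""


def session_to_frame(session: Session) -> pd.DataFrame:
    """Long-format events table: one row per trial phase."""
    cfg = session.config
    durs = {"cue": cfg.cue_dur_s, "selection": cfg.selection_dur_s,
            "outcome": cfg.outcome_dur_s}
    rows = []
    for t in session.trials:
        onsets = {"cue": t.onset_cue_s, "selection": t.onset_selection_s,
                  "outcome": t.onset_outcome_s}
        for phase in _PHASES:
            rows.append({
                "onset": onsets[phase],
                "duration": durs[phase],
                "trial_index": t.index,
                "phase": phase,
                "condition": t.condition,
                "selected": t.selected,
                "rewarded_stimulus": t.rewarded_stimulus,
                "reward": t.reward,
                "agent_selected": t.agent_selected,
            })
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_session_tsv(session: Session, path) -> None:
    session_to_frame(session).to_csv(path, sep="\t", index=False)


def read_session_tsv(path, config: TaskConfig | None = None) -> Session:
    """Read and validate an events TSV back into a :class:`Session`.

    Checks the header, categorical vocabularies, onset monotonicity within
    trials, and the reward/selection consistency invariant; violations raise
    :class:`SchemaError` naming the offending row or column.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col, vocab in (("phase", set(_PHASES)),
                       ("condition", {"Choice", "noChoice"}),
                       ("selected", {"yellow", "blue"}),
                       ("rewarded_stimulus", {"yellow", "blue"})):
        bad = set(df[col].unique()) - vocab
        if bad:
            raise SchemaError(f"{path}: column {col!r} has values {sorted(bad)} "
                              f"outside {sorted(vocab)}")

    cfg = config or TaskConfig()
    trials: list[TrialRecord] = []
    for idx, grp in df.groupby("trial_index", sort=True):
        onsets = {}
        for phase in _PHASES:
            sub = grp[grp["phase"] == phase]
            if len(sub) != 1:
                raise SchemaError(
                    f"{path}: trial {idx} needs exactly one {phase!r} row")
            onsets[phase] = float(sub["onset"].iloc[0])
        if not (onsets["cue"] < onsets["selection"] < onsets["outcome"]):
            raise SchemaError(f"{path}: trial {idx} onsets are not increasing")
        r = grp.iloc[0]
        reward = int(r["reward"])
        if reward != int(r["selected"] == r["rewarded_stimulus"]):
            raise SchemaError(
                f"{path}: trial {idx} reward inconsistent with selection")
        if r["condition"] == "noChoice" and bool(r["agent_selected"]):
            raise SchemaError(
                f"{path}: trial {idx} noChoice trial marked agent-selected")
        trials.append(TrialRecord(
            index=int(idx),
            condition=str(r["condition"]),
            presented_sides={},
            rewarded_stimulus=str(r["rewarded_stimulus"]),
            onset_cue_s=onsets["cue"],
            onset_selection_s=onsets["selection"],
            onset_outcome_s=onsets["outcome"],
            selected=str(r["selected"]),
            agent_selected=bool(r["agent_selected"]),
            reward=reward,
        ))
    trials.sort(key=lambda t: t.index)
    if not trials:
        raise SchemaError(f"{path}: no trials")
    total = trials[-1].onset_outcome_s + cfg.outcome_dur_s
    return Session(trials=trials, config=cfg, total_duration_s=total)


def trajectories_to_frame(beliefs: ParallelBeliefs) -> pd.DataFrame:
    """Per-trial trajectory table for both hierarchies."""
    frames = []
    for cond, traj, idx in (("Choice", beliefs.choice, beliefs.choice_trial_index),
                            ("noChoice", beliefs.nochoice,
                             beliefs.nochoice_trial_index)):
        if len(idx) != len(traj):
            idx = np.arange(1, len(traj) + 1)
        frames.append(pd.DataFrame({
            "trial_index": idx,
            "condition": cond,
            "mu_hat1": traj.mu_hat1,
            "mu2_hat": traj.mu_hat2,
            "sigma2_hat": traj.sigma_hat2,
            "mu2": traj.mu2,
            "sigma2": traj.sigma2,
            "mu3": traj.mu3,
            "sigma3": traj.sigma3,
            "delta1": traj.delta1,
            "delta2": traj.delta2,
        }))
    return (pd.concat(frames, ignore_index=True)
            .sort_values("trial_index", kind="stable")
            .reset_index(drop=True))


def write_trajectories_csv(beliefs: ParallelBeliefs, path) -> None:
    trajectories_to_frame(beliefs).to_csv(path, index=False)


def write_evidence_csv(log_evidence: np.ndarray, model_names, path,
                       subject_ids=None) -> None:
    lme = np.asarray(log_evidence, float)
    idx = subject_ids if subject_ids is not None else range(lme.shape[0])
    pd.DataFrame(lme, columns=list(model_names),
                 index=pd.Index(idx, name="subject")).to_csv(path)


def read_evidence_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(float), list(df.columns)


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a mapping at top level")
    return data


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
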