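"""Simulator for the modified inherent value of choice task (MIVCT).

The MIVCT is a probabilistic instrumental learning task in which participants
learn which of two colour stimuli (yellow vs blue) is more often rewarded
under an 80:20 reinforcement schedule.  On half the trials the participant
chooses freely (Choice condition); on the other half the computer instructs
the selection (noChoice condition).  The computer's selections echo the
participant's own earlier choices with a fixed lag, so the reward histories
of the two conditions are matched.  Each trial has three jittered phases —
Cue (condition revealed), Selection, Outcome.

This module generates trial schedules with that structure and runs
closed-loop synthetic sessions in which an HGF (or Rescorla-Wagner) agent
plays the task.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .hgf import HGFParams, filter_inputs

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "TrialSchedule",
    "Session",
    "generate_schedule",
    "simulate_session",
]

STIMULI = ("yellow", "blue")


@dataclass(frozen=True)
class TaskConfig:
    """Task structure parameters.

    Defaults reproduce the scanner task: 27 trials per condition, 80:20
    reinforcement of the good stimulus, noChoice selections yoked to the
    participant's own choices with a three-trial lag, and uniformly jittered
    inter-phase gaps.
    """

    n_choice_trials: int = 27
    n_nochoice_trials: int = 27
    reward_prob_good: float = 0.8
    yoking_lag: int = 3
    jitter_bounds_s: tuple[float, float] = (2.0, 6.0)
    cue_dur_s: float = 2.0
    selection_dur_s: float = 2.0
    outcome_dur_s: float = 2.0
    good_stimulus: str = "yellow"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_choice_trials <= 0 or self.n_nochoice_trials <= 0:
            raise ValueError("trial counts must be positive")
        if not (0.5 < self.reward_prob_good <= 1.0):
            raise ValueError("reward_prob_good must be in (0.5, 1]")
        if self.yoking_lag < 1:
            raise ValueError("yoking_lag must be >= 1")
        lo, hi = self.jitter_bounds_s
        if not (0 <= lo <= hi):
            raise ValueError("jitter bounds must satisfy 0 <= min <= max")
        if min(self.cue_dur_s, self.selection_dur_s, self.outcome_dur_s) <= 0:
            raise ValueError("phase durations must be positive")
        if self.good_stimulus not in STIMULI:
            raise ValueError(f"good_stimulus must be one of {STIMULI}")


@dataclass
class TrialRecord:
    """One trial: structure, the selection made, and its outcome.

    ``rewarded_stimulus`` is pre-drawn by the schedule; ``reward == 1`` iff
    the selected stimulus matches it.  ``agent_selected`` is False on
    noChoice trials (the computer selects).  ``yoked`` is False on noChoice
    trials that occurred before the yoking queue had filled.
    """

    index: int
    condition: str
    presented_sides: dict[str, str]
    rewarded_stimulus: str
    onset_cue_s: float
    onset_selection_s: float
    onset_outcome_s: float
    selected: str | None = None
    agent_selected: bool = False
    reward: int | None = None
    yoked: bool | None = None

    @property
    def input_u(self) -> int:
        """Level-1 input: 1 iff yellow was the rewarded card this trial."""
        return 1 if self.rewarded_stimulus == "yellow" else 0


@dataclass
class TrialSchedule:
    """Pre-drawn trial structure before any agent has played it."""

    config: TaskConfig
    trials: list[TrialRecord]
    matched_rewards: bool = True

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class Session:
    """A played session: schedule plus selections, rewards and (when
    synthetic) the generating agent parameters."""

    trials: list[TrialRecord]
    config: TaskConfig
    agent_params: dict | None = None
    total_duration_s: float = 0.0

    def __len__(self) -> int:
        return len(self.trials)

    def condition_counts(self) -> dict[str, int]:
        out = {"Choice": 0, "noChoice": 0}
        for t in self.trials:
            out[t.condition] += 1
        return out


def generate_schedule(config: TaskConfig, seed: int | None = None) -> TrialSchedule:
    """Draw a randomized trial schedule.

    The Choice/noChoice order is a uniform shuffle; stimulus screen sides are
    randomized per trial; inter-phase jitters are uniform on
    ``jitter_bounds_s``.  The rewarded stimulus is pre-drawn
    Bernoulli(``reward_prob_good``) for the good stimulus once per
    condition-slot, and the k-th Choice trial shares its draw with the k-th
    noChoice trial, so the reward schedule is identical across conditions.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n_c, n_n = config.n_choice_trials, config.n_nochoice_trials

    conditions = ["Choice"] * n_c + ["noChoice"] * n_n
    rng.shuffle(conditions)

    # One reward draw per condition slot, shared across conditions so that
    # matched trial ranks see the same contingency realization.
    n_slots = max(n_c, n_n)
    good_rewarded = rng.random(n_slots) < config.reward_prob_good
    bad = STIMULI[1] if config.good_stimulus == STIMULI[0] else STIMULI[0]
    slot_reward = [config.good_stimulus if g else bad for g in good_rewarded]

    trials: list[TrialRecord] = []
    t_now = 0.0
    slot = {"Choice": 0, "noChoice": 0}
    for i, cond in enumerate(conditions, start=1):
        sides = (
            {"yellow": "left", "blue": "right"}
            if rng.random() < 0.5
            else {"yellow": "right", "blue": "left"}
        )
        rewarded = slot_reward[slot[cond]]
        slot[cond] += 1
        j1, j2, j3 = rng.uniform(*config.jitter_bounds_s, size=3)
        onset_cue = t_now
        onset_sel = onset_cue + config.cue_dur_s + j1
        onset_out = onset_sel + config.selection_dur_s + j2
        t_now = onset_out + config.outcome_dur_s + j3
        trials.append(
            TrialRecord(
                index=i,
                condition=cond,
                presented_sides=sides,
                rewarded_stimulus=rewarded,
                onset_cue_s=onset_cue,
                onset_selection_s=onset_sel,
                onset_outcome_s=onset_out,
            )
        )
    return TrialSchedule(config=config, trials=trials)


def simulate_session(schedule: TrialSchedule, agent_params, response_params,
                     model, seed: int = 0) -> Session:
    """Play a schedule with a synthetic agent, closed loop.

    On Choice trials the agent samples a selection from its response model
    given its current predictive belief, then its Choice hierarchy updates on
    the observed input.  On noChoice trials the computer replays the agent's
    own selection from the ``yoking_lag``-th most recent preceding Choice
    trial (uniform random before the queue fills, flagged ``yoked=False``),
    and the noChoice hierarchy updates on that trial's input.  Belief state is
    carried per condition independently.

    ``model`` is a :class:`~efficacy_hgf.models.ModelSpec`;
    ``agent_params``/``response_params`` must match its architecture
    (``HGFParams`` per condition or ``RWParams``).

    Replaying the returned session through ``filter_session`` with the
    generating parameters reproduces the simulation-time trajectories
    bit-for-bit: beliefs depend only on the pre-drawn reward sequence.
    """
    from .models import ModelSpec  # local import to avoid a cycle
    from .responses import choice_probability_trajectory

    if not isinstance(model, ModelSpec):
        raise TypeError("model must be a ModelSpec")
    model.validate_agent(agent_params, response_params)

    rng = np.random.default_rng(seed)
    cfg = schedule.config
    trials = [
        TrialRecord(**{**t.__dict__, "presented_sides": dict(t.presented_sides)})
        for t in schedule.trials
    ]

    # Precompute per-condition input sequences (they do not depend on the
    # agent's selections), then filter beliefs once per condition.
    u_choice = [t.input_u for t in trials if t.condition == "Choice"]
    u_nochoice = [t.input_u for t in trials if t.condition == "noChoice"]
    p_yellow_choice = choice_probability_trajectory(
        u_choice, "Choice", agent_params, response_params, model
    )

    queue: deque[str] = deque()
    k_choice = 0
    for t in trials:
        if t.condition == "Choice":
            p = p_yellow_choice[k_choice]
            k_choice += 1
            t.selected = "yellow" if rng.random() < p else "blue"
            t.agent_selected = True
            t.yoked = None
            queue.append(t.selected)
        else:
            if len(queue) >= cfg.yoking_lag:
                t.selected = queue[-cfg.yoking_lag]
                t.yoked = True
            else:
                t.selected = STIMULI[rng.integers(2)]
                t.yoked = False
            t.agent_selected = False
        t.reward = 1 if t.selected == t.rewarded_stimulus else 0

    last = trials[-1]
    total = last.onset_outcome_s + cfg.outcome_dur_s
    return Session(
        trials=trials,
        config=cfg,
        agent_params={
            "model": model.name,
            "agent_params": agent_params,
            "response_params": response_params,
            "seed": seed,
        },
        total_duration_s=total,
    )
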