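"""Response models: mapping predictive beliefs to choice probabilities.

Two links are implemented.  The softmax link has a free decision-noise
parameter ``beta``; its default *symmetric* form
``p(yellow) = 1/(1+exp(-beta*(2*mu_hat1-1)))`` returns 0.5 at belief
indifference.  A *verbatim* form ``1/(1+exp(-beta*mu_hat1))`` — which is
biased toward yellow at indifference — is kept behind a switch for fidelity
testing.  The unit-square sigmoid link has no free parameter: its slope on a
given trial is ``zeta = -log(sigma_hat2)``, the negative log-transformed
uncertainty of the relevant efficacy belief, so greater certainty yields more
deterministic choice.

A Rescorla-Wagner learner with fixed learning rate and softmax response is
provided as the non-hierarchical control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hgf import HGFParams, ParallelBeliefs, Trajectory, filter_inputs

__all__ = [
    "ResponseParams",
    "RWParams",
    "ZETA_FLOOR",
    "softmax_prob",
    "unit_square_prob",
    "rw_update",
    "rw_filter",
    "choice_probability_trajectory",
    "session_log_likelihood",
]

# Floor on the unit-square slope: sigma_hat2 >= 1 would give zeta <= 0 and a
# flat or inverted link, so zeta is clipped below at this value.
ZETA_FLOOR = 1e-3


@dataclass(frozen=True)
class ResponseParams:
    """Softmax decision-noise inverse temperatures, one per condition."""

    beta_choice: float = 1.0
    beta_nochoice: float = 1.0

    def __post_init__(self) -> None:
        if self.beta_choice <= 0 or self.beta_nochoice <= 0:
            raise ValueError("decision-noise parameters must be positive")


@dataclass(frozen=True)
class RWParams:
    """Rescorla-Wagner control: fixed learning rate, softmax noise, initial
    value.  A single (alpha, beta) pair is shared across conditions; the two
    conditions keep separate value trajectories."""

    alpha: float = 0.3
    beta: float = 4.0
    v0: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (0.0 < self.v0 < 1.0):
            raise ValueError("v0 must be in (0, 1)")


def softmax_prob(mu_hat1, beta: float, form: str = "symmetric"):
    """Probability of choosing yellow under the softmax response model.

    ``form='symmetric'`` (default) maps belief indifference to 0.5;
    ``form='verbatim'`` is ``1/(1+exp(-beta*mu_hat1))``.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    mu = np.asarray(mu_hat1, dtype=float)
    if form == "symmetric":
        z = beta * (2.0 * mu - 1.0)
    elif form == "verbatim":
        z = beta * mu
    else:
        raise ValueError(f"unknown softmax form {form!r}")
    out = np.exp(-np.logaddexp(0.0, -z))
    return float(out) if out.ndim == 0 else out


def unit_square_prob(mu_hat1, sigma_hat2, zeta_floor: float = ZETA_FLOOR):
    """Probability of choosing yellow under the unit-square sigmoid.

    ``p = mu^zeta / (mu^zeta + (1-mu)^zeta)`` with
    ``zeta = max(-log(sigma_hat2), zeta_floor)``.  At ``zeta = 1`` the link
    is the identity; smaller ``sigma_hat2`` (more certainty) pushes p away
    from 0.5.
    """
    # guard against float saturation of sigmoid(mu2) at extreme parameters
    mu = np.clip(np.asarray(mu_hat1, dtype=float), 1e-15, 1.0 - 1e-15)
    sh2 = np.asarray(sigma_hat2, dtype=float)
    zeta = np.maximum(-np.log(sh2), zeta_floor)
    # Work in log space for numerical safety at extreme zeta.
    la = zeta * np.log(mu)
    lb = zeta * np.log1p(-mu)
    out = np.exp(la - np.logaddexp(la, lb))
    return float(out) if out.ndim == 0 else out


def rw_update(v: float, u: int, alpha: float) -> float:
    """One Rescorla-Wagner step: ``v' = v + alpha*(u - v)``."""
    return v + alpha * (u - v)


def rw_filter(u, params: RWParams) -> np.ndarray:
    """Predictive value trajectory V_hat (before each trial's outcome)."""
    u = np.asarray(u, dtype=float)
    v_hat = np.empty(len(u))
    v = params.v0
    for k, uk in enumerate(u):
        v_hat[k] = v
        v = rw_update(v, uk, params.alpha)
    return v_hat


def choice_probability_trajectory(u, condition: str, agent_params,
                                  response_params, model) -> np.ndarray:
    """Per-trial p(yellow) for one condition's input sequence.

    For HGF models, beliefs are filtered through that condition's hierarchy
    and passed through the model's response link; for the Rescorla-Wagner
    control, the value trajectory feeds the symmetric softmax.
    """
    if model.perceptual == "rw":
        v_hat = rw_filter(u, agent_params)
        return softmax_prob(v_hat, agent_params.beta)
    params = agent_params[condition] if isinstance(agent_params, dict) else agent_params
    traj = filter_inputs(u, params)
    if model.response == "softmax":
        beta = (response_params.beta_choice if condition == "Choice"
                else response_params.beta_nochoice)
        return softmax_prob(traj.mu_hat1, beta)
    return unit_square_prob(traj.mu_hat1, traj.sigma_hat2)


def _observed_prob(p_yellow: np.ndarray, selected_yellow: np.ndarray) -> np.ndarray:
    return np.where(selected_yellow, p_yellow, 1.0 - p_yellow)


def session_log_likelihood(session, beliefs, response_params, model,
                           score_nochoice: bool = False):
    """Response-model log-likelihood of the observed selections.

    Sums ``log p(selected_k | predictive belief_k)`` over Choice trials (the
    only trials on which the participant acts freely).  When
    ``score_nochoice`` is set, noChoice trials are additionally scored as
    predictions of the yoked computer selection under the noChoice hierarchy
    — off by default because those selections are deterministic given
    history.

    ``beliefs`` is a :class:`ParallelBeliefs` for HGF models, or a dict of
    per-condition value trajectories for the Rescorla-Wagner control.

    Returns ``(total_loglik, per_trial)`` where ``per_trial`` is a list of
    ``(trial_index, condition, p_observed)`` rows for the scored trials.
    """
    sel_yellow_c, sel_yellow_n, idx_c, idx_n = [], [], [], []
    for t in session.trials:
        if t.selected is None:
            raise ValueError("session has unplayed trials")
        if t.condition == "Choice":
            sel_yellow_c.append(t.selected == "yellow")
            idx_c.append(t.index)
        else:
            sel_yellow_n.append(t.selected == "yellow")
            idx_n.append(t.index)
    sel_yellow_c = np.asarray(sel_yellow_c)
    sel_yellow_n = np.asarray(sel_yellow_n)

    if model.perceptual == "rw":
        p_c = softmax_prob(beliefs["Choice"], response_params.beta)
        p_n = softmax_prob(beliefs["noChoice"], response_params.beta)
    elif model.response == "softmax":
        p_c = softmax_prob(beliefs.choice.mu_hat1, response_params.beta_choice)
        p_n = softmax_prob(beliefs.nochoice.mu_hat1, response_params.beta_nochoice)
    else:
        p_c = unit_square_prob(beliefs.choice.mu_hat1, beliefs.choice.sigma_hat2)
        p_n = unit_square_prob(beliefs.nochoice.mu_hat1, beliefs.nochoice.sigma_hat2)

    p_obs_c = _observed_prob(np.asarray(p_c), sel_yellow_c)
    rows = [(i, "Choice", p) for i, p in zip(idx_c, p_obs_c)]
    with np.errstate(divide="ignore"):
        total = float(np.sum(np.log(p_obs_c)))
    if score_nochoice:
        p_obs_n = _observed_prob(np.asarray(p_n), sel_yellow_n)
        rows += [(i, "noChoice", p) for i, p in zip(idx_n, p_obs_n)]
        with np.errstate(divide="ignore"):
            total += float(np.sum(np.log(p_obs_n)))
    rows.sort(key=lambda r: r[0])
    return total, rows
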