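"""Binary Hierarchical Gaussian Filter with parallel Choice/noChoice hierarchies.

The perceptual model is the standard binary HGF: the lowest level ``x1`` is a
binary indicator of whether the yellow card was the rewarded card on a trial,
the second level ``x2`` is the (logit-scale) tendency for yellow to be
rewarding, and an optional third level ``x3`` tracks the log-volatility of
that tendency.  ``x2`` and ``x3`` evolve as Gaussian random walks whose step
sizes are set by the evolution rates ``omega2`` and ``omega3``; ``kappa``
couples level 3 into the level-2 step size.

Inverting the model trial by trial yields precision-weighted belief updates:
each level's posterior mean moves by the prediction error from the level
below, weighted by the ratio of predictive precisions.  Because the task
interleaves free-choice and computer-instructed trials, two independent
hierarchies are filtered in parallel — one sees only Choice trials
(self-efficacy, ``mu_self``/``sigma_self``), the other only noChoice trials
(other-efficacy, ``mu_other``/``sigma_other``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "HGFParams",
    "BeliefState",
    "TrialDiagnostics",
    "Trajectory",
    "ParallelBeliefs",
    "sigmoid",
    "hgf_update",
    "filter_inputs",
    "filter_session",
    "NonPositivePrecisionError",
]


class NonPositivePrecisionError(ValueError):
    """Raised when an update would produce a non-positive posterior precision.

    Possible for extreme parameter settings at level 3; model-fitting code
    treats this as log-joint = -inf.
    """


def sigmoid(x: float) -> float:
    """Logistic sigmoid 1/(1+exp(-x)), mapping the level-2 tendency to a
    probability of the level-1 outcome."""
    # np.logaddexp is stable for large |x|
    return float(np.exp(-np.logaddexp(0.0, -x)))


@dataclass(frozen=True)
class HGFParams:
    """Perceptual-model parameters for one hierarchy.

    omega2 : level-2 evolution rate (log-volatility units); how quickly the
        card-outcome contingency is allowed to drift.
    omega3 : level-3 evolution rate (3-level models only).
    kappa  : coupling strength of level 3 into the level-2 step size; fixed
        at 1 by default and never estimated.
    mu2_0, sigma2_0, mu3_0, sigma3_0 : initial posterior means/variances.
    n_levels : 2 or 3.
    """

    omega2: float = -3.0
    omega3: float = -6.0
    kappa: float = 1.0
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0
    n_levels: int = 3

    def __post_init__(self) -> None:
        if self.n_levels not in (2, 3):
            raise ValueError(f"n_levels must be 2 or 3, got {self.n_levels}")
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("initial variances must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")

    def initial_state(self) -> "BeliefState":
        return BeliefState(self.mu2_0, self.sigma2_0, self.mu3_0, self.sigma3_0)


@dataclass(frozen=True)
class BeliefState:
    """Posterior belief state after some number of trials."""

    mu2: float
    sigma2: float
    mu3: float = 1.0
    sigma3: float = 1.0


@dataclass(frozen=True)
class TrialDiagnostics:
    """Predictive quantities and prediction errors for a single trial."""

    mu_hat1: float
    pi_hat1: float
    mu_hat2: float
    sigma_hat2: float
    delta1: float
    delta2: float
    input_u: int


def hgf_update(
    state: BeliefState, u: int, params: HGFParams
) -> tuple[BeliefState, TrialDiagnostics]:
    """One-trial binary HGF update.

    Prediction step: ``mu_hat1 = sigmoid(mu2)``, level-2 predictive variance
    ``sigma_hat2 = sigma2 + exp(kappa*mu3 + omega2)`` (for 2-level models the
    volatility term is just ``exp(omega2)``).  The level-2 posterior follows
    the precision-weighted update ``mu2' = mu2 + sigma2' * delta1``, which is
    the precision-ratio form ``delta_mu_i = (pi_hat_{i-1}/pi_i) * delta_{i-1}``
    once the level-1 predictive precision ``pi_hat1 = 1/(mu_hat1*(1-mu_hat1))``
    is identified.  Level 3, when present, is updated by the volatility
    prediction error ``delta2`` with the usual weighting factors.

    Raises :class:`NonPositivePrecisionError` if the level-3 posterior
    precision would be non-positive.
    """
    mu_hat2 = state.mu2
    try:
        # same arithmetic as the array kernel, bit for bit
        mu_hat1 = 1.0 / (1.0 + math.exp(-mu_hat2))
    except OverflowError:
        mu_hat1 = 0.0
    delta1 = u - mu_hat1
    if params.n_levels == 3:
        v2 = math.exp(params.kappa * state.mu3 + params.omega2)
    else:
        v2 = math.exp(params.omega2)
    sigma_hat2 = state.sigma2 + v2
    if not (0.0 < sigma_hat2 < 1e300):
        raise NonPositivePrecisionError(
            f"level-2 predictive variance {sigma_hat2:.3g} invalid")

    pi2 = 1.0 / sigma_hat2 + mu_hat1 * (1.0 - mu_hat1)
    if not pi2 > 0.0:
        raise NonPositivePrecisionError(
            f"level-2 posterior precision {pi2:.3g} <= 0")
    sigma2_new = 1.0 / pi2
    mu2_new = state.mu2 + sigma2_new * delta1

    denom1 = mu_hat1 * (1.0 - mu_hat1)
    pi_hat1 = 1.0 / denom1 if denom1 > 0.0 else math.inf
    if params.n_levels == 2:
        new = BeliefState(mu2_new, sigma2_new, state.mu3, state.sigma3)
        diag = TrialDiagnostics(
            mu_hat1=mu_hat1,
            pi_hat1=pi_hat1,
            mu_hat2=mu_hat2,
            sigma_hat2=sigma_hat2,
            delta1=delta1,
            delta2=math.nan,
            input_u=u,
        )
        return new, diag

    # volatility prediction error and level-3 update
    delta2 = (sigma2_new + (mu2_new - state.mu2) ** 2) / sigma_hat2 - 1.0
    w2 = v2 / sigma_hat2
    r2 = (v2 - state.sigma2) / sigma_hat2
    sigma_hat3 = state.sigma3 + math.exp(params.omega3)
    if not (0.0 < sigma_hat3 < 1e300):
        raise NonPositivePrecisionError(
            f"level-3 predictive variance {sigma_hat3:.3g} invalid")
    pi3 = 1.0 / sigma_hat3 + (params.kappa**2 / 2.0) * w2 * (w2 + r2 * delta2)
    if not pi3 > 0.0:
        raise NonPositivePrecisionError(
            f"level-3 posterior precision {pi3:.3g} <= 0"
        )
    sigma3_new = 1.0 / pi3
    mu3_new = state.mu3 + sigma3_new * (params.kappa / 2.0) * w2 * delta2

    new = BeliefState(mu2_new, sigma2_new, mu3_new, sigma3_new)
    diag = TrialDiagnostics(
        mu_hat1=mu_hat1,
        pi_hat1=pi_hat1,
        mu_hat2=mu_hat2,
        sigma_hat2=sigma_hat2,
        delta1=delta1,
        delta2=delta2,
        input_u=u,
    )
    return new, diag


# ---------------------------------------------------------------------------
# Array filter: the production path used by simulation and model fitting.
# A numba-compiled kernel when available; the pure-Python loop otherwise.
# Both execute the identical sequence of floating-point operations.
# ---------------------------------------------------------------------------


def _filter_loop(u, n_levels, omega2, omega3, kappa, mu2_0, sigma2_0, mu3_0, sigma3_0,
                 mu_hat1, sigma_hat2, mu_hat2, mu2, sigma2, mu3, sigma3, delta1, delta2):
    n = u.shape[0]
    m2 = mu2_0
    s2 = sigma2_0
    m3 = mu3_0
    s3 = sigma3_0
    for k in range(n):
        mh1 = 1.0 / (1.0 + math.exp(-m2))
        d1 = u[k] - mh1
        if n_levels == 3:
            v2 = math.exp(kappa * m3 + omega2)
        else:
            v2 = math.exp(omega2)
        sh2 = s2 + v2
        if not (sh2 > 0.0 and sh2 < 1e300):
            return k
        pi2 = 1.0 / sh2 + mh1 * (1.0 - mh1)
        if not (pi2 > 0.0):
            return k
        s2n = 1.0 / pi2
        m2n = m2 + s2n * d1
        mu_hat1[k] = mh1
        sigma_hat2[k] = sh2
        mu_hat2[k] = m2
        delta1[k] = d1
        if n_levels == 3:
            d2 = (s2n + (m2n - m2) ** 2) / sh2 - 1.0
            w2 = v2 / sh2
            r2 = (v2 - s2) / sh2
            sh3 = s3 + math.exp(omega3)
            if not (sh3 > 0.0 and sh3 < 1e300):
                return k
            pi3 = 1.0 / sh3 + (kappa * kappa / 2.0) * w2 * (w2 + r2 * d2)
            if not (pi3 > 0.0):
                return k  # failure at trial k
            s3 = 1.0 / pi3
            m3 = m3 + s3 * (kappa / 2.0) * w2 * d2
            delta2[k] = d2
        else:
            delta2[k] = np.nan
        m2 = m2n
        s2 = s2n
        mu2[k] = m2
        sigma2[k] = s2
        mu3[k] = m3
        sigma3[k] = s3
    return -1  # success


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _filter_loop_fast = njit(cache=False)(_filter_loop)
except Exception:  # pragma: no cover
    _filter_loop_fast = _filter_loop


@dataclass
class Trajectory:
    """Per-trial belief trajectory for one hierarchy (one condition).

    All ``*_hat`` quantities are predictive (pre-outcome); plain ``mu2`` etc.
    are posteriors after seeing that trial's input.
    """

    u: np.ndarray
    mu_hat1: np.ndarray
    sigma_hat2: np.ndarray
    mu_hat2: np.ndarray
    mu2: np.ndarray
    sigma2: np.ndarray
    mu3: np.ndarray
    sigma3: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray

    def __len__(self) -> int:
        return len(self.u)


def filter_inputs(u: Iterable[int], params: HGFParams) -> Trajectory:
    """Filter a sequence of binary inputs through one HGF hierarchy.

    Raises :class:`NonPositivePrecisionError` on a level-3 precision failure.
    """
    u_arr = np.ascontiguousarray(u, dtype=np.float64)
    n = u_arr.shape[0]
    out = [np.empty(n) for _ in range(9)]
    fail = _filter_loop_fast(
        u_arr, params.n_levels, params.omega2, params.omega3, params.kappa,
        params.mu2_0, params.sigma2_0, params.mu3_0, params.sigma3_0, *out,
    )
    if fail >= 0:
        raise NonPositivePrecisionError(
            f"level-3 posterior precision <= 0 at trial {fail}"
        )
    mu_hat1, sigma_hat2, mu_hat2, mu2, sigma2, mu3, sigma3, delta1, delta2 = out
    return Trajectory(u_arr.astype(int), mu_hat1, sigma_hat2, mu_hat2,
                      mu2, sigma2, mu3, sigma3, delta1, delta2)


@dataclass
class ParallelBeliefs:
    """Trajectories of the two parallel hierarchies, in task vocabulary.

    ``mu_self``/``sigma_self`` are the predictive level-2 mean and variance on
    Choice trials (self-efficacy belief and its uncertainty);
    ``mu_other``/``sigma_other`` are their noChoice analogues.
    """

    choice: Trajectory
    nochoice: Trajectory
    choice_trial_index: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    nochoice_trial_index: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def mu_self(self) -> np.ndarray:
        return self.choice.mu_hat2

    @property
    def sigma_self(self) -> np.ndarray:
        return self.choice.sigma_hat2

    @property
    def mu_other(self) -> np.ndarray:
        return self.nochoice.mu_hat2

    @property
    def sigma_other(self) -> np.ndarray:
        return self.nochoice.sigma_hat2


def filter_session(session, params_choice: HGFParams,
                   params_nochoice: HGFParams | None = None) -> ParallelBeliefs:
    """Run the parallel Choice/noChoice hierarchies over a session.

    Each trial is routed to its condition's hierarchy in presentation order;
    the input is ``u = 1`` iff the yellow card was the rewarded card on that
    trial, which is observable in both conditions.  There is no lookahead:
    the trajectory up to trial k depends only on that condition's trials up
    to k.

    Parameters default to sharing ``params_choice`` for both conditions when
    ``params_nochoice`` is omitted.
    """
    if params_nochoice is None:
        params_nochoice = params_choice
    u_c, u_n, idx_c, idx_n = [], [], [], []
    for t in session.trials:
        u = 1 if t.rewarded_stimulus == "yellow" else 0
        if t.condition == "Choice":
            u_c.append(u)
            idx_c.append(t.index)
        else:
            u_n.append(u)
            idx_n.append(t.index)
    if not u_c or not u_n:
        raise ValueError("session must contain trials of both conditions")
    return ParallelBeliefs(
        choice=filter_inputs(u_c, params_choice),
        nochoice=filter_inputs(u_n, params_nochoice),
        choice_trial_index=np.asarray(idx_c, dtype=int),
        nochoice_trial_index=np.asarray(idx_n, dtype=int),
    )
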