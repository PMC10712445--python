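"""Random-effects Bayesian model selection over a group of subjects.

Given a subjects x models matrix of log model evidences, model frequencies
in the population are given a Dirichlet prior and inferred by variational
Bayes: subject-wise posterior model assignments and the Dirichlet
concentration are iterated to convergence.  Exceedance probabilities (the
posterior probability that each model is the most frequent) are estimated by
Monte-Carlo sampling of the posterior Dirichlet.  The Bayes omnibus risk
(BOR) — the posterior probability that all models are equally frequent —
is computed by comparing the free energy of the random-effects model against
the null model in which every subject uses the same uniform frequency
vector, and the protected exceedance probability shrinks the exceedance
probabilities toward uniform accordingly:

    pxp = xp * (1 - bor) + bor / M
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

__all__ = ["BMSResult", "bms"]


@dataclass
class BMSResult:
    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray
    xp: np.ndarray
    bor: float
    pxp: np.ndarray
    model_names: tuple[str, ...] = ()
    free_energy_rfx: float = float("nan")
    free_energy_null: float = float("nan")

    def winner(self) -> int:
        """Index of the model with the highest protected exceedance
        probability."""
        return int(np.argmax(self.pxp))


def _log_beta_fn(alpha: np.ndarray) -> float:
    return float(np.sum(gammaln(alpha)) - gammaln(np.sum(alpha)))


def _vb_dirichlet(lme: np.ndarray, alpha0: np.ndarray, tol: float,
                  max_iter: int = 10_000):
    """Variational Bayes for the random-effects model.

    Returns (alpha, g, free_energy): posterior Dirichlet concentration,
    subject-wise posterior model assignment probabilities, and the
    variational free energy (evidence lower bound) of the random-effects
    model.
    """
    n, m = lme.shape
    alpha = alpha0.copy()
    g = np.full((n, m), 1.0 / m)
    for _ in range(max_iter):
        e_log_r = digamma(alpha) - digamma(alpha.sum())
        log_u = lme + e_log_r
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    # ELBO: E_q[log p(y,z,r)] - E_q[log q(z,r)]
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy_z = -np.sum(np.where(g > 0, g * np.log(g), 0.0))
    f = (
        float(np.sum(g * (lme + e_log_r)))
        + entropy_z
        + _log_beta_fn(alpha) - _log_beta_fn(alpha0)
        + float(np.sum((alpha0 - alpha) * e_log_r))
    )
    return alpha, g, f


def bms(log_evidence: np.ndarray, n_mc_samples: int = 1_000_000,
        seed: int = 0, tol: float = 1e-6,
        model_names: tuple[str, ...] = ()) -> BMSResult:
    """Random-effects model selection on a subjects x models evidence matrix.

    Raises ``ValueError`` on non-finite evidences or fewer than two models.
    Invariant to adding a per-subject constant to a row (only within-subject
    evidence differences matter).
    """
    lme = np.asarray(log_evidence, dtype=float)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("log_evidence must be a subjects x models matrix "
                         "with >= 2 models")
    if not np.all(np.isfinite(lme)):
        raise ValueError("log model evidences must be finite")
    n, m = lme.shape
    # per-subject normalization for numerical stability (no effect on result)
    lme = lme - lme.max(axis=1, keepdims=True)

    alpha0 = np.ones(m)
    alpha, g, f_rfx = _vb_dirichlet(lme, alpha0, tol)
    expected_freq = alpha / alpha.sum()

    # Null model: every subject uses the fixed uniform frequency vector.
    f_null = float(np.sum(logsumexp(lme, axis=1) - np.log(m)))

    # BOR: posterior probability of the null given equal prior odds.
    bor = float(1.0 / (1.0 + np.exp(f_rfx - f_null)))

    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=int(n_mc_samples))
    xp = np.bincount(np.argmax(samples, axis=1), minlength=m) / len(samples)

    pxp = xp * (1.0 - bor) + bor / m
    return BMSResult(
        dirichlet_alpha=alpha,
        expected_freq=expected_freq,
        xp=xp,
        bor=bor,
        pxp=pxp,
        model_names=tuple(model_names),
        free_energy_rfx=f_rfx,
        free_energy_null=f_null,
    )
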