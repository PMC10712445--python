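"""The five candidate model architectures and their free parameters.

The model space crosses two perceptual models (2-level and 3-level binary
HGF) with two response models (softmax; uncertainty-dependent unit-square
sigmoid), plus a Rescorla-Wagner + softmax control:

    ==========  ===========  ============  ==============================
    name        perceptual   response      free parameters
    ==========  ===========  ============  ==============================
    2L_sm       2-level HGF  softmax       w2_c, w2_n, beta_c, beta_n
    2L_us       2-level HGF  unit-square   w2_c, w2_n
    3L_sm       3-level HGF  softmax       w2_c, w2_n, w3_c, w3_n, beta_c, beta_n
    3L_us       3-level HGF  unit-square   w2_c, w2_n, w3_c, w3_n
    RW_sm       R-W          softmax       alpha, beta
    ==========  ===========  ============  ==============================

Each free parameter carries a Gaussian prior in *estimation space* — the
space in which the optimizer works — reached through its transform (identity
for evolution rates, log for decision noise, logit for the learning rate).
The coupling ``kappa`` and the initial belief states are fixed, not
estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .hgf import HGFParams
from .responses import ResponseParams, RWParams

__all__ = ["ParamSpec", "ModelSpec", "MODEL_REGISTRY", "get_model"]


@dataclass(frozen=True)
class ParamSpec:
    """One free parameter: its transform and estimation-space prior."""

    name: str
    transform: str  # identity | log | logit
    prior_mean: float
    prior_sd: float

    def to_natural(self, x: float) -> float:
        if self.transform == "identity":
            return x
        if self.transform == "log":
            return math.exp(x)
        if self.transform == "logit":
            return 1.0 / (1.0 + math.exp(-x))
        raise ValueError(f"unknown transform {self.transform!r}")

    def to_estimation(self, v: float) -> float:
        if self.transform == "identity":
            return v
        if self.transform == "log":
            return math.log(v)
        if self.transform == "logit":
            return math.log(v / (1.0 - v))
        raise ValueError(f"unknown transform {self.transform!r}")


# Default priors: wide and conventional for this model family.  The
# level-3 evolution-rate prior is centred at -6 (slow volatility drift).
_W2 = dict(transform="identity", prior_mean=-3.0, prior_sd=4.0)
_W3 = dict(transform="identity", prior_mean=-6.0, prior_sd=4.0)
_LOGBETA = dict(transform="log", prior_mean=0.0, prior_sd=2.0)
_LOGITALPHA = dict(transform="logit", prior_mean=0.0, prior_sd=1.0)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate architecture: perceptual model, response model, and the
    list of free parameters with their priors."""

    name: str
    perceptual: str  # 2level | 3level | rw
    response: str  # softmax | unit_square
    params: tuple[ParamSpec, ...]
    fixed_hgf: HGFParams = field(default_factory=HGFParams)

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)

    def prior_mean_vector(self) -> np.ndarray:
        return np.array([p.prior_mean for p in self.params])

    def prior_sd_vector(self) -> np.ndarray:
        return np.array([p.prior_sd for p in self.params])

    def natural_from_vector(self, theta: np.ndarray) -> dict[str, float]:
        """Map an estimation-space vector to named natural-space values."""
        return {p.name: p.to_natural(float(x)) for p, x in zip(self.params, theta)}

    def vector_from_natural(self, values: dict[str, float]) -> np.ndarray:
        return np.array([p.to_estimation(values[p.name]) for p in self.params])

    def build_agent(self, values: dict[str, float]):
        """Assemble (agent_params, response_params) from natural-space values.

        For HGF models ``agent_params`` is a dict with per-condition
        :class:`HGFParams`; for the Rescorla-Wagner control it is
        :class:`RWParams` (which doubles as the response parameters).
        """
        if self.perceptual == "rw":
            rw = RWParams(alpha=values["alpha"], beta=values["beta"])
            return rw, rw
        n_levels = 2 if self.perceptual == "2level" else 3
        base = replace(self.fixed_hgf, n_levels=n_levels)
        par_c = replace(base, omega2=values["omega2_choice"],
                        omega3=values.get("omega3_choice", base.omega3))
        par_n = replace(base, omega2=values["omega2_nochoice"],
                        omega3=values.get("omega3_nochoice", base.omega3))
        agent = {"Choice": par_c, "noChoice": par_n}
        if self.response == "softmax":
            resp = ResponseParams(beta_choice=values["beta_choice"],
                                  beta_nochoice=values["beta_nochoice"])
        else:
            resp = ResponseParams()  # unit-square link has no free parameter
        return agent, resp

    def validate_agent(self, agent_params, response_params) -> None:
        if self.perceptual == "rw":
            if not isinstance(agent_params, RWParams):
                raise TypeError(f"model {self.name} requires RWParams")
            return
        if not (isinstance(agent_params, dict)
                and set(agent_params) == {"Choice", "noChoice"}):
            raise TypeError(
                f"model {self.name} requires per-condition HGFParams "
                "{'Choice': ..., 'noChoice': ...}"
            )
        want = 2 if self.perceptual == "2level" else 3
        for cond, p in agent_params.items():
            if not isinstance(p, HGFParams) or p.n_levels != want:
                raise TypeError(
                    f"model {self.name}: {cond} params must be "
                    f"{want}-level HGFParams"
                )
        if self.response == "softmax" and not isinstance(response_params,
                                                         ResponseParams):
            raise TypeError(f"model {self.name} requires ResponseParams")


def _spec(name, perceptual, response, param_defs) -> ModelSpec:
    return ModelSpec(
        name=name, perceptual=perceptual, response=response,
        params=tuple(ParamSpec(n, **kw) for n, kw in param_defs),
    )


MODEL_REGISTRY: dict[str, ModelSpec] = {
    m.name: m
    for m in [
        _spec("2L_sm", "2level", "softmax", [
            ("omega2_choice", _W2), ("omega2_nochoice", _W2),
            ("beta_choice", _LOGBETA), ("beta_nochoice", _LOGBETA),
        ]),
        _spec("2L_us", "2level", "unit_square", [
            ("omega2_choice", _W2), ("omega2_nochoice", _W2),
        ]),
        _spec("3L_sm", "3level", "softmax", [
            ("omega2_choice", _W2), ("omega2_nochoice", _W2),
            ("omega3_choice", _W3), ("omega3_nochoice", _W3),
            ("beta_choice", _LOGBETA), ("beta_nochoice", _LOGBETA),
        ]),
        _spec("3L_us", "3level", "unit_square", [
            ("omega2_choice", _W2), ("omega2_nochoice", _W2),
            ("omega3_choice", _W3), ("omega3_nochoice", _W3),
        ]),
        _spec("RW_sm", "rw", "softmax", [
            ("alpha", _LOGITALPHA), ("beta", _LOGBETA),
        ]),
    ]
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registry: {sorted(MODEL_REGISTRY)}"
        ) from None
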