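"""Six reinforcement-learning models for the two-option reversal task.

All models share a Rescorla-Wagner delta-rule core — the chosen option's value
moves toward the received outcome by a fraction eta of the prediction error —
and a softmax (inverse-logit) choice rule weighting the value difference by an
inverse temperature beta in (0, 10).  The variants are:

====================  =========================  =================================
model_id              parameters                 distinguishing feature
====================  =========================  =================================
RW                    eta, beta                  single learning rate
RP                    eta_pos, eta_neg, beta     separate reward/punishment rates
EWA                   phi, rho, beta             experience-weighted attraction
FU                    eta, beta                  fictitious update of the unchosen
FU_RP                 eta_pos, eta_neg, beta     fictitious + reward/punish rates
FU_RP_IP              eta_pos, eta_neg, beta,    fictitious + reward/punish +
                      alpha                      indecision point in the softmax
====================  =========================  =================================

Outcomes are coded +1 (coin) / -1 (cross); the two options' outcomes are
anti-correlated, so the fictitious outcome for the unchosen option is -O.
Learning rates, phi and rho live in (0, 1); beta in (0, 10); alpha is
unbounded.  Values start at 0 and, for the delta-rule models, remain inside
[-1, 1] by convexity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

__all__ = [
    "MODELS",
    "MODEL_IDS",
    "ModelSpec",
    "AgentState",
    "ParameterError",
    "update_state",
    "choice_probability",
    "simulate_agent",
    "log_likelihood",
]


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    param_names: tuple[str, ...]
    #: (lower, upper); None marks an unbounded side
    bounds: tuple[tuple[float | None, float | None], ...]
    code: int  # integer tag used by the numba kernels

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def validate(self, params: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        """Return the parameter vector in canonical order, checking bounds."""
        if isinstance(params, Mapping):
            missing = set(self.param_names) - set(params)
            if missing:
                raise ParameterError(f"{self.model_id}: missing parameters {sorted(missing)}")
            vec = np.array([float(params[p]) for p in self.param_names])
        else:
            vec = np.asarray(params, dtype=float)
            if vec.shape != (self.n_params,):
                raise ParameterError(
                    f"{self.model_id} expects {self.n_params} parameters "
                    f"({', '.join(self.param_names)}), got shape {vec.shape}"
                )
        for name, value, (lo, hi) in zip(self.param_names, vec, self.bounds):
            # closed at the edges: the degenerate limits (eta = 0 or 1, beta = 0)
            # are well defined; the hierarchical priors keep draws interior
            if (lo is not None and value < lo) or (hi is not None and value > hi):
                raise ParameterError(
                    f"{self.model_id}: {name}={value} outside bounds [{lo}, {hi}]"
                )
        return vec


class ParameterError(ValueError):
    """A parameter vector violates its model's bounds."""


_UNIT = (0.0, 1.0)
_BETA = (0.0, 10.0)
_FREE = (None, None)

MODELS: dict[str, ModelSpec] = {
    "RW": ModelSpec("RW", ("eta", "beta"), (_UNIT, _BETA), 0),
    "RP": ModelSpec("RP", ("eta_pos", "eta_neg", "beta"), (_UNIT, _UNIT, _BETA), 1),
    "EWA": ModelSpec("EWA", ("phi", "rho", "beta"), (_UNIT, _UNIT, _BETA), 2),
    "FU": ModelSpec("FU", ("eta", "beta"), (_UNIT, _BETA), 3),
    "FU_RP": ModelSpec("FU_RP", ("eta_pos", "eta_neg", "beta"), (_UNIT, _UNIT, _BETA), 4),
    "FU_RP_IP": ModelSpec(
        "FU_RP_IP", ("eta_pos", "eta_neg", "beta", "alpha"), (_UNIT, _UNIT, _BETA, _FREE), 5
    ),
}
MODEL_IDS = tuple(MODELS)


def get_model(model: str | ModelSpec) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    key = str(model).upper().replace("-", "_")
    if key not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_IDS}")
    return MODELS[key]


@dataclass
class AgentState:
    """Evolving option values (and, for EWA, experience weights)."""

    values: np.ndarray = field(default_factory=lambda: np.zeros(2))
    experience_weights: np.ndarray = field(default_factory=lambda: np.ones(2))

    def copy(self) -> "AgentState":
        return AgentState(self.values.copy(), self.experience_weights.copy())


def update_state(
    spec: ModelSpec | str,
    params: Mapping[str, float] | Sequence[float],
    state: AgentState,
    choice: int,
    outcome: int,
    *,
    fictitious_pe: str = "unchosen",
    rate_select: str = "factual",
) -> AgentState:
    """One learning step; returns a new state, the input is untouched.

    ``fictitious_pe`` selects whose prior value enters the unchosen option's
    prediction error for the fictitious-update family: the unchosen option's
    own value (``"unchosen"``, the standard rule and default) or the chosen
    option's (``"chosen"``, the variant printed with the model equations,
    retained for comparison).  ``rate_select`` selects the learning rate of the
    FU_RP-family unchosen update by the sign of the obtained outcome
    (``"factual"``, default) or of the fictitious outcome (``"per-option"``).
    """
    spec = get_model(spec)
    vec = spec.validate(params)
    if choice not in (1, 2):
        raise ValueError(f"choice must be 1 or 2, got {choice!r}")
    if outcome not in (1, -1):
        raise ValueError(f"outcome must be +1 or -1, got {outcome!r}")
    if fictitious_pe not in ("unchosen", "chosen"):
        raise ValueError("fictitious_pe must be 'unchosen' or 'chosen'")
    if rate_select not in ("factual", "per-option"):
        raise ValueError("rate_select must be 'factual' or 'per-option'")

    new = state.copy()
    c, o = choice - 1, 2 - choice
    V = new.values
    vc_prev = V[c]

    if spec.model_id == "RW":
        eta, _ = vec
        V[c] += eta * (outcome - V[c])
    elif spec.model_id == "RP":
        eta_pos, eta_neg, _ = vec
        rate = eta_pos if outcome > 0 else eta_neg
        V[c] += rate * (outcome - V[c])
    elif spec.model_id == "EWA":
        phi, rho, _ = vec
        n_prev = new.experience_weights[c]
        n_new = n_prev * rho + 1.0
        V[c] = (V[c] * phi * n_prev + outcome) / n_new
        new.experience_weights[c] = n_new
    elif spec.model_id == "FU":
        eta, _ = vec
        V[c] += eta * (outcome - V[c])
        ref = vc_prev if fictitious_pe == "chosen" else V[o]
        V[o] += eta * (-outcome - ref)
    else:  # FU_RP, FU_RP_IP
        eta_pos, eta_neg = vec[0], vec[1]
        rate_c = eta_pos if outcome > 0 else eta_neg
        if rate_select == "factual":
            rate_o = rate_c
        else:
            rate_o = eta_pos if -outcome > 0 else eta_neg
        V[c] += rate_c * (outcome - V[c])
        ref = vc_prev if fictitious_pe == "chosen" else V[o]
        V[o] += rate_o * (-outcome - ref)
    return new


def choice_probability(
    spec: ModelSpec | str,
    params: Mapping[str, float] | Sequence[float],
    state: AgentState,
) -> float:
    """Probability of choosing option 1 under the model's softmax rule."""
    spec = get_model(spec)
    vec = spec.validate(params)
    d = state.values[0] - state.values[1]
    beta = vec[spec.param_names.index("beta")]
    if spec.model_id == "FU_RP_IP":
        alpha = vec[spec.param_names.index("alpha")]
        return float(expit(beta * (d - alpha)))
    return float(expit(beta * d))


def simulate_agent(
    spec: ModelSpec | str,
    params: Mapping[str, float] | Sequence[float],
    schedule,
    rng: np.random.Generator | int | None = None,
    **update_kwargs,
) -> pd.DataFrame:
    """Forward-simulate one agent on one block.

    Per trial: evaluate the choice probability from the current state, draw the
    choice, resolve the outcome on the schedule, then learn.  Returns one row
    per trial with columns trial (1-based), choice, outcome, p1 and correct.
    """
    spec = get_model(spec)
    spec.validate(params)
    rng = np.random.default_rng(rng)
    state = AgentState()
    rows = np.empty((schedule.n_trials, 3), dtype=np.int64)
    p1s = np.empty(schedule.n_trials)
    for t in range(schedule.n_trials):
        p1 = choice_probability(spec, params, state)
        choice = 1 if rng.random() < p1 else 2
        outcome = schedule.outcome_for(t, choice)
        state = update_state(spec, params, state, choice, outcome, **update_kwargs)
        rows[t] = (t + 1, choice, outcome)
        p1s[t] = p1
    frame = pd.DataFrame(rows, columns=["trial", "choice", "outcome"])
    frame["p1"] = p1s
    frame["correct"] = (frame["choice"].to_numpy() == schedule.correct_option).astype(int)
    return frame


def log_likelihood(
    spec: ModelSpec | str,
    params: Mapping[str, float] | Sequence[float],
    choices: Sequence[int],
    outcomes: Sequence[int],
    *,
    return_pointwise: bool = False,
    trials: Sequence[int] | None = None,
    **update_kwargs,
):
    """Log-likelihood of an ordered choice/outcome sequence for one
    subject-condition.

    Missing responses (choice == 0) contribute no likelihood term and trigger
    no state update.  The per-trial vector (0.0 on missing trials) is available
    for LOO-based model comparison via ``return_pointwise``.
    """
    spec = get_model(spec)
    vec = spec.validate(params)
    choices = np.asarray(choices, dtype=int)
    outcomes = np.asarray(outcomes, dtype=int)
    if choices.shape != outcomes.shape or choices.ndim != 1:
        raise ValueError("choices and outcomes must be 1-d and equally long")
    if trials is not None:
        trials = np.asarray(trials)
        if len(trials) != len(choices) or np.any(np.diff(trials) <= 0):
            raise ValueError("trial indices must be strictly increasing and match data length")
    observed = choices != 0
    bad = choices[~np.isin(choices, (0, 1, 2))]
    if bad.size:
        raise ValueError(f"choices must be 0 (missing), 1 or 2; found {bad[:5]}")
    if not observed.any():
        warnings.warn("all trials missing; log-likelihood is an empty sum (0.0)")
    if np.any(~np.isin(outcomes[observed], (1, -1))):
        raise ValueError("outcomes on non-missing trials must be +1 or -1")

    beta = vec[spec.param_names.index("beta")]
    alpha = vec[spec.param_names.index("alpha")] if spec.model_id == "FU_RP_IP" else 0.0
    state = AgentState()
    pointwise = np.zeros(len(choices))
    for t, (choice, outcome) in enumerate(zip(choices, outcomes)):
        if choice == 0:
            continue
        d = state.values[0] - state.values[1]
        # log sigma(m): numerically stable log-logistic form
        m = beta * ((d - alpha) if choice == 1 else (alpha - d))
        pointwise[t] = log_expit(m)
        state = update_state(spec, vec, state, int(choice), int(outcome), **update_kwargs)
    total = float(pointwise.sum())
    if return_pointwise:
        return total, pointwise
    return total
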