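"""Delta-rule + soft-max reinforcement learning with an explicit reward weight.

The agent learns option values by the delta rule and chooses by soft-max.
On top of the classical (alpha, beta) parameterization, the model carries a
reward weight gamma that converts externally presented reward points into
internal value: the internal value trace is V = gamma * W, where W is the
delta-rule trace on the raw reward scale,

    W[i, t+1] = W[i, t] + alpha * (r_t - W[i, t])        (chosen option only)

and the choice rule applies the inverse temperature to the value expressed
per unit of weighted reward,

    P_i = exp(beta * V_i / gamma) / sum_n exp(beta * V_n / gamma)
        = softmax((beta / gamma) * W).

Behavior therefore depends on alpha and on the *ratio* beta/gamma only:
(beta, gamma) and (k*beta, k*gamma) generate identical choice probabilities
for every k > 0.  The scale parameters are unidentified unless one of them
is fixed; the learning rate alpha is identified regardless.  Fitting with
gamma = 1 returns beta-hat = beta/gamma; fitting with beta = 1 returns
gamma-hat = gamma/beta, the reciprocal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_softmax, logit, softmax

__all__ = [
    "RLParams",
    "BanditTask",
    "RLData",
    "RLFit",
    "FitFailureError",
    "update_value",
    "choice_probabilities",
    "simulate_agent",
    "log_likelihood",
    "fit",
]


class FitFailureError(RuntimeError):
    """No restart of the likelihood optimization converged."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class RLParams:
    """(alpha, beta, gamma) with initial value v0 on the internal scale."""

    alpha: float
    beta: float
    gamma: float = 1.0
    v0: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


@dataclass(frozen=True)
class BanditTask:
    """An N-armed bandit with Bernoulli rewards scaled by a magnitude.

    Defaults are the package's reference task: two arms, reward
    probabilities (0.8, 0.2), unit reward magnitude, 200 trials.
    """

    n_options: int = 2
    reward_prob: Sequence[float] = (0.8, 0.2)
    reward_magnitude: Sequence[float] = (1.0, 1.0)
    n_trials: int = 200

    def __post_init__(self) -> None:
        if self.n_options < 2:
            raise ValueError("need at least two options")
        if len(self.reward_prob) != self.n_options:
            raise ValueError("reward_prob length must equal n_options")
        if len(self.reward_magnitude) != self.n_options:
            raise ValueError("reward_magnitude length must equal n_options")
        if any(not (0.0 <= p <= 1.0) for p in self.reward_prob):
            raise ValueError("reward probabilities must lie in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class RLData:
    """Observed choice/reward sequence, optionally with the value trace.

    ``value_trace[t, i]`` is the *internal* value (gamma-weighted scale) of
    option i immediately before the choice on trial t.
    """

    choices: np.ndarray
    rewards: np.ndarray
    n_options: int
    value_trace: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        choices = np.asarray(self.choices, dtype=np.int64)
        rewards = np.asarray(self.rewards, dtype=float)
        if choices.shape != rewards.shape or choices.ndim != 1:
            raise ValueError("choices and rewards must be equal-length 1-D arrays")
        if choices.size and (choices.min() < 0 or choices.max() >= self.n_options):
            raise ValueError("choices must lie in [0, n_options)")
        object.__setattr__(self, "choices", choices)
        object.__setattr__(self, "rewards", rewards)

    @property
    def n_trials(self) -> int:
        return int(self.choices.size)


@dataclass(frozen=True)
class RLFit:
    """Result of maximum-likelihood fitting."""

    params: RLParams
    log_lik: float
    fixed: str
    n_restarts_used: int
    converged: bool


def update_value(v: float, r: float, alpha: float, gamma: float = 1.0) -> float:
    """One delta-rule step on the internal value scale.

    Returns ``(1 - alpha) * v + alpha * gamma * r``: the reward weight gamma
    converts the external reward into internal value before the prediction
    error is formed.  Callers update only the chosen option.
    """
    return (1.0 - alpha) * v + alpha * gamma * r


def choice_probabilities(values: np.ndarray, beta: float) -> np.ndarray:
    """Soft-max choice probabilities with a max-subtraction guard.

    ``beta = 0`` yields uniform probabilities whatever the values.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    return softmax(beta * values)


def _reward_scale_trace(
    choices: np.ndarray, rewards: np.ndarray, n_options: int, alpha: float, w0: float
) -> np.ndarray:
    """Delta-rule trace on the raw reward scale; row t = values before trial t."""
    n = choices.size
    trace = np.empty((n, n_options), dtype=float)
    w = np.full(n_options, w0, dtype=float)
    for t in range(n):
        trace[t] = w
        i = choices[t]
        w[i] = w[i] + alpha * (rewards[t] - w[i])
    return trace


def simulate_agent(task: BanditTask, params: RLParams, seed: Optional[int] = None) -> RLData:
    """Simulate one agent on ``task``; reproducible under ``seed``.

    Choices are sampled from the soft-max of the current values; the reward
    for the chosen option is Bernoulli(prob) * magnitude.  Because behavior
    depends on beta/gamma only, two parameter sets with an equal ratio and
    the same seed produce identical choice/reward sequences.
    """
    rng = np.random.default_rng(seed)
    probs = np.asarray(task.reward_prob, dtype=float)
    mags = np.asarray(task.reward_magnitude, dtype=float)
    scale = params.beta / params.gamma

    choices = np.empty(task.n_trials, dtype=np.int64)
    rewards = np.empty(task.n_trials, dtype=float)
    trace = np.empty((task.n_trials, task.n_options), dtype=float)
    w = np.full(task.n_options, params.v0 / params.gamma, dtype=float)
    for t in range(task.n_trials):
        trace[t] = params.gamma * w  # stored on the internal scale
        p = softmax(scale * w)
        c = int(rng.choice(task.n_options, p=p))
        r = mags[c] * float(rng.random() < probs[c])
        w[c] = w[c] + params.alpha * (r - w[c])
        choices[t] = c
        rewards[t] = r
    return RLData(choices=choices, rewards=rewards, n_options=task.n_options, value_trace=trace)


def log_likelihood(data: RLData, params: RLParams) -> float:
    """Summed log probability of the observed choices under ``params``.

    The value trace is reconstructed from ``data.rewards``; the soft-max
    weight is beta/gamma, so the result is exactly invariant under
    (beta, gamma) -> (k*beta, k*gamma).
    """
    trace = _reward_scale_trace(
        data.choices, data.rewards, data.n_options, params.alpha, params.v0 / params.gamma
    )
    scale = params.beta / params.gamma
    logp = log_softmax(scale * trace, axis=1)
    return float(logp[np.arange(data.n_trials), data.choices].sum())


def _fit_objective(data: RLData, fixed: str, v0: float):
    def nll(x: np.ndarray) -> float:
        alpha = float(expit(x[0]))
        scale = float(math.exp(x[1]))
        beta, gamma = (scale, 1.0) if fixed == "gamma" else (1.0, scale)
        try:
            params = RLParams(alpha=alpha, beta=beta, gamma=gamma, v0=v0)
        except ValueError:
            return np.inf
        return -log_likelihood(data, params)

    return nll


def fit(
    data: RLData,
    fixed: Literal["gamma", "beta"] = "gamma",
    n_restarts: int = 10,
    seed: Optional[int] = None,
    v0: float = 0.0,
    tol: float = 1e-8,
) -> RLFit:
    """Maximum-likelihood fit of (alpha, free scale) with one scale fixed at 1.

    ``fixed="gamma"`` estimates (alpha, beta) with gamma = 1;
    ``fixed="beta"`` estimates (alpha, gamma) with beta = 1.  alpha is
    optimized on a logit scale and the free scale parameter on a log scale,
    by Nelder-Mead from ``n_restarts`` random starts (plus one default
    start).  Because only beta/gamma is identified, the two fixing choices
    return reciprocal scale estimates and the same alpha.
    """
    if fixed not in ("gamma", "beta"):
        raise ValueError(f"fixed must be 'gamma' or 'beta', got {fixed!r}")
    if data.n_options < 2:
        raise ValueError("need at least two options")
    rng = np.random.default_rng(seed)
    nll = _fit_objective(data, fixed, v0)

    starts = [np.array([logit(0.3), 0.0])]
    for _ in range(n_restarts):
        starts.append(
            np.array([logit(rng.uniform(0.05, 0.95)), rng.uniform(math.log(0.1), math.log(10.0))])
        )

    best = None
    n_ok = 0
    diagnostics = []
    for x0 in starts:
        res = minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": tol, "fatol": tol, "maxiter": 2000},
        )
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
        else:
            diagnostics.append({"x0": x0.tolist(), "message": res.message})
    if best is None:
        raise FitFailureError(
            "all restarts produced a non-finite objective",
            {"n_restarts": len(starts), "failures": diagnostics},
        )

    alpha = float(expit(best.x[0]))
    scale = float(math.exp(best.x[1]))
    beta, gamma = (scale, 1.0) if fixed == "gamma" else (1.0, scale)
    return RLFit(
        params=RLParams(alpha=alpha, beta=beta, gamma=gamma, v0=v0),
        log_lik=-float(best.fun),
        fixed=fixed,
        n_restarts_used=len(starts),
        converged=bool(n_ok > 0),
    )
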