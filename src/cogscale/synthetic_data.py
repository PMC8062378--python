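"""Synthetic populations for the scaling-constraint correlation analyses.

Three generators, one per model family, each emitting a :class:`Population`
that keeps the generating ("true") parameters next to the simulated data so
recovery can be checked:

* an SDT detection population in which an external factor F in [-1, 1]
  drives the decision cutoff: per participant
  c ~ U(F-0.1, F+0.1), d' ~ U(0.9, 1.1), s ~ U(0.7, 1.3),
  with 200 trials (half noise, half target) scored against the cutoff;
* bandit agents with (alpha, beta) drawn per participant and the reward
  weight gamma fixed or drawn - the identified quantity beta/gamma is kept
  as the population factor;
* an LBA population whose threshold (or another chosen parameter) is
  linked to an external covariate m ("temporal precision"):
  m = intercept + slope * parameter + noise, with multiplicative log-normal
  individual differences on the linked parameter.

All generators are deterministic under a fixed seed (child streams are
spawned per participant) and respect every stated parameter bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .lba import LBAParams, LBATrialSet, simulate_lba
from .rl import BanditTask, RLData, RLParams, simulate_agent
from .sdt import CUTOFF, DetectionCounts, SDTParams

__all__ = [
    "SDTPopulationSpec",
    "RLPopulationSpec",
    "LBAPopulationSpec",
    "Population",
    "simulate_detection",
    "generate_sdt_population",
    "generate_rl_population",
    "generate_lba_population",
]


@dataclass(frozen=True)
class Population:
    """Per-participant true parameters, data, and the external factor."""

    kind: str
    params: Tuple
    data: Tuple
    factor: np.ndarray
    factor_name: str = "F"

    def __post_init__(self) -> None:
        factor = np.asarray(self.factor, dtype=float)
        if not (len(self.params) == len(self.data) == factor.size):
            raise ValueError("params, data and factor must have one entry per participant")
        if factor.size and not np.all(np.isfinite(factor)):
            raise ValueError("factor values must be finite")
        object.__setattr__(self, "factor", factor)

    @property
    def n_participants(self) -> int:
        return len(self.params)


@dataclass(frozen=True)
class SDTPopulationSpec:
    """Design of the SDT detection population (defaults are the reference design)."""

    n_participants: int = 20
    n_trials: int = 200
    f_values: Optional[Sequence[float]] = None  # default: equally spaced on [-1, 1]
    criterion_jitter: float = 0.1
    d_prime_range: Tuple[float, float] = (0.9, 1.1)
    sigma_range: Tuple[float, float] = (0.7, 1.3)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if self.n_trials < 2 or self.n_trials % 2:
            raise ValueError("n_trials must be even and >= 2")
        if self.sigma_range[0] <= 0:
            raise ValueError("sigma must stay positive")

    def resolved_f(self) -> np.ndarray:
        if self.f_values is not None:
            f = np.asarray(self.f_values, dtype=float)
            if f.size != self.n_participants:
                raise ValueError("f_values length must equal n_participants")
            return f
        if self.n_participants == 1:
            return np.zeros(1)
        return np.linspace(-1.0, 1.0, self.n_participants)


@dataclass(frozen=True)
class RLPopulationSpec:
    """Design of the bandit-agent population."""

    n_participants: int = 20
    task: BanditTask = field(default_factory=BanditTask)
    alpha_range: Tuple[float, float] = (0.1, 0.5)
    beta_range: Tuple[float, float] = (1.0, 5.0)
    gamma: float = 1.0
    gamma_range: Optional[Tuple[float, float]] = None  # overrides gamma when set
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass(frozen=True)
class LBAPopulationSpec:
    """Design of the LBA population with an external covariate m.

    ``m = link_intercept + link_slope * (linked parameter) + N(0, link_noise_sd)``;
    the linked parameter receives multiplicative log-normal individual
    differences with SD ``id_sd`` (on the log scale), other parameters may be
    perturbed too via ``perturb_others``.
    """

    n_participants: int = 30
    n_trials: int = 1000
    base_params: LBAParams = field(
        default_factory=lambda: LBAParams(A=0.5, B=1.0, v1=3.0, v2=1.5, s1=1.0, s2=1.0, t0=0.2)
    )
    linked_parameter: str = "B"
    link_intercept: float = 1.5
    link_slope: float = -1.0
    link_noise_sd: float = 0.05
    id_sd: float = 0.15
    perturb_others: Tuple[str, ...] = ()
    other_sd: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_trials < 1:
            raise ValueError("need at least one participant and one trial")
        if self.link_noise_sd < 0 or self.id_sd < 0 or self.other_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        valid = {"A", "B", "v1", "v2", "s1", "s2", "t0"}
        if self.linked_parameter not in valid:
            raise ValueError(f"unknown linked parameter {self.linked_parameter!r}")
        if any(p not in valid for p in self.perturb_others):
            raise ValueError("perturb_others contains an unknown parameter name")


def simulate_detection(
    params: SDTParams, n_trials: int, seed: Optional[int] = None
) -> DetectionCounts:
    """Score a yes/no detection run of ``n_trials`` (half noise, half target).

    Noise samples come from N(0, s) and target samples from N(d', s); a
    sample strictly above the cutoff is a detection (false alarm / hit), a
    sample at or below it a non-detection (ties score as non-detections;
    this is a measure-zero event).
    """
    if n_trials < 2 or n_trials % 2:
        raise ValueError("n_trials must be even and >= 2")
    rng = np.random.default_rng(seed)
    half = n_trials // 2
    cutoff = params.cutoff
    noise = rng.normal(0.0, params.sigma, size=half)
    target = rng.normal(params.d_prime, params.sigma, size=half)
    fa = int(np.sum(noise > cutoff))
    hits = int(np.sum(target > cutoff))
    return DetectionCounts(
        hits=hits, misses=half - hits, false_alarms=fa, correct_rejections=half - fa
    )


def generate_sdt_population(spec: SDTPopulationSpec) -> Population:
    """Draw per-participant (c, d', s) given F and simulate detection counts."""
    f = spec.resolved_f()
    ss = np.random.SeedSequence(spec.seed)
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(spec.n_participants)
    params, data = [], []
    for i in range(spec.n_participants):
        c = draw_rng.uniform(f[i] - spec.criterion_jitter, f[i] + spec.criterion_jitter)
        d = draw_rng.uniform(*spec.d_prime_range)
        s = draw_rng.uniform(*spec.sigma_range)
        p = SDTParams(d_prime=d, criterion=c, sigma=s, anchor=CUTOFF)
        params.append(p)
        data.append(simulate_detection(p, spec.n_trials, seed=child_seeds[i]))
    return Population(kind="sdt", params=tuple(params), data=tuple(data),
                      factor=f, factor_name="F")


def generate_rl_population(spec: RLPopulationSpec) -> Population:
    """Draw per-participant (alpha, beta[, gamma]) and simulate bandit runs.

    The population factor is the identified scale ratio beta/gamma.
    """
    ss = np.random.SeedSequence(spec.seed)
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(spec.n_participants)
    params, data, factor = [], [], []
    for i in range(spec.n_participants):
        alpha = draw_rng.uniform(*spec.alpha_range)
        beta = draw_rng.uniform(*spec.beta_range)
        gamma = (
            draw_rng.uniform(*spec.gamma_range) if spec.gamma_range is not None else spec.gamma
        )
        p = RLParams(alpha=alpha, beta=beta, gamma=gamma)
        params.append(p)
        data.append(simulate_agent(spec.task, p, seed=child_seeds[i]))
        factor.append(beta / gamma)
    return Population(kind="rl", params=tuple(params), data=tuple(data),
                      factor=np.array(factor), factor_name="beta/gamma")


def _perturbed(base: LBAParams, name: str, factor: float) -> LBAParams:
    return replace(base, **{name: getattr(base, name) * factor})


def generate_lba_population(spec: LBAPopulationSpec) -> Population:
    """Perturb the base parameters per participant, derive m, simulate trials.

    Participants whose perturbed parameters are invalid (e.g. B < A) are
    redrawn; with the default ranges this is essentially never triggered.
    """
    ss = np.random.SeedSequence(spec.seed)
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(spec.n_participants)
    params, data, m_values = [], [], []
    for i in range(spec.n_participants):
        for _ in range(100):
            p = spec.base_params
            if spec.id_sd > 0:
                p = _perturbed(p, spec.linked_parameter,
                               math.exp(draw_rng.normal(0.0, spec.id_sd)))
            for name in spec.perturb_others:
                p = _perturbed(p, name, math.exp(draw_rng.normal(0.0, spec.other_sd)))
            try:
                LBAParams(**{n: getattr(p, n) for n in ("A", "B", "v1", "v2", "s1", "s2", "t0")})
            except ValueError:
                continue
            break
        else:
            raise RuntimeError("could not draw valid perturbed parameters")
        linked = getattr(p, spec.linked_parameter)
        m = spec.link_intercept + spec.link_slope * linked
        if spec.link_noise_sd > 0:
            m += draw_rng.normal(0.0, spec.link_noise_sd)
        params.append(p)
        m_values.append(m)
        data.append(simulate_lba(p, spec.n_trials, seed=child_seeds[i]))
    return Population(kind="lba", params=tuple(params), data=tuple(data),
                      factor=np.array(m_values), factor_name="m")
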