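"""Linear ballistic accumulator: densities, likelihood, simulation, fitting,
and post-hoc rescaling under alternative scaling constraints.

Two accumulators race linearly to a threshold B.  Per trial, accumulator i
starts at k ~ U[0, A] and rises with a fixed drift sampled from N(v_i, s_i);
the first to reach B determines the choice, and the response time is the
finishing time plus a non-decision offset t0.  The five shared parameters
(A, B) and per-accumulator (v_i, s_i) carry an arbitrary evidence unit E:
multiplying all of (A, B, v1, v2, s1, s2) by k > 0 leaves the predicted
choice/RT distribution - and hence the likelihood of any data set - exactly
unchanged.  Fits without a scaling constraint therefore return one point on
this ridge; fixing s1 = 1 (or post-hoc dividing by s1, s2, v1+v2 or B)
selects a point and fixes the units of everything else.

Drift rates are parameterized as positive (they are log-transformed for
fitting); trials on which both sampled drifts are non-positive would never
finish and are redrawn in simulation, with the analytic defective densities
renormalized by 1 - P(both non-positive) whenever that probability exceeds
1e-6, keeping simulation and likelihood consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtr

_SQRT2PI = math.sqrt(2.0 * math.pi)


def _npdf(z):
    """Standard normal density (low-overhead; hot path)."""
    return np.exp(-0.5 * np.square(z)) / _SQRT2PI

__all__ = [
    "LBAParams",
    "LBATrialSet",
    "LBAFit",
    "RescaledLBAParams",
    "FitFailureError",
    "lba_cdf_one",
    "lba_pdf_one",
    "defective_pdf",
    "response_probability",
    "neg_log_likelihood",
    "transform_params",
    "untransform_params",
    "fit_lba",
    "simulate_lba",
    "rescale_params",
]

#: density floor applied before taking logs in the likelihood
DENSITY_FLOOR = 1e-10
#: both-negative-drift probability above which defective densities are renormalized
RENORM_THRESHOLD = 1e-6
#: |scaling denominator| below this flags (but does not refuse) a rescaling
DEFAULT_DENOMINATOR_GUARD = 0.05

RESCALE_CHOICES = ("s1", "s2", "v_sum", "B")


class FitFailureError(RuntimeError):
    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class LBAParams:
    """Five-parameter, two-accumulator LBA parameter set.

    A: start-point range (evidence units E); B: threshold (E, B >= A);
    v1, v2: mean drift rates of the correct/incorrect accumulators (E/s);
    s1, s2: drift-rate SDs (E/s); t0: non-decision time (seconds).
    """

    A: float
    B: float
    v1: float
    v2: float
    s1: float
    s2: float
    t0: float

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError(f"A must be >= 0, got {self.A}")
        if self.B <= 0:
            raise ValueError(f"B must be > 0, got {self.B}")
        if self.B < self.A:
            raise ValueError(f"need B >= A, got B={self.B} < A={self.A}")
        if self.s1 <= 0 or self.s2 <= 0:
            raise ValueError("drift-rate SDs must be > 0")
        if self.t0 < 0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        for name in ("A", "B", "v1", "v2", "s1", "s2", "t0"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def scaled(self, k: float) -> "LBAParams":
        """All evidence-scale parameters multiplied by k; t0 untouched."""
        if k <= 0:
            raise ValueError("scale factor must be > 0")
        return LBAParams(self.A * k, self.B * k, self.v1 * k, self.v2 * k,
                         self.s1 * k, self.s2 * k, self.t0)

    def drift_params(self, index: int) -> tuple[float, float]:
        if index == 1:
            return self.v1, self.s1
        if index == 2:
            return self.v2, self.s2
        raise ValueError(f"accumulator index must be 1 or 2, got {index}")

    @property
    def p_none_finish(self) -> float:
        """Probability that both sampled drifts are non-positive."""
        return float(ndtr(-self.v1 / self.s1) * ndtr(-self.v2 / self.s2))


@dataclass(frozen=True)
class LBATrialSet:
    """Choice (1=correct accumulator, 2=incorrect) and RT (seconds) per trial."""

    rt: np.ndarray
    choice: np.ndarray

    def __post_init__(self) -> None:
        rt = np.asarray(self.rt, dtype=float)
        choice = np.asarray(self.choice, dtype=np.int64)
        if rt.shape != choice.shape or rt.ndim != 1:
            raise ValueError("rt and choice must be equal-length 1-D arrays")
        if rt.size and rt.min() <= 0:
            raise ValueError("all response times must be > 0")
        if rt.size and not np.all(np.isin(choice, (1, 2))):
            raise ValueError("choices must be 1 or 2")
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "choice", choice)

    @property
    def n_trials(self) -> int:
        return int(self.rt.size)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.choice == 1)) if self.rt.size else float("nan")


@dataclass(frozen=True)
class LBAFit:
    params: LBAParams
    neg_log_lik: float
    n_restarts_used: int
    converged: bool
    constraint: str = "none"


@dataclass(frozen=True)
class RescaledLBAParams:
    """Parameters divided by a scaling quantity, with unit labels.

    The scaling quantity equals 1 in ``params`` (v1 + v2 = 1 for "v_sum");
    t0 is carried over unchanged.
    """

    params: LBAParams
    scaled_by: str
    unit_labels: Mapping[str, str] = field(default_factory=dict)
    small_denominator: bool = False


# ---------------------------------------------------------------------------
# single-accumulator first-passage distribution (start U[0,A], drift N(v,s))
# ---------------------------------------------------------------------------

_A_EPS = 1e-9  # below this, use the A -> 0 limiting forms


def _validate_one(A: float, b: float, s: float) -> None:
    if A < 0 or b <= 0 or b < A or s <= 0:
        raise ValueError(
            f"invalid accumulator parameters: A={A}, b={b}, s={s} (need b >= A >= 0, s > 0)"
        )


def lba_cdf_one(t, A: float, b: float, v: float, s: float):
    """P(a single accumulator has reached threshold b by time t).

    Vectorized over t; clipped to [0, 1].  t <= 0 gives 0 (the threshold
    sits above the start range).
    """
    _validate_one(A, b, s)
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    if A < _A_EPS:
        out[pos] = ndtr((v - b / tp) / s)
    else:
        ts = tp * s
        z1 = (b - A - tp * v) / ts
        z2 = (b - tp * v) / ts
        out[pos] = (
            1.0
            + (b - A - tp * v) / A * ndtr(z1)
            - (b - tp * v) / A * ndtr(z2)
            + ts / A * _npdf(z1)
            - ts / A * _npdf(z2)
        )
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def lba_pdf_one(t, A: float, b: float, v: float, s: float):
    """First-passage density of a single accumulator (1/seconds); 0 for t <= 0."""
    _validate_one(A, b, s)
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    if A < _A_EPS:
        out[pos] = (b / tp**2) * _npdf((b / tp - v) / s) / s
    else:
        ts = tp * s
        z1 = (b - A - tp * v) / ts
        z2 = (b - tp * v) / ts
        out[pos] = (
            -v * ndtr(z1) + s * _npdf(z1) + v * ndtr(z2) - s * _npdf(z2)
        ) / A
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def defective_pdf(t, params: LBAParams, winner: int):
    """Density of responding with ``winner`` at time t (jointly with the
    other accumulator not having finished).

    0 for t <= t0.  Renormalized by 1 - P(both drifts non-positive) when
    that probability exceeds ``RENORM_THRESHOLD``, matching the rejection
    rule used by :func:`simulate_lba`.
    """
    loser = 2 if winner == 1 else 1
    vw, sw = params.drift_params(winner)
    vl, sl = params.drift_params(loser)
    t = np.asarray(t, dtype=float)
    u = t - params.t0
    out = np.zeros_like(u)
    pos = u > 0
    up = u[pos]
    dens = lba_pdf_one(up, params.A, params.B, vw, sw) * (
        1.0 - lba_cdf_one(up, params.A, params.B, vl, sl)
    )
    p_none = params.p_none_finish
    if p_none > RENORM_THRESHOLD:
        dens = dens / (1.0 - p_none)
    out[pos] = dens
    return out if out.ndim else float(out)


def response_probability(params: LBAParams, winner: int) -> float:
    """Total probability of a ``winner`` response (integral of its defective density)."""
    upper = params.t0 + 50.0 * params.B / max(min(params.v1, params.v2), 1e-3)
    val, _ = quad(lambda t: defective_pdf(t, params, winner), params.t0, upper, limit=200)
    return float(val)


def neg_log_likelihood(trials: LBATrialSet, params: LBAParams) -> float:
    """-sum log defective density, with densities floored at ``DENSITY_FLOOR``.

    Exactly invariant under joint multiplication of (A, B, v1, v2, s1, s2)
    by k > 0 with t0 fixed (the scaling ridge).
    """
    total = 0.0
    for winner in (1, 2):
        mask = trials.choice == winner
        if not mask.any():
            continue
        dens = defective_pdf(trials.rt[mask], params, winner)
        total -= float(np.log(np.maximum(dens, DENSITY_FLOOR)).sum())
    return total


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_FREE_NAMES = ("A", "B", "v1", "v2", "s1", "s2")


def transform_params(params: LBAParams, min_rt: float) -> np.ndarray:
    """Map parameters to an unconstrained vector for optimization.

    (A, B, v1, v2, s1, s2) are log-transformed (hence strictly positive in
    this parameterization - mean drifts cannot be negative); t0 is mapped
    through the inverse of ``t0 = min_rt * logistic(x)``.  Round-trips with
    :func:`untransform_params` to better than 1e-12.
    """
    if min_rt <= 0:
        raise ValueError("min_rt must be > 0")
    vals = [getattr(params, n) for n in _FREE_NAMES]
    if any(v <= 0 for v in vals):
        raise ValueError("log transform requires A, B, v1, v2, s1, s2 > 0")
    if not (0.0 < params.t0 < min_rt):
        raise ValueError(f"t0 must lie strictly inside (0, min_rt={min_rt})")
    return np.array([*map(math.log, vals), float(logit(params.t0 / min_rt))])


def untransform_params(x: np.ndarray, min_rt: float) -> LBAParams:
    """Inverse of :func:`transform_params`."""
    if min_rt <= 0:
        raise ValueError("min_rt must be > 0")
    a, b, v1, v2, s1, s2 = map(math.exp, x[:6])
    t0 = min_rt * float(expit(x[6]))
    return LBAParams(A=a, B=b, v1=v1, v2=v2, s1=s1, s2=s2, t0=t0)


def _raw_nll(rt: np.ndarray, choice: np.ndarray, A, B, v1, v2, s1, s2, t0) -> float:
    """Objective on raw values: +big penalty outside the valid region."""
    if B < A:
        return 1e10 + 1e6 * (A - B)
    try:
        params = LBAParams(A=A, B=B, v1=v1, v2=v2, s1=s1, s2=s2, t0=t0)
    except ValueError:
        return np.inf
    total = 0.0
    for winner in (1, 2):
        mask = choice == winner
        if not mask.any():
            continue
        vw, sw = (v1, s1) if winner == 1 else (v2, s2)
        vl, sl = (v2, s2) if winner == 1 else (v1, s1)
        u = rt[mask] - t0
        dens = np.zeros_like(u)
        pos = u > 0
        if pos.any():
            d = lba_pdf_one(u[pos], A, B, vw, sw) * (1.0 - lba_cdf_one(u[pos], A, B, vl, sl))
            p_none = params.p_none_finish
            if p_none > RENORM_THRESHOLD:
                d = d / (1.0 - p_none)
            dens[pos] = d
        total -= float(np.log(np.maximum(dens, DENSITY_FLOOR)).sum())
    return total


def _start_vector(trials: LBATrialSet, rng: np.random.Generator, min_rt: float) -> np.ndarray:
    """Random start in transformed space around data-informed heuristics."""
    mean_rt = float(trials.rt.mean())
    t0_c = 0.9 * min_rt
    dec = max(mean_rt - t0_c, 0.05)
    v1_c, v2_c, s2_c = 2.0, 1.0, 1.0
    b_c = dec * v1_c
    a_c = 0.5 * b_c
    jitter = lambda c: math.log(c) + rng.uniform(-0.7, 0.7)
    x = np.array([
        jitter(a_c), jitter(b_c), jitter(v1_c), jitter(v2_c),
        jitter(1.0), jitter(s2_c),
        float(logit(rng.uniform(0.3, 0.95))),
    ])
    if x[0] > x[1]:  # keep the start inside B >= A
        x[0] = x[1] - 0.1
    return x


def fit_lba(
    trials: LBATrialSet,
    n_restarts: int = 500,
    seed: Optional[int] = None,
    constraint: Literal["none", "s1"] = "none",
    maxiter: int = 2000,
    fatol: float = 1e-8,
) -> LBAFit:
    """Maximum-likelihood LBA fit by multi-restart Nelder-Mead.

    Optimization runs in the transformed space of :func:`transform_params`
    (log scales, logistic t0).  With ``constraint="none"`` the returned
    parameters are one point on the scaling ridge - only their ratios are
    identified; with ``constraint="s1"`` the ridge is removed by fixing
    s1 = 1.  Start values are drawn log-uniform around data-informed
    heuristics; the best objective over all restarts wins.
    """
    if constraint not in ("none", "s1"):
        raise ValueError(f"unknown constraint {constraint!r}")
    if trials.n_trials < 2:
        raise ValueError("need at least two trials")
    rng = np.random.default_rng(seed)
    min_rt = float(trials.rt.min())
    rt, choice = trials.rt, trials.choice
    s1_fixed = constraint == "s1"

    if s1_fixed:
        idx = [0, 1, 2, 3, 5, 6]  # drop the log s1 coordinate

        def objective(z: np.ndarray) -> float:
            a, b, v1, v2, s2 = map(math.exp, z[:5])
            t0 = min_rt * float(expit(z[5]))
            return _raw_nll(rt, choice, a, b, v1, v2, 1.0, s2, t0)
    else:
        idx = list(range(7))

        def objective(z: np.ndarray) -> float:
            a, b, v1, v2, s1, s2 = map(math.exp, z[:6])
            t0 = min_rt * float(expit(z[6]))
            return _raw_nll(rt, choice, a, b, v1, v2, s1, s2, t0)

    best = None
    n_ok = 0
    failures = []
    for _ in range(n_restarts):
        x0 = _start_vector(trials, rng, min_rt)[idx]
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxiter": maxiter, "fatol": fatol, "xatol": 1e-4},
        )
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
        else:
            failures.append({"x0": x0.tolist(), "message": str(res.message)})
    if best is None:
        raise FitFailureError(
            "all restarts produced a non-finite objective",
            {"n_restarts": n_restarts, "failures": failures[:10]},
        )

    z = best.x
    if s1_fixed:
        a, b, v1, v2, s2 = map(math.exp, z[:5])
        params = LBAParams(A=min(a, b), B=b, v1=v1, v2=v2, s1=1.0, s2=s2,
                           t0=min_rt * float(expit(z[5])))
    else:
        a, b, v1, v2, s1, s2 = map(math.exp, z[:6])
        params = LBAParams(A=min(a, b), B=b, v1=v1, v2=v2, s1=s1, s2=s2,
                           t0=min_rt * float(expit(z[6])))
    return LBAFit(
        params=params,
        neg_log_lik=float(best.fun),
        n_restarts_used=n_restarts,
        converged=bool(n_ok > 0),
        constraint=constraint,
    )


def simulate_lba(params: LBAParams, n: int, seed: Optional[int] = None) -> LBATrialSet:
    """Simulate n (choice, RT) trials; reproducible under ``seed``.

    Per trial each accumulator gets a start k ~ U[0, A] and a drift
    ~ N(v_i, s_i); a non-positive drift never finishes.  Trials on which
    neither accumulator would finish are redrawn (see module notes).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params.p_none_finish > 0.999:
        raise ValueError("both drifts are almost surely non-positive; simulation cannot finish")
    rng = np.random.default_rng(seed)
    rt = np.empty(n, dtype=float)
    choice = np.empty(n, dtype=np.int64)
    pending = np.arange(n)
    means = np.array([params.v1, params.v2])
    sds = np.array([params.s1, params.s2])
    for _ in range(1000):
        m = pending.size
        if m == 0:
            break
        starts = rng.uniform(0.0, params.A, size=(m, 2)) if params.A > 0 else np.zeros((m, 2))
        drifts = rng.normal(means, sds, size=(m, 2))
        with np.errstate(divide="ignore"):
            finish = np.where(drifts > 0, (params.B - starts) / drifts, np.inf)
        tmin = finish.min(axis=1)
        done = np.isfinite(tmin)
        idx = pending[done]
        rt[idx] = tmin[done] + params.t0
        choice[idx] = finish[done].argmin(axis=1) + 1
        pending = pending[~done]
    else:
        raise RuntimeError("rejection sampling failed to terminate")
    return LBATrialSet(rt=rt, choice=choice)


_UNIT_LABELS = {
    # dividing by a drift-rate SD (units E/s)
    "s1": {"A": "E/(E/s)", "B": "E/(E/s)", "v1": "signal-to-noise", "v2": "signal-to-noise",
           "s1": "signal-to-noise", "s2": "signal-to-noise", "t0": "s"},
    "s2": {"A": "E/(E/s)", "B": "E/(E/s)", "v1": "signal-to-noise", "v2": "signal-to-noise",
           "s1": "signal-to-noise", "s2": "signal-to-noise", "t0": "s"},
    # dividing by the summed mean drift (units E/s)
    "v_sum": {"A": "E/(E/s)", "B": "E/(E/s)", "v1": "signal-to-noise", "v2": "signal-to-noise",
              "s1": "signal-to-noise", "s2": "signal-to-noise", "t0": "s"},
    # dividing by the threshold (units E): drifts become threshold distances
    # per second, i.e. a frequency 1/s
    "B": {"A": "E/E", "B": "E/E", "v1": "1/s", "v2": "1/s",
          "s1": "1/s", "s2": "1/s", "t0": "s"},
}


def rescale_params(
    params: LBAParams,
    by: Literal["s1", "s2", "v_sum", "B"],
    denominator_guard: float = DEFAULT_DENOMINATOR_GUARD,
) -> RescaledLBAParams:
    """Divide all evidence-scale parameters by a scaling quantity; t0 unchanged.

    The predicted RT distribution (and hence the likelihood of any data
    set) is identical before and after - rescaling only moves along the
    ridge and relabels the units.  The scaling quantity is set to exactly 1
    in the output (v1 + v2 = 1 for "v_sum").
    """
    if by not in RESCALE_CHOICES:
        raise ValueError(f"unknown rescale choice {by!r}; options: {RESCALE_CHOICES}")
    denom = {
        "s1": params.s1, "s2": params.s2, "v_sum": params.v1 + params.v2, "B": params.B,
    }[by]
    if denom == 0.0:
        raise ZeroDivisionError(f"scaling quantity {by} is exactly 0")
    if denom < 0:
        raise ValueError(f"scaling quantity {by} is negative ({denom}); cannot rescale")
    new = LBAParams(
        A=params.A / denom, B=params.B / denom,
        v1=params.v1 / denom, v2=params.v2 / denom,
        s1=params.s1 / denom, s2=params.s2 / denom,
        t0=params.t0,
    )
    # pin the scaled quantity exactly
    if by == "s1":
        new = replace(new, s1=1.0)
    elif by == "s2":
        new = replace(new, s2=1.0)
    elif by == "B":
        new = replace(new, B=1.0)
    else:
        v1 = params.v1 / denom
        new = replace(new, v1=v1, v2=1.0 - v1)
    return RescaledLBAParams(
        params=new,
        scaled_by=by,
        unit_labels=_UNIT_LABELS[by],
        small_denominator=abs(denom) < denominator_guard,
    )
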