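"""Equal-variance signal detection theory with an explicit noise-SD parameter.

The model: noise evidence ~ N(0, sigma), signal evidence ~ N(d_prime, sigma),
and the observer reports "signal" whenever the evidence sample exceeds a
cutoff on the evidence axis.  The three parameters (d_prime, criterion,
sigma) are identified only up to a common multiplicative scale: multiplying
all of them by k > 0 leaves the hit and false-alarm rates unchanged.  A
scaling constraint (conventionally sigma = 1) pins the scale; every estimate
is then interpretable only *relative* to the constrained parameter, which is
what the unit labels attached to estimates record (e.g. "c/s" when sigma is
the constraint).

Criterion anchoring
-------------------
Two anchorings of the criterion are in common use and both appear here,
explicitly:

* ``"cutoff"`` - the absolute location of the decision cutoff on the
  evidence axis, measured from the noise mean.  This is the natural
  generative parameter (a sample is a hit/false alarm when it exceeds it).
* ``"centered"`` - the criterion measured from the midpoint between the
  noise and signal means, the quantity the classical estimator
  ``c = -(Z(HR) + Z(FAR))/2`` returns.  cutoff = d'/2 + c.

:class:`SDTParams` defaults to the cutoff anchor; :class:`SDTEstimate` is
always centered.  :func:`forward_rates` converts exactly, so estimation and
the forward model round-trip to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Optional, Union

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "SDTParams",
    "RatePair",
    "DetectionCounts",
    "ConstraintSpec",
    "SDTEstimate",
    "DegenerateRateError",
    "InfeasibleConstraintError",
    "rates_from_counts",
    "forward_rates",
    "estimate_standard",
    "refit_under_constraint",
    "rescale_estimate",
    "unit_labels_for",
]

CUTOFF = "cutoff"
CENTERED = "centered"
#: sign conventions for the centered criterion estimator.
#: "standard": c = -(Z(HR)+Z(FAR))/2 (increases with a more conservative
#: observer); "negated": c = +(Z(HR)+Z(FAR))/2, the mirror-image sign that
#: some sources print.
CONVENTIONS = ("standard", "negated")

PARAM_NAMES = ("d_prime", "criterion", "sigma")
_SHORT = {"d_prime": "d'", "criterion": "c", "sigma": "s"}

#: |denominator| below this (in the source parameter's units) flags, but does
#: not refuse, a rescaling.  Rescaling onto a near-zero parameter is legal -
#: the c = 1 constraint divides by a criterion that crosses zero in perfectly
#: reasonable populations - but the resulting values blow up, so downstream
#: correlation analyses exclude flagged participants.
DEFAULT_DENOMINATOR_GUARD = 0.05


class DegenerateRateError(ValueError):
    """A hit or false-alarm rate of exactly 0 or 1 cannot be Z-transformed."""


class InfeasibleConstraintError(ValueError):
    """The requested scaling constraint has no solution for these rates."""


def _check_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class SDTParams:
    """Generative SDT parameter triple.

    ``criterion`` is interpreted according to ``anchor`` (see module notes);
    the default cutoff anchor matches the generative recipe where a sample
    above ``criterion`` is scored as a detection.
    """

    d_prime: float
    criterion: float
    sigma: float = 1.0
    anchor: Literal["cutoff", "centered"] = CUTOFF

    def __post_init__(self) -> None:
        _check_finite(d_prime=self.d_prime, criterion=self.criterion, sigma=self.sigma)
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.anchor not in (CUTOFF, CENTERED):
            raise ValueError(f"unknown criterion anchor {self.anchor!r}")

    @property
    def cutoff(self) -> float:
        """Absolute decision cutoff on the evidence axis."""
        if self.anchor == CUTOFF:
            return self.criterion
        return self.d_prime / 2.0 + self.criterion


@dataclass(frozen=True)
class RatePair:
    """Hit and false-alarm rates, optionally with the trial counts behind them."""

    hr: float
    far: float
    n_signal: Optional[int] = None
    n_noise: Optional[int] = None

    def __post_init__(self) -> None:
        for name, rate in (("hr", self.hr), ("far", self.far)):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        for name, n in (("n_signal", self.n_signal), ("n_noise", self.n_noise)):
            if n is not None and n < 1:
                raise ValueError(f"{name} must be >= 1, got {n}")

    def require_interior(self) -> None:
        if not (0.0 < self.hr < 1.0 and 0.0 < self.far < 1.0):
            raise DegenerateRateError(
                f"rates must lie strictly inside (0, 1), got hr={self.hr}, far={self.far}"
            )


@dataclass(frozen=True)
class DetectionCounts:
    """Scored trial counts from a yes/no detection task."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.hits + self.misses < 1:
            raise ValueError("need at least one signal trial")
        if self.false_alarms + self.correct_rejections < 1:
            raise ValueError("need at least one noise trial")

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class ConstraintSpec:
    """A scaling constraint: fix one named parameter to a constant."""

    which: Literal["d_prime", "criterion", "sigma"]
    value: float = 1.0

    def __post_init__(self) -> None:
        if self.which not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.which!r}")
        if self.value == 0:
            raise ValueError("a scaling constraint of 0 collapses the model")

    @property
    def label(self) -> str:
        return f"{self.which}={self.value:g}"


def unit_labels_for(which: str) -> Mapping[str, str]:
    """Ratio unit labels for estimates under the constraint fixing ``which``."""
    denom = _SHORT[which]
    return {p: f"{_SHORT[p]}/{denom}" for p in PARAM_NAMES}


@dataclass(frozen=True)
class SDTEstimate:
    """An estimated (d', c, s) triple under an explicit scaling constraint.

    The criterion is centered (midpoint-anchored) with the sign given by
    ``convention``.  ``unit_labels`` record what each number means relative
    to the constrained parameter.
    """

    d_prime: float
    criterion: float
    sigma: float
    constraint: ConstraintSpec
    convention: Literal["standard", "negated"] = "standard"
    unit_labels: Mapping[str, str] = field(default_factory=dict)
    small_denominator: bool = False

    def __post_init__(self) -> None:
        _check_finite(d_prime=self.d_prime, criterion=self.criterion, sigma=self.sigma)
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")
        pinned = getattr(self, self.constraint.which)
        if pinned != self.constraint.value:
            raise ValueError(
                f"constrained parameter {self.constraint.which} is {pinned}, "
                f"expected exactly {self.constraint.value}"
            )
        if not (
            math.isfinite(self.d_prime / self.sigma)
            and math.isfinite(self.criterion / self.sigma)
        ):
            raise ValueError("d_prime/sigma and criterion/sigma must be finite")

    @property
    def criterion_standard(self) -> float:
        """Centered criterion in the standard sign, whatever the convention."""
        return self.criterion if self.convention == "standard" else -self.criterion

    @property
    def cutoff(self) -> float:
        return self.d_prime / 2.0 + self.criterion_standard

    def as_params(self) -> SDTParams:
        """The generative parameter triple this estimate describes."""
        return SDTParams(self.d_prime, self.cutoff, self.sigma, anchor=CUTOFF)


def rates_from_counts(
    counts: DetectionCounts,
    edge_policy: Literal["half_count", "error"] = "half_count",
) -> RatePair:
    """Convert scored counts to rates, handling 0/1 rates per ``edge_policy``.

    Under ``half_count``, a rate of 0 or 1 for a trial type with N trials is
    replaced by 1/(2N) or 1 - 1/(2N).
    """
    hr = counts.hits / counts.n_signal
    far = counts.false_alarms / counts.n_noise
    if edge_policy == "half_count":
        if hr == 0.0:
            hr = 1.0 / (2 * counts.n_signal)
        elif hr == 1.0:
            hr = 1.0 - 1.0 / (2 * counts.n_signal)
        if far == 0.0:
            far = 1.0 / (2 * counts.n_noise)
        elif far == 1.0:
            far = 1.0 - 1.0 / (2 * counts.n_noise)
    elif edge_policy == "error":
        if hr in (0.0, 1.0) or far in (0.0, 1.0):
            raise DegenerateRateError(
                f"degenerate rate (hr={hr}, far={far}) with edge_policy='error'"
            )
    else:
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    return RatePair(hr=hr, far=far, n_signal=counts.n_signal, n_noise=counts.n_noise)


def forward_rates(params: Union[SDTParams, SDTEstimate]) -> RatePair:
    """Predicted (HR, FAR) for a parameter triple.

    With the absolute cutoff k = params.cutoff:
    ``HR = Phi((d' - k)/s)``, ``FAR = Phi(-k/s)``.  Accepts either a
    generative :class:`SDTParams` (any anchor) or an :class:`SDTEstimate`
    (centered; its convention is honoured), so estimates round-trip exactly.
    """
    if isinstance(params, SDTEstimate):
        d, k, s = params.d_prime, params.cutoff, params.sigma
        if s <= 0:
            raise ValueError(f"sigma must be > 0, got {s}")
    else:
        d, k, s = params.d_prime, params.cutoff, params.sigma
    hr = float(norm.cdf((d - k) / s))
    far = float(norm.cdf(-k / s))
    return RatePair(hr=hr, far=far)


def _zscores(rates: RatePair) -> tuple[float, float]:
    rates.require_interior()
    return float(norm.ppf(rates.hr)), float(norm.ppf(rates.far))


def estimate_standard(
    rates: RatePair,
    convention: Literal["standard", "negated"] = "standard",
) -> SDTEstimate:
    """Classical SDT estimation under the sigma = 1 scaling constraint.

    ``d' = Z(HR) - Z(FAR)``; the centered criterion is
    ``-(Z(HR)+Z(FAR))/2`` under the standard convention and its negation
    under ``"negated"``.
    """
    zh, zf = _zscores(rates)
    d_prime = zh - zf
    c_std = -(zh + zf) / 2.0
    criterion = c_std if convention == "standard" else -c_std
    return SDTEstimate(
        d_prime=d_prime,
        criterion=criterion,
        sigma=1.0,
        constraint=ConstraintSpec("sigma", 1.0),
        convention=convention,
        unit_labels=unit_labels_for("sigma"),
    )


def refit_under_constraint(
    rates: RatePair,
    constraint: ConstraintSpec,
    convention: Literal["standard", "negated"] = "standard",
    log_sigma_bounds: tuple[float, float] = (-5.0, 5.0),
    tol: float = 1e-14,
) -> SDTEstimate:
    """Re-estimate (d', c, s) with ``constraint`` fixed, by 1-D numerical
    inversion of the forward model over sigma.

    For the sigma constraint the solution is closed-form (the classical
    estimator rescaled).  For d' or criterion constraints, sigma is found by
    Brent root-finding on the signed Z-scale rate mismatch over
    ``log sigma`` in ``log_sigma_bounds`` (the residual is monotone in
    sigma), with the remaining free parameter solved in closed form from the
    false-alarm equation at each sigma.  The result reproduces the input
    rates exactly and agrees with :func:`rescale_estimate` of the standard
    estimate to numerical precision.
    """
    zh, zf = _zscores(rates)
    d_hat = zh - zf  # identified ratio d'/sigma
    c_hat = -(zh + zf) / 2.0  # identified ratio c/sigma (standard sign)

    which, value = constraint.which, constraint.value

    if which == "sigma":
        if value <= 0:
            raise InfeasibleConstraintError("sigma must be constrained to a positive value")
        d = value * d_hat
        c_std = value * c_hat
        sigma = value
    else:
        # target (standard-sign) value of the constrained parameter
        target = value
        if which == "criterion" and convention == "negated":
            target = -value
        identified = d_hat if which == "d_prime" else c_hat
        if identified == 0.0 or (target / identified) <= 0.0:
            reason = (
                "hr <= far implies d' <= 0" if which == "d_prime"
                else "these rates imply a criterion of the opposite sign"
            )
            raise InfeasibleConstraintError(
                f"cannot fix {which} to {value}: {reason}"
            )

        lo, hi = log_sigma_bounds

        if which == "d_prime":
            # given sigma, c from the FAR equation: Z(FAR) = -(d/2 + c)/sigma
            def residual(log_sigma: float) -> float:
                sigma = math.exp(log_sigma)
                # predicted Z(HR) with c solved from FAR: target/sigma + zf
                return (target / sigma + zf) - zh
        else:
            # given sigma, d' from the FAR equation with c fixed
            def residual(log_sigma: float) -> float:
                sigma = math.exp(log_sigma)
                return (-zf - 2.0 * target / sigma) - zh

        r_lo, r_hi = residual(lo), residual(hi)
        if r_lo == 0.0:
            log_sigma = lo
        elif r_hi == 0.0:
            log_sigma = hi
        elif r_lo * r_hi > 0:
            raise InfeasibleConstraintError(
                f"no sigma in e^[{lo}, {hi}] satisfies the {which}={value} constraint"
            )
        else:
            log_sigma = brentq(residual, lo, hi, xtol=tol, rtol=8.9e-16)
        sigma = math.exp(log_sigma)
        if which == "d_prime":
            d = target
            c_std = -sigma * zf - target / 2.0
        else:
            c_std = target
            d = -2.0 * (sigma * zf + target)

    criterion = c_std if convention == "standard" else -c_std
    est = SDTEstimate(
        d_prime=d,
        criterion=criterion,
        sigma=sigma,
        constraint=constraint,
        convention=convention,
        unit_labels=unit_labels_for(which),
    )
    # pin the constrained field bit-exactly (float noise from the solve)
    return replace(est, **{which: value})


def rescale_estimate(
    est: SDTEstimate,
    target: ConstraintSpec,
    denominator_guard: float = DEFAULT_DENOMINATOR_GUARD,
) -> SDTEstimate:
    """Analytically re-express an estimate under a different scaling constraint.

    All three parameters are divided by ``current / target.value`` where
    ``current`` is the present value of the parameter named by the target
    constraint.  The ratios d'/s, c/s and d'/c are untouched - rescaling
    moves the whole triple along the model's scaling ridge.  A source
    parameter with magnitude below ``denominator_guard`` sets the
    ``small_denominator`` flag on the output (rescaling onto a near-zero
    parameter is numerically explosive but not illegal).
    """
    current = getattr(est, target.which)
    if current == 0.0:
        raise ZeroDivisionError(
            f"cannot rescale onto {target.which}: its current estimate is exactly 0"
        )
    factor = current / target.value
    values = {p: getattr(est, p) / factor for p in PARAM_NAMES}
    values[target.which] = target.value  # exact, not current/factor
    # A negative factor (e.g. c = 1 when the estimated criterion is negative)
    # flips the signs of the other parameters, including sigma.  The result is
    # a formal re-expression, not a generative parameter set; it is kept, as
    # the c = 1 scenario analysis divides by the criterion regardless of sign.
    return SDTEstimate(
        d_prime=values["d_prime"],
        criterion=values["criterion"],
        sigma=values["sigma"],
        constraint=target,
        convention=est.convention,
        unit_labels=unit_labels_for(target.which),
        small_denominator=est.small_denominator or abs(current) < denominator_guard,
    )
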