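"""Scenario engine: one population, several scaling constraints, all the
behavior-parameter correlations.

The workflow this module automates: estimate each participant's parameters
once, re-express the estimates under every scaling constraint of interest
(each block of the resulting long-format table), and correlate every
parameter with the external factor within each block.  Because rescaling
moves estimates along the likelihood ridge, the blocks all describe the
same fitted model; only the *ratios* of parameters are identified, so any
correlation computed on a ratio is identical across blocks, while the
correlation of an individual parameter can change size and even sign from
block to block.  The constrained parameter itself has zero variance within
its block and its correlation is reported as undefined, not zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import lba as _lba
from . import sdt as _sdt
from .synthetic_data import (
    LBAPopulationSpec,
    Population,
    SDTPopulationSpec,
    generate_lba_population,
    generate_sdt_population,
)

__all__ = [
    "CorrelationResult",
    "SDT_DEFAULT_CONSTRAINTS",
    "apply_constraints",
    "correlate",
    "run_sdt_scenario",
    "run_lba_scenario",
    "scenario_summary",
    "plot_scenario",
]

logger = logging.getLogger(__name__)

#: the three classic SDT scaling constraints, in presentation order
SDT_DEFAULT_CONSTRAINTS = (
    _sdt.ConstraintSpec("sigma", 1.0),
    _sdt.ConstraintSpec("d_prime", 1.0),
    _sdt.ConstraintSpec("criterion", 1.0),
)

TABLE_COLUMNS = [
    "participant", "constraint", "parameter", "value", "unit_label", "factor", "flagged",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson (or Spearman) correlation of one parameter with the factor."""

    parameter: str
    constraint: str
    r: float
    t_stat: float
    p_value: float
    n: int
    defined: bool = True
    note: str = ""


def _sdt_rows(est: _sdt.SDTEstimate, participant, factor) -> list[dict]:
    return [
        {
            "participant": participant,
            "constraint": est.constraint.label,
            "parameter": name,
            "value": getattr(est, name),
            "unit_label": est.unit_labels.get(name, ""),
            "factor": factor,
            "flagged": est.small_denominator,
        }
        for name in _sdt.PARAM_NAMES
    ]


def _lba_rows(res: _lba.RescaledLBAParams, participant, factor) -> list[dict]:
    return [
        {
            "participant": participant,
            "constraint": res.scaled_by,
            "parameter": name,
            "value": getattr(res.params, name),
            "unit_label": res.unit_labels.get(name, ""),
            "factor": factor,
            "flagged": res.small_denominator,
        }
        for name in ("A", "B", "v1", "v2", "s1", "s2", "t0")
    ]


def apply_constraints(
    estimates: Sequence,
    constraints: Iterable,
    factor: Optional[Sequence[float]] = None,
    participants: Optional[Sequence] = None,
    denominator_guard: float = _sdt.DEFAULT_DENOMINATOR_GUARD,
) -> pd.DataFrame:
    """Build the long-format scenario table: one block per constraint.

    ``estimates`` is one per-participant estimate: :class:`~cogscale.sdt.SDTEstimate`
    objects with :class:`~cogscale.sdt.ConstraintSpec` constraints, or LBA
    fits / parameter sets with rescale choices ("s1", "s2", "v_sum", "B").
    A participant whose denominator for a given constraint is exactly zero
    is flagged and logged rather than dropped; flagged rows are excluded
    from correlations downstream.
    """
    if participants is None:
        participants = list(range(len(estimates)))
    if factor is None:
        factor = [math.nan] * len(estimates)
    if not (len(participants) == len(factor) == len(estimates)):
        raise ValueError("estimates, factor and participants must align")

    rows: list[dict] = []
    for constraint in constraints:
        for pid, est, f in zip(participants, estimates, factor):
            if isinstance(est, _lba.LBAFit):
                est_params = est.params
            else:
                est_params = est
            try:
                if isinstance(constraint, _sdt.ConstraintSpec):
                    rescaled = _sdt.rescale_estimate(est_params, constraint,
                                                    denominator_guard=denominator_guard)
                    rows.extend(_sdt_rows(rescaled, pid, f))
                else:
                    rescaled = _lba.rescale_params(est_params, constraint,
                                                  denominator_guard=denominator_guard)
                    rows.extend(_lba_rows(rescaled, pid, f))
            except ZeroDivisionError:
                logger.warning(
                    "participant %s: zero denominator under constraint %s; flagged",
                    pid, constraint,
                )
                label = constraint.label if isinstance(constraint, _sdt.ConstraintSpec) else constraint
                rows.append({
                    "participant": pid, "constraint": label, "parameter": "",
                    "value": math.nan, "unit_label": "", "factor": f, "flagged": True,
                })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def correlate(
    table: pd.DataFrame,
    method: Literal["pearson", "spearman"] = "pearson",
    min_n: int = 3,
) -> list[CorrelationResult]:
    """Correlate every (constraint, parameter) cell's values with the factor.

    Flagged participants are excluded per cell.  Cells with zero variance
    (the constrained parameter) are reported as undefined rather than 0; a
    factor with zero variance raises, since no correlation is defined at all.
    """
    results: list[CorrelationResult] = []
    usable = table[(~table["flagged"]) & (table["parameter"] != "")]
    for (constraint, parameter), cell in usable.groupby(["constraint", "parameter"], sort=False):
        x = cell["factor"].to_numpy(dtype=float)
        y = cell["value"].to_numpy(dtype=float)
        n = len(cell)
        if n < min_n:
            results.append(CorrelationResult(parameter, constraint, math.nan, math.nan,
                                             math.nan, n, False, f"fewer than {min_n} participants"))
            continue
        if np.ptp(x) == 0.0 or np.std(x) == 0.0:
            raise ValueError(f"factor has zero variance in block {constraint!r}")
        if np.ptp(y) == 0.0:
            results.append(CorrelationResult(parameter, constraint, math.nan, math.nan,
                                             math.nan, n, False, "constrained parameter (zero variance)"))
            continue
        if method == "pearson":
            r, p = stats.pearsonr(x, y)
        elif method == "spearman":
            r, p = stats.spearmanr(x, y)
        else:
            raise ValueError(f"unknown method {method!r}")
        r = float(r)
        denom = 1.0 - r * r
        t_stat = math.inf if denom <= 0 else r * math.sqrt((n - 2) / denom)
        results.append(CorrelationResult(parameter, constraint, r, t_stat, float(p), n))
    return results


def correlations_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def run_sdt_scenario(
    spec: Optional[SDTPopulationSpec] = None,
    constraints: Sequence[_sdt.ConstraintSpec] = SDT_DEFAULT_CONSTRAINTS,
    convention: Literal["standard", "negated"] = "standard",
    edge_policy: Literal["half_count", "error"] = "half_count",
    population: Optional[Population] = None,
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[pd.DataFrame, list[CorrelationResult]]:
    """Generate (or take) an SDT population, estimate each participant under
    every constraint, and correlate all parameters with F.

    One call reproduces the three-row scenario analysis: the same data set
    read under sigma = 1, d' = 1 and c = 1.
    """
    if population is None:
        population = generate_sdt_population(spec if spec is not None else SDTPopulationSpec())
    estimates = [
        _sdt.estimate_standard(_sdt.rates_from_counts(counts, edge_policy), convention)
        for counts in population.data
    ]
    table = apply_constraints(estimates, constraints, factor=population.factor)
    return table, correlate(table, method=method)


def run_lba_scenario(
    population: Population,
    rescale_choices: Sequence[str] = _lba.RESCALE_CHOICES,
    fit_constraint: Literal["none", "s1"] = "s1",
    n_restarts: int = 10,
    seed: Optional[int] = None,
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[pd.DataFrame, list[CorrelationResult], list[_lba.LBAFit]]:
    """Fit every participant, rescale the fits under each choice, correlate with m.

    Participants whose fit fails are excluded from the table and logged.
    Returns (table, correlations, fits); failed fits appear as None in the
    fits list.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(population.n_participants)
    fits: list[Optional[_lba.LBAFit]] = []
    for i, trials in enumerate(population.data):
        try:
            fits.append(_lba.fit_lba(trials, n_restarts=n_restarts,
                                     seed=child_seeds[i], constraint=fit_constraint))
        except _lba.FitFailureError as err:
            logger.warning("participant %d: fit failed (%s); excluded", i, err)
            fits.append(None)
    kept = [(i, f) for i, f in enumerate(fits) if f is not None]
    table = apply_constraints(
        [f for _, f in kept],
        rescale_choices,
        factor=[population.factor[i] for i, _ in kept],
        participants=[i for i, _ in kept],
    )
    return table, correlate(table, method=method), fits


def scenario_summary(table: pd.DataFrame, results: Sequence[CorrelationResult],
                     sig_digits: int = 6) -> pd.DataFrame:
    """Correlations as a tidy frame with values rounded to ``sig_digits``
    significant digits (full precision is kept in ``results``)."""
    frame = correlations_frame(list(results))
    def _round(v):
        if isinstance(v, float) and math.isfinite(v) and v != 0:
            return round(v, sig_digits - 1 - int(math.floor(math.log10(abs(v)))))
        return v
    for col in ("r", "t_stat", "p_value"):
        frame[col] = frame[col].map(_round)
    return frame


def plot_scenario(table: pd.DataFrame, path=None):
    """Panels of parameter vs factor, one row per constraint block.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    usable = table[(~table["flagged"]) & (table["parameter"] != "")]
    constraints = list(dict.fromkeys(usable["constraint"]))
    parameters = list(dict.fromkeys(usable["parameter"]))
    fig, axes = plt.subplots(
        len(constraints), len(parameters),
        figsize=(3 * len(parameters), 2.5 * len(constraints)),
        squeeze=False,
    )
    for i, constraint in enumerate(constraints):
        for j, parameter in enumerate(parameters):
            cell = usable[(usable["constraint"] == constraint)
                          & (usable["parameter"] == parameter)]
            ax = axes[i][j]
            ax.scatter(cell["factor"], cell["value"], s=12)
            if i == 0:
                ax.set_title(parameter)
            if j == 0:
                ax.set_ylabel(constraint)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
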