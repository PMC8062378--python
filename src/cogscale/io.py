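"""Delimited-text readers and writers for the package's tables.

Everything is plain CSV/TSV through pandas; population specs travel as
small YAML documents with a schema version.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .lba import LBAFit, LBATrialSet, RescaledLBAParams
from .rl import RLData
from .sdt import DetectionCounts, SDTEstimate

COUNT_COLUMNS = ["participant_id", "hits", "misses", "false_alarms", "correct_rejections"]
ESTIMATE_COLUMNS = [
    "participant_id", "constraint", "d_prime", "criterion", "sigma",
    "d_prime_unit", "criterion_unit", "sigma_unit", "flagged",
]
RL_COLUMNS = ["trial", "choice", "reward"]
LBA_TRIAL_COLUMNS = ["participant_id", "rt_seconds", "choice"]

SPEC_SCHEMA_VERSION = 1


def _read(path, sep: Optional[str]) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")


def read_count_table(path, sep: Optional[str] = None) -> pd.DataFrame:
    """Per-participant detection counts; validates columns and nonnegativity."""
    frame = _read(path, sep)
    missing = [c for c in COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"count table is missing columns: {missing}")
    for counts in counts_from_frame(frame):
        pass  # constructing DetectionCounts validates every row
    return frame[COUNT_COLUMNS]


def counts_from_frame(frame: pd.DataFrame) -> list[DetectionCounts]:
    return [
        DetectionCounts(int(r.hits), int(r.misses), int(r.false_alarms),
                        int(r.correct_rejections))
        for r in frame.itertuples()
    ]


def write_count_table(path, counts: Sequence[DetectionCounts],
                      participant_ids: Optional[Sequence] = None) -> None:
    if participant_ids is None:
        participant_ids = list(range(len(counts)))
    pd.DataFrame({
        "participant_id": participant_ids,
        "hits": [c.hits for c in counts],
        "misses": [c.misses for c in counts],
        "false_alarms": [c.false_alarms for c in counts],
        "correct_rejections": [c.correct_rejections for c in counts],
    }).to_csv(path, index=False)


def write_estimate_table(path, estimates: Sequence[SDTEstimate],
                         participant_ids: Optional[Sequence] = None) -> None:
    if participant_ids is None:
        participant_ids = list(range(len(estimates)))
    pd.DataFrame({
        "participant_id": participant_ids,
        "constraint": [e.constraint.label for e in estimates],
        "d_prime": [e.d_prime for e in estimates],
        "criterion": [e.criterion for e in estimates],
        "sigma": [e.sigma for e in estimates],
        "d_prime_unit": [e.unit_labels.get("d_prime", "") for e in estimates],
        "criterion_unit": [e.unit_labels.get("criterion", "") for e in estimates],
        "sigma_unit": [e.unit_labels.get("sigma", "") for e in estimates],
        "flagged": [e.small_denominator for e in estimates],
    }).to_csv(path, index=False)


def write_rl_data(path, data: RLData) -> None:
    pd.DataFrame({
        "trial": np.arange(data.n_trials),
        "choice": data.choices,
        "reward": data.rewards,
    }).to_csv(path, index=False)


def read_rl_data(path, n_options: int, sep: Optional[str] = None) -> RLData:
    frame = _read(path, sep)
    missing = [c for c in RL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"RL data table is missing columns: {missing}")
    frame = frame.sort_values("trial")
    return RLData(choices=frame["choice"].to_numpy(dtype=np.int64),
                  rewards=frame["reward"].to_numpy(dtype=float),
                  n_options=n_options)


def write_lba_trials(path, trials: LBATrialSet, participant_id=0) -> None:
    pd.DataFrame({
        "participant_id": participant_id,
        "rt_seconds": trials.rt,
        "choice": trials.choice,
    }).to_csv(path, index=False)


def read_lba_trials(path, sep: Optional[str] = None) -> dict[object, LBATrialSet]:
    """Trials keyed by participant_id (a single-participant file yields one entry)."""
    frame = _read(path, sep)
    missing = [c for c in LBA_TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"LBA trial table is missing columns: {missing}")
    out = {}
    for pid, grp in frame.groupby("participant_id", sort=False):
        out[pid] = LBATrialSet(rt=grp["rt_seconds"].to_numpy(dtype=float),
                               choice=grp["choice"].to_numpy(dtype=np.int64))
    return out


def write_lba_fit_table(path, fits: Sequence[LBAFit],
                        participant_ids: Optional[Sequence] = None) -> None:
    if participant_ids is None:
        participant_ids = list(range(len(fits)))
    rows = []
    for pid, f in zip(participant_ids, fits):
        row = {"participant_id": pid, "constraint": f.constraint,
               "neg_log_lik": f.neg_log_lik, "converged": f.converged,
               "n_restarts_used": f.n_restarts_used}
        row.update({n: getattr(f.params, n) for n in ("A", "B", "v1", "v2", "s1", "s2", "t0")})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_rescaled_lba_table(path, rescaled: Sequence[RescaledLBAParams],
                             participant_ids: Optional[Sequence] = None) -> None:
    if participant_ids is None:
        participant_ids = list(range(len(rescaled)))
    rows = []
    for pid, r in zip(participant_ids, rescaled):
        row = {"participant_id": pid, "scaled_by": r.scaled_by, "flagged": r.small_denominator}
        for n in ("A", "B", "v1", "v2", "s1", "s2", "t0"):
            row[n] = getattr(r.params, n)
            row[f"{n}_unit"] = r.unit_labels.get(n, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_population_truths(path, population) -> None:
    """True per-participant parameters and the external factor, as CSV."""
    rows = []
    for i, p in enumerate(population.params):
        row = {"participant_id": i, population.factor_name: population.factor[i]}
        for name, value in vars(p).items():
            if isinstance(value, (int, float)):
                row[name] = value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_spec(path, spec_mapping: dict) -> None:
    doc = {"schema_version": SPEC_SCHEMA_VERSION, **spec_mapping}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_spec(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("spec file must be a YAML mapping")
    version = doc.pop("schema_version", SPEC_SCHEMA_VERSION)
    if version != SPEC_SCHEMA_VERSION:
        raise ValueError(f"unsupported spec schema_version {version}")
    return doc
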