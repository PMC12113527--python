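"""Eligibility filters, transport-interval delta features, and splits.

Filtering follows the study-eligibility flow: records missing a key
variable at either assessment are excluded first, then records whose
vitals lie outside physiological plausibility bounds (strict
inequalities: SBP or DBP > 300 mmHg, BT > 50 or < 20 degC, PR > 300
/min, RR > 50 /min, SpO2 > 100 or < 30 %).  Both assessments are held to
the bounds: an implausible value at either invalidates the pair used for
delta features.  Filters never mutate records; every stage returns
(kept, excluded) partitions and the flow is summarized by
:func:`exclusion_flow`.

Delta features are prehospital minus in-hospital, so a positive d_pr is
a pulse-rate *decrease* during transport.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fieldtriage.errors import ConfigError, ValidationError
from fieldtriage.records import VITALS, PatientRecord

log = logging.getLogger(__name__)

#: Key variables required at both assessments (blood pressure means SBP+DBP).
DEFAULT_REQUIRED = ("sbp", "dbp", "bt", "pr", "rr", "spo2")


@dataclass(frozen=True)
class FilterBounds:
    """Plausibility bounds; values strictly beyond a bound are excluded."""

    sbp_max: float = 300.0
    dbp_max: float = 300.0
    bt_max: float = 50.0
    bt_min: float = 20.0
    pr_max: float = 300.0
    rr_max: float = 50.0
    spo2_max: float = 100.0
    spo2_min: float = 30.0

    def __post_init__(self) -> None:
        if not (self.bt_min < self.bt_max and self.spo2_min < self.spo2_max):
            raise ValidationError("filter bounds require min < max")

    def limits(self, variable: str) -> tuple[float, float]:
        """(lower, upper) plausibility limits; infinite where unbounded."""
        lo = {"bt": self.bt_min, "spo2": self.spo2_min}.get(variable, -math.inf)
        hi = {
            "sbp": self.sbp_max,
            "dbp": self.dbp_max,
            "bt": self.bt_max,
            "pr": self.pr_max,
            "rr": self.rr_max,
            "spo2": self.spo2_max,
        }.get(variable, math.inf)
        return lo, hi


@dataclass(frozen=True)
class DeltaFeatures:
    """Per-patient transport-interval changes (prehospital - in-hospital)."""

    d_sbp: float | None
    d_dbp: float | None
    d_pr: float | None
    d_rr: float | None
    d_bt: float | None
    d_spo2: float | None
    avpu_from: str | None
    avpu_to: str | None


def _required_columns(required_fields) -> list[str]:
    columns = []
    for name in required_fields:
        if name not in VITALS:
            raise ConfigError(f"unknown required field {name!r}; expected one of {VITALS}")
        columns.extend([f"{name}_1", f"{name}_2"])
    return columns


def filter_missing(frame: pd.DataFrame, required_fields=DEFAULT_REQUIRED):
    """Partition into (kept, excluded) by missingness of key variables.

    A record is excluded iff any required vital is missing at either
    assessment.
    """
    columns = _required_columns(required_fields)
    bad = frame[columns].isna().any(axis=1)
    kept, excluded = frame[~bad], frame[bad]
    log.info("filter_missing: %d in -> %d kept, %d excluded", len(frame), len(kept), len(excluded))
    return kept, excluded


def filter_outliers(frame: pd.DataFrame, bounds: FilterBounds = FilterBounds()):
    """Partition into (kept, excluded) by the plausibility bounds.

    Strict inequalities exactly as stated: SpO2 = 100 or BT = 20 are kept,
    SpO2 = 100.5 or BT = 19.9 are excluded.  Missing values never violate
    a bound (missingness is the previous filter's concern).
    """
    bad = np.zeros(len(frame), dtype=bool)
    for variable in VITALS:
        lo, hi = bounds.limits(variable)
        for suffix in ("1", "2"):
            values = frame[f"{variable}_{suffix}"].to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                bad |= (values < lo) | (values > hi)
    kept, excluded = frame[~bad], frame[bad]
    log.info(
        "filter_outliers: %d in -> %d kept, %d excluded", len(frame), len(kept), len(excluded)
    )
    return kept, excluded


def compute_deltas(record: PatientRecord) -> DeltaFeatures:
    """Delta features of one record; a delta is missing unless both sides exist."""
    values = {}
    for name in VITALS:
        v1 = getattr(record.prehospital, name)
        v2 = getattr(record.inhospital, name)
        values[f"d_{name}"] = None if v1 is None or v2 is None else v1 - v2
    return DeltaFeatures(
        avpu_from=record.prehospital.avpu, avpu_to=record.inhospital.avpu, **values
    )


def add_delta_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Copy of the frame with d_<vital> columns (prehospital - in-hospital)."""
    out = frame.copy()
    for name in VITALS:
        out[f"d_{name}"] = out[f"{name}_1"] - out[f"{name}_2"]
    return out


def stratify_age(frame: pd.DataFrame, cutoff: int = 65):
    """(elderly, younger) partition at the age cutoff; age >= cutoff is elderly."""
    elderly = frame[frame["age"] >= cutoff]
    younger = frame[frame["age"] < cutoff]
    return elderly, younger


def split_cohort(
    frame: pd.DataFrame,
    test_fraction: float = 0.3,
    seed: int = 0,
    stratify_on: tuple[str, ...] = ("age_group", "icu", "death"),
    age_cutoff: int = 65,
):
    """Deterministic stratified train/test split.

    The train set holds exactly ``floor((1 - test_fraction) * n)`` records;
    per-stratum train counts are apportioned by largest remainder so each
    stratum's train share is within one record of the global share.
    ``age_group`` in ``stratify_on`` refers to the age >= ``age_cutoff``
    dichotomy; any other entry must be a column name.
    """
    if not 0 < test_fraction < 1:
        raise ValidationError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    n = len(frame)
    if n == 0:
        raise ValidationError("cannot split an empty cohort")
    keys = []
    for name in stratify_on:
        if name == "age_group":
            keys.append((frame["age"] >= age_cutoff).astype(int).astype(str))
        elif name in frame.columns:
            keys.append(frame[name].astype(str))
        else:
            raise ConfigError(f"unknown stratification key {name!r}")
    if keys:
        stratum = keys[0].str.cat(keys[1:], sep="|") if len(keys) > 1 else keys[0]
    else:
        stratum = pd.Series(["all"] * n, index=frame.index)

    n_train = int(math.floor((1 - test_fraction) * n))
    sizes = stratum.value_counts().sort_index()
    quotas = sizes * (n_train / n)
    base = np.floor(quotas).astype(int)
    leftover = n_train - int(base.sum())
    # largest-remainder apportionment; ties broken by stratum size then key
    order = sorted(
        sizes.index, key=lambda k: (-(quotas[k] - base[k]), -sizes[k], str(k))
    )
    train_counts = base.copy()
    for key in order[:leftover]:
        train_counts[key] += 1

    rng = np.random.default_rng(seed)
    positions = np.arange(n)
    train_mask = np.zeros(n, dtype=bool)
    for key in sizes.index:
        members = positions[(stratum == key).to_numpy()]
        members = members[rng.permutation(len(members))]
        train_mask[members[: train_counts[key]]] = True
    train, test = frame.iloc[train_mask], frame.iloc[~train_mask]
    log.info(
        "split_cohort: %d in -> %d train, %d test (test_fraction=%.3f, seed=%d)",
        n, len(train), len(test), test_fraction, seed,
    )
    return train, test


def exclusion_flow(stages: list[tuple[str, int, int]]) -> pd.DataFrame:
    """Tabulate an eligibility flow as (stage, n_in, n_excluded, n_out) rows."""
    rows = [
        {"stage": name, "n_in": n_in, "n_excluded": n_excl, "n_out": n_in - n_excl}
        for name, n_in, n_excl in stages
    ]
    return pd.DataFrame(rows, columns=["stage", "n_in", "n_excluded", "n_out"])


def run_filters(frame: pd.DataFrame, bounds: FilterBounds = FilterBounds(),
                required_fields=DEFAULT_REQUIRED):
    """Missing filter then outlier filter; returns (kept, flow table)."""
    kept1, excl_missing = filter_missing(frame, required_fields)
    kept2, excl_outlier = filter_outliers(kept1, bounds)
    flow = exclusion_flow(
        [
            ("missing_key_variables", len(frame), len(excl_missing)),
            ("extreme_outliers", len(kept1), len(excl_outlier)),
        ]
    )
    return kept2, flow


__all__ = [
    "DEFAULT_REQUIRED",
    "FilterBounds",
    "DeltaFeatures",
    "filter_missing",
    "filter_outliers",
    "compute_deltas",
    "add_delta_columns",
    "stratify_age",
    "split_cohort",
    "exclusion_flow",
    "run_filters",
]
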