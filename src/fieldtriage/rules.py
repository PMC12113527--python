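"""Triage rule sets as data, shipped guideline constants, and the ISS.

A :class:`RuleSet` is a disjunction (logical OR) of :class:`Criterion`
predicates: a patient is classified severe as soon as any single criterion
fires.  Criteria come in six flavours:

``lt`` / ``gt``
    vital strictly below / above a threshold;
``outside``
    vital strictly below ``low`` or strictly above ``high``;
``avpu_le``
    consciousness at or below an AVPU level (``V`` means V, P or U);
``avpu_trans``
    a specific AVPU transition between the two assessments
    (e.g. alert at the scene, unresponsive at the hospital);
``delta_ge``
    the transport-interval change (prehospital minus in-hospital) at or
    above a threshold, either signed (a decrease of at least ``t``) or
    absolute (a swing of at least ``t`` in either direction).

Each criterion carries an ``assessment`` tag saying where it looks:
``prehospital``, ``inhospital``, ``either`` (fires if met at either
assessment), or ``delta`` (the paired difference).  A criterion whose
inputs are missing evaluates to False — field practice triggers on
observed derangement — and the miss is logged for audit.

The shipped constants are the current physiological field-triage
criteria (SBP < 90 mmHg, RR < 10 or > 29 /min, AVPU V or lower), applied
at the prehospital assessment (``CURRENT_1``), the in-hospital assessment
(``CURRENT_2``) or either (``CURRENT_3``), and the eight-criterion
age-adapted alternative guideline (SBP < 106; SpO2 < 91 %; RR < 8 or
> 22; PR < 52; AVPU <= V; A-to-U deterioration; |dSBP| >= 60 mmHg;
PR decrease >= 44 /min).  All comparison strictness follows the printed
wording: "below 90" is ``< 90``, "over 29" is ``> 29``, ">= 60" and
">= 44" are inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from fieldtriage.errors import ConfigError, ValidationError
from fieldtriage.records import (
    AVPU_LEVELS,
    VITALS,
    PatientRecord,
    avpu_severity,
    avpu_severity_array,
)

log = logging.getLogger(__name__)

_OPS = ("lt", "gt", "outside", "avpu_le", "avpu_trans", "delta_ge")
_ASSESSMENTS = ("prehospital", "inhospital", "either", "delta")
_SUFFIX = {"prehospital": ("1",), "inhospital": ("2",), "either": ("1", "2")}


@dataclass(frozen=True)
class Criterion:
    """A single threshold or transition predicate."""

    op: str
    variable: str | None = None
    threshold: float | None = None
    low: float | None = None
    high: float | None = None
    level: str | None = None
    from_level: str | None = None
    to_level: str | None = None
    mode: str = "signed"
    assessment: str = "prehospital"

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ConfigError(f"unknown criterion op {self.op!r}")
        if self.assessment not in _ASSESSMENTS:
            raise ConfigError(f"unknown assessment tag {self.assessment!r}")
        if self.op in ("lt", "gt", "outside", "delta_ge"):
            if self.variable not in VITALS:
                raise ConfigError(f"unknown variable {self.variable!r}")
        if self.op in ("lt", "gt", "delta_ge"):
            if self.threshold is None or not np.isfinite(self.threshold):
                raise ValidationError(f"{self.op} criterion needs a finite threshold")
        if self.op == "outside":
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValidationError("outside criterion needs finite low < high")
        if self.op == "avpu_le" and self.level not in AVPU_LEVELS:
            raise ValidationError(f"avpu_le level must be one of {AVPU_LEVELS}")
        if self.op == "avpu_trans":
            if self.from_level not in AVPU_LEVELS or self.to_level not in AVPU_LEVELS:
                raise ValidationError("avpu_trans needs valid from/to levels")
        if self.op == "delta_ge" and self.mode not in ("signed", "absolute"):
            raise ValidationError(f"delta mode must be signed|absolute, got {self.mode!r}")

    def describe(self) -> str:
        if self.op == "lt":
            return f"{self.variable}<{self.threshold:g}@{self.assessment}"
        if self.op == "gt":
            return f"{self.variable}>{self.threshold:g}@{self.assessment}"
        if self.op == "outside":
            return f"{self.variable}<{self.low:g}|>{self.high:g}@{self.assessment}"
        if self.op == "avpu_le":
            return f"avpu<={self.level}@{self.assessment}"
        if self.op == "avpu_trans":
            return f"avpu {self.from_level}->{self.to_level}"
        bars = "|d|" if self.mode == "absolute" else "d"
        return f"{bars}{self.variable}>={self.threshold:g}"


# -- constructor helpers -----------------------------------------------------


def below(variable: str, threshold: float, assessment: str = "prehospital") -> Criterion:
    return Criterion(op="lt", variable=variable, threshold=threshold, assessment=assessment)


def above(variable: str, threshold: float, assessment: str = "prehospital") -> Criterion:
    return Criterion(op="gt", variable=variable, threshold=threshold, assessment=assessment)


def outside(variable: str, low: float, high: float, assessment: str = "prehospital") -> Criterion:
    return Criterion(op="outside", variable=variable, low=low, high=high, assessment=assessment)


def avpu_at_or_below(level: str, assessment: str = "prehospital") -> Criterion:
    return Criterion(op="avpu_le", level=level, assessment=assessment)


def avpu_transition(from_level: str, to_level: str) -> Criterion:
    return Criterion(
        op="avpu_trans", from_level=from_level, to_level=to_level, assessment="delta"
    )


def delta_at_least(variable: str, threshold: float, mode: str = "signed") -> Criterion:
    return Criterion(
        op="delta_ge", variable=variable, threshold=threshold, mode=mode, assessment="delta"
    )


@dataclass(frozen=True)
class RuleSet:
    """A named disjunction of criteria; any criterion met -> severe."""

    name: str
    criteria: tuple[Criterion, ...]
    positive_label_meaning: str = "severe trauma"

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValidationError("a rule set needs at least one criterion")


# -- evaluation --------------------------------------------------------------


def _record_value(record: PatientRecord, variable: str, suffix: str) -> float | None:
    vitals = record.prehospital if suffix == "1" else record.inhospital
    return getattr(vitals, variable)


def evaluate_criterion(criterion: Criterion, record: PatientRecord) -> bool:
    """Evaluate one criterion on one record; missing inputs -> False."""
    c = criterion
    if c.op in ("lt", "gt", "outside"):
        for suffix in _SUFFIX.get(c.assessment, ("1",)):
            value = _record_value(record, c.variable, suffix)
            if value is None:
                log.debug("criterion %s: missing %s_%s", c.describe(), c.variable, suffix)
                continue
            if c.op == "lt" and value < c.threshold:
                return True
            if c.op == "gt" and value > c.threshold:
                return True
            if c.op == "outside" and (value < c.low or value > c.high):
                return True
        return False
    if c.op == "avpu_le":
        rank = avpu_severity(c.level)
        for suffix in _SUFFIX.get(c.assessment, ("1",)):
            avpu = record.prehospital.avpu if suffix == "1" else record.inhospital.avpu
            if avpu is None:
                continue
            if avpu_severity(avpu) >= rank:
                return True
        return False
    if c.op == "avpu_trans":
        pre, post = record.prehospital.avpu, record.inhospital.avpu
        if pre is None or post is None:
            return False
        return pre == c.from_level and post == c.to_level
    # delta_ge
    v1 = _record_value(record, c.variable, "1")
    v2 = _record_value(record, c.variable, "2")
    if v1 is None or v2 is None:
        return False
    delta = v1 - v2
    if c.mode == "absolute":
        delta = abs(delta)
    return delta >= c.threshold


def classify(rule_set: RuleSet, record: PatientRecord, deltas=None) -> bool:
    """OR of the rule set's criteria on one record.

    ``deltas`` may carry precomputed transport-interval differences from
    :func:`fieldtriage.preprocess.compute_deltas`; they are derivable from
    the record itself, so passing them is an optimization only.
    """
    return any(evaluate_criterion(c, record) for c in rule_set.criteria)


def criterion_mask(criterion: Criterion, frame: pd.DataFrame) -> np.ndarray:
    """Vectorized criterion evaluation over a cohort frame."""
    c = criterion
    n = len(frame)
    out = np.zeros(n, dtype=bool)
    if c.op in ("lt", "gt", "outside"):
        for suffix in _SUFFIX.get(c.assessment, ("1",)):
            values = frame[f"{c.variable}_{suffix}"].to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                if c.op == "lt":
                    out |= values < c.threshold
                elif c.op == "gt":
                    out |= values > c.threshold
                else:
                    out |= (values < c.low) | (values > c.high)
        return out
    if c.op == "avpu_le":
        rank = avpu_severity(c.level)
        for suffix in _SUFFIX.get(c.assessment, ("1",)):
            sev = avpu_severity_array(frame[f"avpu_{suffix}"])
            with np.errstate(invalid="ignore"):
                out |= sev >= rank
        return out
    if c.op == "avpu_trans":
        return (
            (frame["avpu_1"] == c.from_level) & (frame["avpu_2"] == c.to_level)
        ).to_numpy(dtype=bool)
    # delta_ge
    delta = frame[f"{c.variable}_1"].to_numpy(dtype=float) - frame[
        f"{c.variable}_2"
    ].to_numpy(dtype=float)
    if c.mode == "absolute":
        delta = np.abs(delta)
    with np.errstate(invalid="ignore"):
        return delta >= c.threshold


def apply_rule_set(rule_set: RuleSet, frame: pd.DataFrame) -> np.ndarray:
    """Boolean severe/not-severe classification of every row."""
    out = np.zeros(len(frame), dtype=bool)
    for criterion in rule_set.criteria:
        out |= criterion_mask(criterion, frame)
    return out


# -- shipped guideline constants --------------------------------------------


def _criterion_to_dict(c: Criterion) -> dict:
    d = {"op": c.op, "assessment": c.assessment}
    if c.variable is not None:
        d["variable"] = c.variable
    if c.op in ("lt", "gt", "delta_ge"):
        d["threshold"] = c.threshold
    if c.op == "outside":
        d["low"], d["high"] = c.low, c.high
    if c.op == "avpu_le":
        d["level"] = c.level
    if c.op == "avpu_trans":
        d["from_level"], d["to_level"] = c.from_level, c.to_level
    if c.op == "delta_ge":
        d["mode"] = c.mode
    return d


def ruleset_to_dict(rule_set: RuleSet) -> dict:
    return {
        "name": rule_set.name,
        "positive_label_meaning": rule_set.positive_label_meaning,
        "criteria": [_criterion_to_dict(c) for c in rule_set.criteria],
    }


def ruleset_from_dict(data: dict) -> RuleSet:
    criteria = tuple(Criterion(**c) for c in data["criteria"])
    return RuleSet(
        name=data["name"],
        criteria=criteria,
        positive_label_meaning=data.get("positive_label_meaning", "severe trauma"),
    )


def save_rulesets(rule_sets: dict[str, RuleSet], path) -> None:
    payload = {name: ruleset_to_dict(rs) for name, rs in rule_sets.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_rulesets(path) -> dict[str, RuleSet]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {name: ruleset_from_dict(d) for name, d in payload.items()}


def guideline_constants() -> dict[str, RuleSet]:
    """The shipped guideline rule sets, loaded from package data.

    Returns CURRENT_1 (prehospital assessment), CURRENT_2 (in-hospital),
    CURRENT_3 (either assessment), and ALTERNATIVE (the eight-criterion
    age-adapted guideline).
    """
    text = resources.files("fieldtriage").joinpath("data/guidelines.yaml").read_text()
    payload = yaml.safe_load(text)
    return {name: ruleset_from_dict(d) for name, d in payload.items()}


# -- Injury Severity Score ---------------------------------------------------


def iss_from_ais(ais_codes, max_ais_six_is_75: bool = True) -> int:
    """Injury Severity Score: sum of squares of the three highest AIS codes.

    The Abbreviated Injury Scale grades each injured body region 1 (minor)
    to 6 (unsurvivable).  By the standard convention any AIS of 6 sets the
    ISS to its maximum of 75; pass ``max_ais_six_is_75=False`` for the
    plain sum-of-squares arithmetic.
    """
    codes = list(ais_codes)
    for code in codes:
        if not (isinstance(code, (int, np.integer)) and 1 <= code <= 6):
            raise ValidationError(f"AIS codes must be integers in 1..6, got {code!r}")
    if not codes:
        return 0
    if max_ais_six_is_75 and 6 in codes:
        log.info("AIS 6 present; ISS set to 75 by convention")
        return 75
    top3 = sorted(codes, reverse=True)[:3]
    return int(sum(c**2 for c in top3))


__all__ = [
    "Criterion",
    "RuleSet",
    "below",
    "above",
    "outside",
    "avpu_at_or_below",
    "avpu_transition",
    "delta_at_least",
    "evaluate_criterion",
    "classify",
    "criterion_mask",
    "apply_rule_set",
    "ruleset_to_dict",
    "ruleset_from_dict",
    "save_rulesets",
    "load_rulesets",
    "guideline_constants",
    "iss_from_ais",
]
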