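"""Guideline-comparison tables and subgroup analyses.

Every evaluation cell is one (rule set, outcome, age stratum, subset)
combination: a confusion matrix plus the six derived metrics.  Tables are
emitted tidy (one metric per row), wide (metrics as rows, rule sets as
columns, mirroring the usual presentation of triage-comparison studies)
and as a machine-readable JSON summary.  Undefined (0/0) cells render
blank, never as 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from fieldtriage.metrics import ConfusionMatrix, MetricSet, confusion, metric_set, round_reported
from fieldtriage.preprocess import stratify_age
from fieldtriage.rules import RuleSet, apply_rule_set

log = logging.getLogger(__name__)

_METRIC_FIELDS = ("sensitivity", "specificity", "precision", "f1", "f2", "accuracy")


@dataclass(frozen=True)
class EvaluationResult:
    """One table cell: counts and metrics for (rule set, outcome, stratum, subset)."""

    ruleset_name: str
    outcome: str
    stratum: str
    subset: str
    n: int
    confusion: ConfusionMatrix | None
    metrics: MetricSet | None


@dataclass(frozen=True)
class SubgroupDef:
    """A named subset of records; the mask function must be total."""

    name: str
    mask: Callable[[pd.DataFrame], np.ndarray]


def iss_subgroup(cutoff: int = 16, name: str | None = None) -> SubgroupDef:
    """High-injury-severity subgroup: ISS >= cutoff.

    Records without an ISS are excluded from the subgroup (and logged);
    injury severity is simply unknown for them.
    """

    def mask(frame: pd.DataFrame) -> np.ndarray:
        iss = frame["iss"].to_numpy(dtype=float)
        lacking = int(np.isnan(iss).sum())
        if lacking:
            log.info("iss subgroup: %d records lack ISS and are excluded", lacking)
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(iss, nan=-1.0) >= cutoff

    return SubgroupDef(name=name or f"iss_ge_{cutoff}", mask=mask)


def injury_subgroup(injury_type: str) -> SubgroupDef:
    """Membership subgroup for one injury-type label (non-exclusive)."""

    def mask(frame: pd.DataFrame) -> np.ndarray:
        types = frame["injury_types"].fillna("")
        return types.str.split(";").map(lambda ts: injury_type in ts).to_numpy(dtype=bool)

    return SubgroupDef(name=injury_type, mask=mask)


def default_subgroups(iss_cutoff: int = 16) -> list[SubgroupDef]:
    return [iss_subgroup(iss_cutoff)] + [
        injury_subgroup(t) for t in ("TBI", "chest", "abdominal_pelvic", "extremity")
    ]


def evaluate_cell(rule_set: RuleSet, frame: pd.DataFrame, outcome: str,
                  beta: float = 2.0, stratum: str = "all", subset: str = "all",
                  name: str | None = None) -> EvaluationResult:
    """Classify a cohort subset with one rule set and derive all metrics."""
    n = len(frame)
    if n == 0:
        return EvaluationResult(
            ruleset_name=name or rule_set.name, outcome=outcome, stratum=stratum,
            subset=subset, n=0, confusion=None, metrics=None,
        )
    preds = apply_rule_set(rule_set, frame)
    labels = frame[outcome].to_numpy(dtype=bool)
    cm = confusion(preds, labels)
    return EvaluationResult(
        ruleset_name=name or rule_set.name, outcome=outcome, stratum=stratum,
        subset=subset, n=n, confusion=cm, metrics=metric_set(cm, beta=beta),
    )


def _strata(frame: pd.DataFrame, age_cutoff: int):
    elderly, younger = stratify_age(frame, age_cutoff)
    return [("age>=%d" % age_cutoff, elderly), ("age<%d" % age_cutoff, younger)]


def compare_guidelines(rule_sets, frame: pd.DataFrame, outcomes=("icu", "death"),
                       beta: float = 2.0, age_cutoff: int = 65) -> list[EvaluationResult]:
    """One evaluation cell per (rule set x outcome x age stratum)."""
    rule_sets = _as_ruleset_list(rule_sets)
    results = []
    for stratum_name, sub in _strata(frame, age_cutoff):
        for outcome in outcomes:
            for rs in rule_sets:
                results.append(
                    evaluate_cell(rs, sub, outcome, beta=beta, stratum=stratum_name)
                )
    return results


def subgroup_eval(rule_sets, frame: pd.DataFrame, subgroups: list[SubgroupDef],
                  outcomes=("icu", "death"), beta: float = 2.0,
                  age_cutoff: int = 65) -> list[EvaluationResult]:
    """Guideline comparison restricted to each subgroup, by age stratum."""
    rule_sets = _as_ruleset_list(rule_sets)
    results = []
    for stratum_name, sub in _strata(frame, age_cutoff):
        for group in subgroups:
            member = sub[group.mask(sub)]
            for outcome in outcomes:
                for rs in rule_sets:
                    results.append(
                        evaluate_cell(
                            rs, member, outcome, beta=beta,
                            stratum=stratum_name, subset=group.name,
                        )
                    )
    return results


def _as_ruleset_list(rule_sets) -> list[RuleSet]:
    if isinstance(rule_sets, dict):
        return list(rule_sets.values())
    return list(rule_sets)


# -- rendering ---------------------------------------------------------------


def tidy_frame(results: list[EvaluationResult], ndigits: int = 3) -> pd.DataFrame:
    """Long-format table: one row per (cell, metric)."""
    rows = []
    for r in results:
        cells = {"n": r.n}
        if r.confusion is not None:
            cells.update(tp=r.confusion.tp, fp=r.confusion.fp,
                         fn=r.confusion.fn, tn=r.confusion.tn)
        for name in _METRIC_FIELDS:
            value = getattr(r.metrics, name) if r.metrics is not None else None
            cells[name] = round_reported(value, ndigits)
        for metric, value in cells.items():
            rows.append(
                {
                    "ruleset": r.ruleset_name, "outcome": r.outcome,
                    "stratum": r.stratum, "subset": r.subset,
                    "metric": metric, "value": value,
                }
            )
    return pd.DataFrame(rows, columns=["ruleset", "outcome", "stratum", "subset",
                                       "metric", "value"])


def wide_frame(results: list[EvaluationResult], ndigits: int = 3) -> pd.DataFrame:
    """Wide table per (outcome, stratum, subset): metric rows, rule-set columns."""
    tidy = tidy_frame(results, ndigits)
    tidy = tidy[tidy["metric"].isin(_METRIC_FIELDS + ("n",))]
    wide = tidy.pivot_table(
        index=["outcome", "stratum", "subset", "metric"],
        columns="ruleset", values="value", aggfunc="first", dropna=False,
    ).reset_index()
    wide.columns.name = None
    order = {m: i for i, m in enumerate(("n",) + _METRIC_FIELDS)}
    wide["_order"] = wide["metric"].map(order)
    wide = wide.sort_values(["outcome", "stratum", "subset", "_order"]).drop(columns="_order")
    return wide.reset_index(drop=True)


def json_summary(results: list[EvaluationResult], ndigits: int = 3) -> str:
    """Machine-readable summary, with conventions documented in metadata."""
    payload = {
        "metadata": {
            "positive_label": "severe trauma",
            "undertriage": "fn / (tp + fn), i.e. 1 - sensitivity",
            "overtriage": "fp / (tn + fp), i.e. 1 - specificity",
            "rounding": f"{ndigits} decimals, half away from zero",
        },
        "cells": [],
    }
    for r in results:
        cell = {
            "ruleset": r.ruleset_name, "outcome": r.outcome, "stratum": r.stratum,
            "subset": r.subset, "n": r.n,
        }
        if r.confusion is not None:
            cell["confusion"] = {
                "tp": r.confusion.tp, "fp": r.confusion.fp,
                "fn": r.confusion.fn, "tn": r.confusion.tn,
            }
        if r.metrics is not None:
            cell["metrics"] = {
                name: round_reported(getattr(r.metrics, name), ndigits)
                for name in _METRIC_FIELDS
            }
        payload["cells"].append(cell)
    return json.dumps(payload, indent=2)


def markdown_report(results: list[EvaluationResult], title: str = "Guideline comparison",
                    ndigits: int = 3) -> str:
    """Plain-text/markdown rendering of the wide tables."""
    wide = wide_frame(results, ndigits)
    lines = [f"# {title}", ""]
    for (outcome, stratum, subset), block in wide.groupby(["outcome", "stratum", "subset"]):
        lines.append(f"## outcome={outcome}, stratum={stratum}, subset={subset}")
        lines.append("")
        body = block.drop(columns=["outcome", "stratum", "subset"]).fillna("")
        lines.append("```")
        lines.append(body.to_string(index=False))
        lines.append("```")
        lines.append("")
    return "\n".join(lines)


__all__ = [
    "EvaluationResult",
    "SubgroupDef",
    "iss_subgroup",
    "injury_subgroup",
    "default_subgroups",
    "evaluate_cell",
    "compare_guidelines",
    "subgroup_eval",
    "tidy_frame",
    "wide_frame",
    "json_summary",
    "markdown_report",
]
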