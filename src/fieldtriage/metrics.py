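"""Confusion-matrix bookkeeping and the F-beta score family.

Triage evaluation is a highly imbalanced binary problem: the positive
class (ICU admission, in-hospital death) is rare, so accuracy is nearly
meaningless and the optimization objective is the F2 score, the F-beta
member with beta = 2 that weights recall (sensitivity) four times as
heavily as precision and therefore penalizes undertriage.

Degenerate cells (0/0 ratios) are reported as ``None`` ("undefined"),
never silently as 0; callers that need a number for an objective must
make that substitution explicitly.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np

from fieldtriage.errors import ValidationError


@dataclass(frozen=True)
class ConfusionMatrix:
    """Standard 2x2 counts; positive means classified/true severe."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """The six reported metrics; ``None`` marks an undefined (0/0) cell."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    accuracy: float | None
    f1: float | None
    f2: float | None
    beta: float = 2.0


def confusion(predictions, labels) -> ConfusionMatrix:
    """Tally the 2x2 confusion matrix of boolean predictions vs labels."""
    pred = np.asarray(predictions, dtype=bool)
    lab = np.asarray(labels, dtype=bool)
    if pred.shape != lab.shape or pred.ndim != 1 or pred.size == 0:
        raise ValidationError(
            f"predictions and labels must be equal-length 1-d with size >= 1; "
            f"got shapes {pred.shape} and {lab.shape}"
        )
    tp = int(np.sum(pred & lab))
    fp = int(np.sum(pred & ~lab))
    fn = int(np.sum(~pred & lab))
    tn = int(np.sum(~pred & ~lab))
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def f_beta(precision: float, recall: float, beta: float = 2.0) -> float:
    """F-beta score ((1 + beta^2) * P * R) / (beta^2 * P + R).

    Defined as 0.0 when the denominator vanishes (P = R = 0).
    """
    if beta <= 0:
        raise ValidationError(f"beta must be positive, got {beta}")
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValidationError("precision and recall must lie in [0, 1]")
    denom = beta**2 * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta**2) * precision * recall / denom


def f_beta_from_counts(tp: int, fp: int, fn: int, beta: float = 2.0) -> float | None:
    """F-beta straight from counts; ``None`` when no positives exist anywhere.

    Algebraically equal to ``f_beta(tp/(tp+fp), tp/(tp+fn))`` wherever the
    two ratios are defined, but also well behaved when only one of them is.
    """
    if beta <= 0:
        raise ValidationError(f"beta must be positive, got {beta}")
    denom = (1 + beta**2) * tp + beta**2 * fn + fp
    if denom == 0:
        return None
    return (1 + beta**2) * tp / denom


def _ratio(num: int, denom: int) -> float | None:
    return None if denom == 0 else num / denom


def metric_set(cm: ConfusionMatrix, beta: float = 2.0) -> MetricSet:
    """Derive the six reported metrics from a confusion matrix."""
    if cm.total == 0:
        raise ValidationError("confusion matrix must contain at least one observation")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    acc = (cm.tp + cm.tn) / cm.total
    if prec is None or sens is None:
        f1 = f2 = None
    else:
        f1 = f_beta(prec, sens, 1.0)
        f2 = f_beta(prec, sens, beta)
    return MetricSet(
        sensitivity=sens, specificity=spec, precision=prec, accuracy=acc, f1=f1, f2=f2, beta=beta
    )


def triage_rates(cm: ConfusionMatrix) -> tuple[float | None, float | None]:
    """(undertriage, overtriage) = (1 - sensitivity, 1 - specificity).

    Undertriage is the miss rate among truly severe patients; overtriage is
    the false-alarm rate among non-severe patients.  Either is ``None`` when
    its denominator is empty.
    """
    ms = metric_set(cm)
    under = None if ms.sensitivity is None else 1.0 - ms.sensitivity
    over = None if ms.specificity is None else 1.0 - ms.specificity
    return under, over


def prevalence(labels) -> float:
    """Proportion of positive labels."""
    lab = np.asarray(labels, dtype=bool)
    if lab.size == 0:
        raise ValidationError("labels must be non-empty")
    return float(lab.mean())


def round_reported(value: float | None, ndigits: int = 3) -> float | None:
    """Round for presentation: half away from zero, as in printed tables."""
    if value is None:
        return None
    quant = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(value)).quantize(quant, rounding=decimal.ROUND_HALF_UP))


__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "confusion",
    "f_beta",
    "f_beta_from_counts",
    "metric_set",
    "triage_rates",
    "prevalence",
    "round_reported",
]
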