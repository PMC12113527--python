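"""Calibrated synthetic trauma-cohort generator.

The generator emulates the statistical structure the triage analysis
assumes, so that every downstream stage (filters, delta features, rule
evaluation, threshold search) is testable without access to the original
EMS registry:

* age-stratified vitals (age >= 65 vs < 65) at two assessments, drawn
  from moment-matched truncated normals inside the plausibility bounds;
* in-hospital values derived as prehospital value + Gaussian transport
  drift, which induces the pairing that delta features need; the drift
  mean is solved numerically so the configured in-hospital marginal mean
  is recovered despite clipping at the bounds;
* ordered AVPU with a configurable probability of deterioration between
  assessments (one step, or a jump from alert straight to unresponsive);
* injury-type labels with per-region AIS severities and the derived ISS;
* two logistic outcome processes (ICU admission; in-hospital death) whose
  features are derangement indicators and transport-interval deltas, so
  rule-based separation exists by construction.  Death can be restricted
  to (latently) admitted patients, mirroring registries where mortality
  is ascertained in-hospital only.

Default calibration reproduces the marginal means/SDs, AVPU category
frequencies and outcome prevalences of a metropolitan EMS trauma
population (about 44 % aged 65+; ICU admission 10.0 % in the elderly
stratum and 4.7 % in the younger; in-hospital death 10.2 % / 4.2 % of
admitted patients).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from fieldtriage.errors import ConfigError, ValidationError
from fieldtriage.records import (
    AVPU_LEVELS,
    COHORT_COLUMNS,
    INJURY_TYPES,
    VITALS,
    avpu_severity_array,
)
from fieldtriage.rules import iss_from_ais

STRATA = ("elderly", "younger")

#: Generation bounds per vital: the plausibility bounds where they exist,
#: physiological floors where the filters leave a side open.
GEN_BOUNDS = {
    "sbp": (30.0, 300.0),
    "dbp": (10.0, 300.0),
    "pr": (10.0, 300.0),
    "rr": (0.0, 50.0),
    "bt": (20.0, 50.0),
    "spo2": (30.0, 100.0),
}

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class VitalParams:
    """Target marginal mean/SD of one vital at both assessments."""

    mean_1: float
    sd_1: float
    mean_2: float
    sd_2: float


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model: P(event) = sigmoid(intercept + sum_f w_f * x_f).

    Weight keys are derangement-feature expressions, e.g. ``sbp_2<106``,
    ``avpu_2>=V``, ``avpu_A_to_U``, ``|d_sbp|>=60``, ``d_pr>=44``.
    """

    intercept: float
    weights: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortSpec:
    """Full specification of a synthetic cohort; see module docstring."""

    n: int
    seed: int = 0
    elderly_fraction: float = 0.4362
    vital_params: dict = field(default_factory=lambda: _default_vital_params())
    avpu_probs: dict = field(default_factory=lambda: _default_avpu_probs())
    transition_noise: float = 0.03
    transition_au_fraction: float = 0.15
    outcome_model: dict = field(default_factory=lambda: _default_outcome_models())
    ward_admission_rate: dict = field(
        default_factory=lambda: {"elderly": 0.292, "younger": 0.140}
    )
    mortality_among_admitted: bool = True
    missing_rate: float = 0.196
    outlier_rate: float = 0.007
    injury_mix: dict = field(
        default_factory=lambda: {
            "TBI": 0.25, "chest": 0.15, "abdominal_pelvic": 0.10,
            "extremity": 0.35, "other": 0.15,
        }
    )
    multi_injury_rate: float = 0.15
    ais_model: dict = field(default_factory=lambda: _default_ais_model())
    age_params: dict = field(
        default_factory=lambda: {
            "elderly": (77.68, 7.92, 65, 105),
            "younger": (41.74, 15.80, 0, 64),
        }
    )
    sex_female_prob: dict = field(
        default_factory=lambda: {"elderly": 0.532, "younger": 0.478}
    )


def _default_vital_params() -> dict:
    # marginal mean +/- SD per stratum and assessment for a metropolitan
    # EMS trauma population
    return {
        "elderly": {
            "sbp": VitalParams(143.18, 29.39, 145.76, 31.49),
            "dbp": VitalParams(83.13, 18.03, 78.95, 16.76),
            "pr": VitalParams(86.65, 19.23, 85.30, 19.96),
            "rr": VitalParams(18.16, 3.40, 19.61, 3.25),
            "bt": VitalParams(36.93, 0.91, 36.77, 0.86),
            "spo2": VitalParams(96.10, 5.96, 96.59, 4.24),
        },
        "younger": {
            "sbp": VitalParams(131.68, 24.61, 132.30, 26.53),
            "dbp": VitalParams(82.35, 16.86, 80.24, 16.41),
            "pr": VitalParams(88.77, 19.39, 87.32, 19.70),
            "rr": VitalParams(18.02, 3.08, 19.18, 2.64),
            "bt": VitalParams(36.85, 0.74, 36.77, 0.72),
            "spo2": VitalParams(97.98, 3.20, 97.83, 2.77),
        },
    }


def _normalized(counts: tuple[float, ...]) -> tuple[float, ...]:
    total = sum(counts)
    return tuple(c / total for c in counts)


def _default_avpu_probs() -> dict:
    # category counts (A, V, P, U) per stratum and assessment, normalized.
    # The in-hospital entry documents the target second-assessment marginal;
    # generation reaches the second assessment through the transition model.
    return {
        "elderly": {
            "prehospital": _normalized((85062, 5032, 4576, 927)),
            "inhospital": _normalized((84186, 6323, 4625, 463)),
        },
        "younger": {
            "prehospital": _normalized((116582, 3433, 2832, 707)),
            "inhospital": _normalized((116439, 4068, 2757, 290)),
        },
    }


def _default_ais_model() -> dict:
    # probability over AIS severities 1..6 per injured region type
    return {
        "TBI": (0.25, 0.30, 0.25, 0.12, 0.07, 0.01),
        "chest": (0.30, 0.30, 0.22, 0.12, 0.05, 0.01),
        "abdominal_pelvic": (0.35, 0.30, 0.20, 0.10, 0.045, 0.005),
        "extremity": (0.45, 0.30, 0.15, 0.07, 0.025, 0.005),
    }


def _default_outcome_models() -> dict:
    # Weights encode the derangements that drive severity; intercepts were
    # calibrated by simulation against the target prevalences (see
    # docs/methods.md) and are frozen here.
    icu_weights = {
        "sbp_2<106": 0.8,
        "sbp_1<106": 0.5,
        "spo2_2<91": 1.2,
        "rr_2>22": 0.6,
        "pr_2<52": 0.8,
        "avpu_2>=V": 1.8,
        "avpu_A_to_U": 1.5,
        "|d_sbp|>=60": 1.0,
        "d_pr>=44": 0.9,
    }
    death_weights = {
        "sbp_2<106": 0.6,
        "spo2_2<91": 1.0,
        "rr_2>22": 0.5,
        "avpu_2>=V": 2.2,
        "avpu_A_to_U": 2.0,
        "|d_sbp|>=60": 0.8,
        "d_pr>=44": 0.8,
    }
    return {
        "icu": {
            "elderly": OutcomeModel(-3.117, dict(icu_weights)),
            "younger": OutcomeModel(-3.794, dict(icu_weights)),
        },
        "death": {
            "elderly": OutcomeModel(-3.302, dict(death_weights)),
            "younger": OutcomeModel(-4.200, dict(death_weights)),
        },
    }


# -- validation --------------------------------------------------------------


def _check_prob(name: str, value: float) -> None:
    if not 0 <= value <= 1:
        raise ValidationError(f"{name} must lie in [0, 1], got {value}")


def _check_simplex(name: str, probs) -> None:
    for p in probs:
        _check_prob(name, p)
    if abs(sum(probs) - 1.0) > _PROB_TOL:
        raise ValidationError(f"{name} must sum to 1, got {sum(probs)!r}")


def validate_spec(spec: CohortSpec) -> None:
    """Raise :class:`ValidationError` naming the first offending field."""
    if spec.n <= 0:
        raise ValidationError(f"n must be positive, got {spec.n}")
    _check_prob("elderly_fraction", spec.elderly_fraction)
    _check_prob("transition_noise", spec.transition_noise)
    _check_prob("transition_au_fraction", spec.transition_au_fraction)
    _check_prob("missing_rate", spec.missing_rate)
    _check_prob("outlier_rate", spec.outlier_rate)
    _check_prob("multi_injury_rate", spec.multi_injury_rate)
    for stratum in STRATA:
        for vital in VITALS:
            vp = spec.vital_params[stratum][vital]
            if vp.sd_1 <= 0 or vp.sd_2 <= 0:
                raise ValidationError(f"vital_params[{stratum}][{vital}]: SDs must be > 0")
        for assessment in ("prehospital", "inhospital"):
            _check_simplex(
                f"avpu_probs[{stratum}][{assessment}]", spec.avpu_probs[stratum][assessment]
            )
        _check_prob(f"ward_admission_rate[{stratum}]", spec.ward_admission_rate[stratum])
    _check_simplex("injury_mix", [spec.injury_mix[t] for t in INJURY_TYPES])
    for region, probs in spec.ais_model.items():
        _check_simplex(f"ais_model[{region}]", probs)
    for outcome in ("icu", "death"):
        for stratum in STRATA:
            model = spec.outcome_model[outcome][stratum]
            if not np.isfinite(model.intercept):
                raise ValidationError(f"outcome_model[{outcome}][{stratum}].intercept not finite")
            for expr in model.weights:
                _parse_feature(expr)  # raises ConfigError on bad expressions


# -- derangement-feature mini-language ---------------------------------------

_VITAL_RE = re.compile(r"^(sbp|dbp|pr|rr|bt|spo2)_(1|2)(<|>)(-?\d+(?:\.\d+)?)$")
_DELTA_RE = re.compile(r"^d_(sbp|dbp|pr|rr|bt|spo2)>=(-?\d+(?:\.\d+)?)$")
_ABS_RE = re.compile(r"^\|d_(sbp|dbp|pr|rr|bt|spo2)\|>=(\d+(?:\.\d+)?)$")
_AVPU_RE = re.compile(r"^avpu_(1|2)>=(A|V|P|U)$")
_TRANS_RE = re.compile(r"^avpu_(A|V|P|U)_to_(A|V|P|U)$")


def _parse_feature(expr: str):
    for regex in (_VITAL_RE, _DELTA_RE, _ABS_RE, _AVPU_RE, _TRANS_RE):
        m = regex.match(expr)
        if m:
            return regex, m
    raise ConfigError(f"cannot parse feature expression {expr!r}")


def feature_column(frame: pd.DataFrame, expr: str) -> np.ndarray:
    """0/1 indicator column for one derangement-feature expression.

    Missing inputs yield 0 (no observed derangement).
    """
    regex, m = _parse_feature(expr)
    with np.errstate(invalid="ignore"):
        if regex is _VITAL_RE:
            var, suffix, op, thr = m.group(1), m.group(2), m.group(3), float(m.group(4))
            values = frame[f"{var}_{suffix}"].to_numpy(dtype=float)
            mask = values < thr if op == "<" else values > thr
        elif regex is _DELTA_RE:
            var, thr = m.group(1), float(m.group(2))
            delta = frame[f"{var}_1"].to_numpy(float) - frame[f"{var}_2"].to_numpy(float)
            mask = delta >= thr
        elif regex is _ABS_RE:
            var, thr = m.group(1), float(m.group(2))
            delta = frame[f"{var}_1"].to_numpy(float) - frame[f"{var}_2"].to_numpy(float)
            mask = np.abs(delta) >= thr
        elif regex is _AVPU_RE:
            suffix, level = m.group(1), m.group(2)
            sev = avpu_severity_array(frame[f"avpu_{suffix}"])
            mask = sev >= AVPU_LEVELS.index(level)
        else:
            mask = (frame["avpu_1"] == m.group(1)) & (frame["avpu_2"] == m.group(2))
    return np.nan_to_num(np.asarray(mask, dtype=float), nan=0.0)


def linear_predictor(frame: pd.DataFrame, model: OutcomeModel) -> np.ndarray:
    eta = np.full(len(frame), model.intercept, dtype=float)
    for expr, weight in model.weights.items():
        eta += weight * feature_column(frame, expr)
    return eta


# -- truncated-normal moment matching ----------------------------------------


@lru_cache(maxsize=512)
def matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """(mu, sigma) of the parent normal whose [lo, hi]-truncation has the
    target mean (and SD, where jointly attainable).

    When the two moments cannot both be met inside the bounds, the mean is
    matched exactly with sigma held at the target SD.
    """

    def moments(params):
        mu, sigma = params
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return float(m), float(math.sqrt(v))

    def residual(params):
        m, s = moments((params[0], abs(params[1]) + 1e-9))
        return [m - mean, s - sd]

    sol = optimize.least_squares(residual, x0=[mean, sd], xtol=1e-12, ftol=1e-12, gtol=1e-12)
    mu, sigma = sol.x[0], abs(sol.x[1]) + 1e-9
    if abs(moments((mu, sigma))[0] - mean) < 1e-6:
        return float(mu), float(sigma)

    # fall back: match the mean only, sigma fixed at the target SD
    def mean_err(mu_):
        a, b = (lo - mu_) / sd, (hi - mu_) / sd
        return float(stats.truncnorm.mean(a, b, loc=mu_, scale=sd)) - mean

    mu = optimize.brentq(mean_err, lo - 10 * sd, hi + 10 * sd, xtol=1e-10)
    return float(mu), float(sd)


def _sample_truncnorm(rng, mean, sd, lo, hi, size) -> np.ndarray:
    mu, sigma = matched_truncnorm(round(mean, 6), round(sd, 6), lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def _clipped_normal_mean(mu: np.ndarray, sd: float, lo: float, hi: float) -> np.ndarray:
    """E[clip(Y, lo, hi)] for Y ~ N(mu, sd), vectorized over mu."""
    a = (lo - mu) / sd
    b = (hi - mu) / sd
    return (
        lo * stats.norm.cdf(a)
        + hi * stats.norm.sf(b)
        + mu * (stats.norm.cdf(b) - stats.norm.cdf(a))
        - sd * (stats.norm.pdf(b) - stats.norm.pdf(a))
    )


def _solve_drift_mean(v1: np.ndarray, target_mean: float, drift_sd: float,
                      lo: float, hi: float) -> float:
    """Drift mean m such that E[clip(v1 + N(m, drift_sd), lo, hi)] = target."""
    sample = v1 if len(v1) <= 20000 else v1[:20000]

    def err(m):
        return float(np.mean(_clipped_normal_mean(sample + m, drift_sd, lo, hi))) - target_mean

    span = hi - lo
    return optimize.brentq(err, -span, span, xtol=1e-9)


# -- generation --------------------------------------------------------------


def _sample_avpu(rng, probs, size) -> np.ndarray:
    idx = rng.choice(4, size=size, p=np.asarray(probs, dtype=float) / np.sum(probs))
    return np.asarray(AVPU_LEVELS, dtype=object)[idx]


def _transition_avpu(rng, avpu_1, noise, au_fraction) -> np.ndarray:
    """Second-assessment AVPU: unchanged, or worsened with probability noise."""
    avpu_2 = avpu_1.copy()
    worsen = (rng.random(len(avpu_1)) < noise) & (avpu_1 != "U")
    rank = np.array([AVPU_LEVELS.index(a) for a in avpu_1])
    new_rank = np.minimum(rank + 1, 3)
    jump = worsen & (avpu_1 == "A") & (rng.random(len(avpu_1)) < au_fraction)
    new_rank[jump] = 3
    levels = np.asarray(AVPU_LEVELS, dtype=object)
    avpu_2[worsen] = levels[new_rank[worsen]]
    return avpu_2


def _sample_injuries(rng, spec: CohortSpec, size: int):
    """Injury-type sets, AIS codes and ISS for ``size`` records."""
    mix = np.array([spec.injury_mix[t] for t in INJURY_TYPES], dtype=float)
    mix = mix / mix.sum()
    primary = rng.choice(len(INJURY_TYPES), size=size, p=mix)
    second = rng.choice(len(INJURY_TYPES), size=size, p=mix)
    has_second = rng.random(size) < spec.multi_injury_rate
    ais_draws = rng.random((size, 2))
    injury_col, ais_col, iss_col = [], [], []
    for i in range(size):
        types = {INJURY_TYPES[primary[i]]}
        if has_second[i]:
            types.add(INJURY_TYPES[second[i]])
        codes = []
        for j, t in enumerate(sorted(types)):
            probs = spec.ais_model.get(t)
            if probs is None:  # untyped ("other") injuries carry no AIS code
                continue
            cum = np.cumsum(np.asarray(probs) / np.sum(probs))
            codes.append(1 + int(np.searchsorted(cum, ais_draws[i, j % 2])))
        injury_col.append(";".join(sorted(types)))
        ais_col.append(";".join(str(c) for c in codes))
        iss_col.append(iss_from_ais(codes) if codes else np.nan)
    return injury_col, ais_col, iss_col


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate exactly ``spec.n`` clean records (no artifacts injected).

    Deterministic given ``spec.seed``: identical specs yield byte-identical
    cohort CSVs.  Before artifact injection no record violates the
    plausibility bounds.
    """
    validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    n_elderly = int(round(n * spec.elderly_fraction))
    stratum_of = np.array(["elderly"] * n_elderly + ["younger"] * (n - n_elderly), dtype=object)
    rng.shuffle(stratum_of)

    frame = pd.DataFrame(index=range(n), columns=COHORT_COLUMNS)
    frame["id"] = [f"P{i:07d}" for i in range(n)]

    for stratum in STRATA:
        mask = stratum_of == stratum
        size = int(mask.sum())
        if size == 0:
            continue
        mean, sd, lo, hi = spec.age_params[stratum]
        ages = _sample_truncnorm(rng, mean, sd, lo, hi + 0.999, size)
        frame.loc[mask, "age"] = np.clip(np.floor(ages), lo, hi).astype(int)
        female = rng.random(size) < spec.sex_female_prob[stratum]
        frame.loc[mask, "sex"] = np.where(female, "female", "male")

        for vital in VITALS:
            vp = spec.vital_params[stratum][vital]
            glo, ghi = GEN_BOUNDS[vital]
            v1 = _sample_truncnorm(rng, vp.mean_1, vp.sd_1, glo, ghi, size)
            drift_sd = math.sqrt(max(vp.sd_2**2 - vp.sd_1**2, (0.2 * vp.sd_1) ** 2))
            drift_mu = _solve_drift_mean(v1, vp.mean_2, drift_sd, glo, ghi)
            v2 = np.clip(v1 + rng.normal(drift_mu, drift_sd, size), glo, ghi)
            decimals = 1 if vital in ("bt", "spo2") else 0
            frame.loc[mask, f"{vital}_1"] = np.round(v1, decimals)
            frame.loc[mask, f"{vital}_2"] = np.round(v2, decimals)

        avpu_1 = _sample_avpu(rng, spec.avpu_probs[stratum]["prehospital"], size)
        avpu_2 = _transition_avpu(
            rng, avpu_1, spec.transition_noise, spec.transition_au_fraction
        )
        frame.loc[mask, "avpu_1"] = avpu_1
        frame.loc[mask, "avpu_2"] = avpu_2

    injury_col, ais_col, iss_col = _sample_injuries(rng, spec, n)
    frame["injury_types"] = injury_col
    frame["ais_codes"] = ais_col
    frame["iss"] = iss_col

    for col in [f"{v}_{s}" for v in VITALS for s in ("1", "2")] + ["age"]:
        frame[col] = frame[col].astype(float)
    frame["age"] = frame["age"].astype(int)

    # outcomes: logistic in the derangement features, per stratum
    icu = np.zeros(n, dtype=bool)
    p_death = np.zeros(n, dtype=float)
    ward_draw = rng.random(n)
    icu_draw = rng.random(n)
    death_draw = rng.random(n)
    for stratum in STRATA:
        mask = stratum_of == stratum
        if not mask.any():
            continue
        sub = frame[mask]
        eta_icu = linear_predictor(sub, spec.outcome_model["icu"][stratum])
        icu[mask] = icu_draw[mask] < 1.0 / (1.0 + np.exp(-eta_icu))
        eta_death = linear_predictor(sub, spec.outcome_model["death"][stratum])
        p_death[mask] = 1.0 / (1.0 + np.exp(-eta_death))
    ward = np.zeros(n, dtype=bool)
    for stratum in STRATA:
        mask = stratum_of == stratum
        ward[mask] = ward_draw[mask] < spec.ward_admission_rate[stratum]
    admitted = icu | ward
    death = death_draw < p_death
    if spec.mortality_among_admitted:
        death &= admitted
    frame["icu"] = icu.astype(int)
    frame["death"] = death.astype(int)
    return frame


# -- artifact injection -------------------------------------------------------

_OUTLIER_VALUES = {
    "sbp": ("high", 301.0, 340.0),
    "dbp": ("high", 301.0, 340.0),
    "pr": ("high", 301.0, 340.0),
    "rr": ("high", 51.0, 70.0),
    "bt": ("both", (50.5, 55.0), (15.0, 19.5)),
    "spo2": ("both", (100.5, 105.0), (10.0, 29.5)),
}


def inject_artifacts(frame: pd.DataFrame, missing_rate: float, outlier_rate: float,
                     seed: int):
    """Blank or corrupt fields in a copy of the cohort; return (frame, manifest).

    Each affected record receives exactly one artifact: either one required
    field blanked, or one vital set strictly beyond one plausibility bound.
    The manifest lists ``(id, field, kind, value)`` per injected artifact;
    the missing/outlier record sets are disjoint, so the downstream filters
    should exclude exactly the manifest ids.
    """
    for name, rate in (("missing_rate", missing_rate), ("outlier_rate", outlier_rate)):
        if not 0 <= rate <= 1:
            raise ValidationError(f"{name} must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    out = frame.copy()
    n = len(out)
    u = rng.random(n)
    is_missing = u < missing_rate
    is_outlier = (~is_missing) & (u < min(missing_rate + outlier_rate, 1.0))
    fields = [f"{v}_{s}" for v in VITALS for s in ("1", "2")]
    manifest_rows = []
    for pos in np.flatnonzero(is_missing):
        col = fields[rng.integers(len(fields))]
        out.iloc[pos, out.columns.get_loc(col)] = np.nan
        manifest_rows.append(
            {"id": out.iloc[pos]["id"], "field": col, "kind": "missing", "value": np.nan}
        )
    for pos in np.flatnonzero(is_outlier):
        vital = VITALS[rng.integers(len(VITALS))]
        suffix = "1" if rng.random() < 0.5 else "2"
        kind, *ranges = _OUTLIER_VALUES[vital]
        if kind == "high":
            lo, hi = ranges
            value = float(rng.uniform(lo, hi))
        else:
            high_range, low_range = ranges
            lo, hi = high_range if rng.random() < 0.5 else low_range
            value = float(rng.uniform(lo, hi))
        col = f"{vital}_{suffix}"
        out.iloc[pos, out.columns.get_loc(col)] = round(value, 1)
        manifest_rows.append(
            {"id": out.iloc[pos]["id"], "field": col, "kind": "outlier", "value": round(value, 1)}
        )
    manifest = pd.DataFrame(manifest_rows, columns=["id", "field", "kind", "value"])
    return out, manifest


def simulate(spec: CohortSpec):
    """Generate a cohort and apply the spec's artifact rates.

    Returns (frame, manifest); the artifact seed is derived from the spec
    seed so the whole simulation is reproducible from one integer.
    """
    clean = generate_cohort(spec)
    return inject_artifacts(clean, spec.missing_rate, spec.outlier_rate,
                            seed=(spec.seed * 1_000_003 + 1) % (2**31))


# -- spec serialization -------------------------------------------------------


def spec_to_dict(spec: CohortSpec) -> dict:
    # asdict expands the nested VitalParams/OutcomeModel dataclasses
    return asdict(spec)


def spec_from_dict(data: dict) -> CohortSpec:
    data = dict(data)
    if "vital_params" in data:
        data["vital_params"] = {
            stratum: {v: VitalParams(**vp) if isinstance(vp, dict) else vp
                      for v, vp in per.items()}
            for stratum, per in data["vital_params"].items()
        }
    if "outcome_model" in data:
        data["outcome_model"] = {
            outcome: {stratum: OutcomeModel(**m) if isinstance(m, dict) else m
                      for stratum, m in per.items()}
            for outcome, per in data["outcome_model"].items()
        }
    # YAML has no tuple type; restore tuples where the defaults use them
    if "avpu_probs" in data:
        data["avpu_probs"] = {
            stratum: {assessment: tuple(p) for assessment, p in per.items()}
            for stratum, per in data["avpu_probs"].items()
        }
    for name in ("ais_model", "age_params"):
        if name in data:
            data[name] = {key: tuple(v) for key, v in data[name].items()}
    return CohortSpec(**data)


def save_spec(spec: CohortSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=True)


def load_spec(path) -> CohortSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


__all__ = [
    "STRATA",
    "GEN_BOUNDS",
    "VitalParams",
    "OutcomeModel",
    "CohortSpec",
    "validate_spec",
    "feature_column",
    "linear_predictor",
    "matched_truncnorm",
    "generate_cohort",
    "inject_artifacts",
    "simulate",
    "spec_to_dict",
    "spec_from_dict",
    "save_spec",
    "load_spec",
]
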