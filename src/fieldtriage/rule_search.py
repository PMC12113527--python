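"""Threshold-rule induction by sequential model-based optimization.

The search space is a mixed binary/continuous vector: per candidate
criterion, a binary inclusion flag ("feature combinations") plus its
threshold(s) where the criterion is numeric; AVPU-level and
AVPU-transition candidates are categorical and enter as pure inclusion
flags.  The objective is the mean held-out F2 score of the candidate
rule set over stratified cross-validation folds.

The optimizer is any-surrogate sequential model-based search: after
``n_initial`` random evaluations, a random-forest surrogate is fit to the
observed (parameters, objective) pairs and the next candidate maximizes
expected improvement (mean/spread taken across trees) over a sampled
pool, never re-evaluating an already-scored parameter vector.  When the
space is fully discretized and fits inside the evaluation budget the
optimizer simply enumerates it, which makes the search provably exact on
small spaces.  Ties in the objective are broken toward fewer included
criteria, then toward the earlier evaluation, so results are
deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import StratifiedKFold

from fieldtriage.errors import ConfigError, ValidationError
from fieldtriage.metrics import f_beta_from_counts
from fieldtriage.rules import (
    Criterion,
    RuleSet,
    apply_rule_set,
)

log = logging.getLogger(__name__)

_DIRECTIONS = ("below", "above", "outside", "delta_ge", "avpu_le", "avpu_trans")


@dataclass(frozen=True)
class CandidateCriterion:
    """Template for one searchable criterion.

    ``below``/``above``/``delta_ge`` need one threshold range; ``outside``
    needs both ``low_range`` and ``high_range``; ``avpu_le`` and
    ``avpu_trans`` are fully specified by their levels and contribute only
    an inclusion flag.
    """

    variable: str | None = None
    direction: str = "below"
    assessment: str = "prehospital"
    threshold_range: tuple[float, float] | None = None
    low_range: tuple[float, float] | None = None
    high_range: tuple[float, float] | None = None
    step: float | None = None
    mode: str = "signed"
    level: str | None = None
    from_level: str | None = None
    to_level: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ConfigError(f"unknown direction {self.direction!r}")
        for name, rng_ in (
            ("threshold_range", self.threshold_range),
            ("low_range", self.low_range),
            ("high_range", self.high_range),
        ):
            if rng_ is not None and not rng_[0] < rng_[1]:
                raise ValidationError(f"{name} must satisfy lo < hi, got {rng_}")
        if self.direction in ("below", "above", "delta_ge") and self.threshold_range is None:
            raise ValidationError(f"{self.direction} candidate needs threshold_range")
        if self.direction == "outside" and (self.low_range is None or self.high_range is None):
            raise ValidationError("outside candidate needs low_range and high_range")

    @property
    def n_thresholds(self) -> int:
        return {"below": 1, "above": 1, "delta_ge": 1, "outside": 2}.get(self.direction, 0)

    def ranges(self) -> list[tuple[float, float]]:
        if self.direction == "outside":
            return [self.low_range, self.high_range]
        if self.n_thresholds == 1:
            return [self.threshold_range]
        return []

    def grid(self) -> list[np.ndarray] | None:
        """Threshold grids, or None if any dimension is continuous."""
        if self.n_thresholds == 0:
            return []
        if self.step is None:
            return None
        out = []
        for lo, hi in self.ranges():
            k = int(math.floor((hi - lo) / self.step + 1e-9))
            out.append(lo + self.step * np.arange(k + 1))
        return out

    def build(self, thresholds: tuple[float, ...]) -> Criterion:
        d = self.direction
        if d == "below":
            return Criterion(op="lt", variable=self.variable, threshold=thresholds[0],
                             assessment=self.assessment)
        if d == "above":
            return Criterion(op="gt", variable=self.variable, threshold=thresholds[0],
                             assessment=self.assessment)
        if d == "outside":
            return Criterion(op="outside", variable=self.variable, low=thresholds[0],
                             high=thresholds[1], assessment=self.assessment)
        if d == "delta_ge":
            return Criterion(op="delta_ge", variable=self.variable, threshold=thresholds[0],
                             mode=self.mode, assessment="delta")
        if d == "avpu_le":
            return Criterion(op="avpu_le", level=self.level, assessment=self.assessment)
        return Criterion(op="avpu_trans", from_level=self.from_level,
                         to_level=self.to_level, assessment="delta")


@dataclass(frozen=True)
class SearchSpace:
    candidates: tuple[CandidateCriterion, ...]
    max_criteria: int | None = None

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValidationError("search space needs at least one candidate criterion")

    def enumerable_size(self) -> int | None:
        """Number of non-empty rule sets, or None if any dim is continuous."""
        total = 1
        for cand in self.candidates:
            grids = cand.grid()
            if grids is None:
                return None
            ways = 1
            for g in grids:
                ways *= len(g)
            total *= 1 + ways
        return total - 1  # the all-excluded combination is not a rule set


@dataclass(frozen=True)
class OptimizerConfig:
    budget: int = 200
    n_initial: int = 30
    cv_folds: int = 5
    beta: float = 2.0
    seed: int = 0
    surrogate: str = "model_based"  # or "random" for the ablation baseline

    def __post_init__(self) -> None:
        if not self.budget >= self.n_initial >= 1:
            raise ConfigError(
                f"budget ({self.budget}) must be >= n_initial ({self.n_initial}) >= 1"
            )
        if self.cv_folds < 2:
            raise ConfigError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.surrogate not in ("model_based", "random"):
            raise ConfigError(f"surrogate must be model_based|random, got {self.surrogate!r}")


@dataclass
class TraceEntry:
    iteration: int
    params: tuple
    n_criteria: int
    fold_scores: tuple[float, ...]
    mean_score: float
    incumbent_score: float


@dataclass
class SearchTrace:
    entries: list[TraceEntry] = field(default_factory=list)
    best_index: int = -1

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "iteration": e.iteration,
                "params": repr(e.params),
                "n_criteria": e.n_criteria,
                "fold_f2s": ";".join(f"{s:.6f}" for s in e.fold_scores),
                "mean_f2": e.mean_score,
                "incumbent": e.incumbent_score,
            }
            for e in self.entries
        ]
        return pd.DataFrame(
            rows, columns=["iteration", "params", "n_criteria", "fold_f2s", "mean_f2", "incumbent"]
        )


# -- objective ---------------------------------------------------------------


def cv_fold_scores(rule_set: RuleSet, frame: pd.DataFrame, outcome: str,
                   cv_folds: int = 5, beta: float = 2.0, seed: int = 0) -> list[float]:
    """Held-out F2 per stratified fold for a fixed (no-fitting) rule set."""
    if outcome not in ("icu", "death"):
        raise ConfigError(f"outcome must be icu|death, got {outcome!r}")
    labels = frame[outcome].to_numpy(dtype=bool)
    preds = apply_rule_set(rule_set, frame)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = []
    for _, fold_idx in skf.split(np.zeros(len(labels)), labels):
        p, y = preds[fold_idx], labels[fold_idx]
        tp = int(np.sum(p & y))
        fp = int(np.sum(p & ~y))
        fn = int(np.sum(~p & y))
        score = f_beta_from_counts(tp, fp, fn, beta)
        if score is None or not y.any():
            log.warning("fold with undefined F2 (no positive labels); scored as 0")
            score = 0.0
        scores.append(score)
    return scores


def objective(rule_set: RuleSet, frame: pd.DataFrame, outcome: str,
              cv_folds: int = 5, beta: float = 2.0, seed: int = 0) -> float:
    """Mean held-out F2 of the candidate rule set (the search objective)."""
    return float(np.mean(cv_fold_scores(rule_set, frame, outcome, cv_folds, beta, seed)))


# -- parameter vectors -------------------------------------------------------


def _params_n_criteria(space: SearchSpace, params: tuple) -> int:
    count, i = 0, 0
    for cand in space.candidates:
        count += int(params[i])
        i += 1 + cand.n_thresholds
    return count


def build_rule_set(space: SearchSpace, params: tuple, name: str = "candidate") -> RuleSet:
    """Materialize a parameter vector into a rule set."""
    criteria, i = [], 0
    for cand in space.candidates:
        include = int(params[i])
        thresholds = tuple(params[i + 1: i + 1 + cand.n_thresholds])
        i += 1 + cand.n_thresholds
        if include:
            criteria.append(cand.build(thresholds))
    if not criteria:
        raise ValidationError("parameter vector includes no criteria")
    return RuleSet(name=name, criteria=tuple(criteria))


def _mid(lo: float, hi: float) -> float:
    return (lo + hi) / 2.0


def _random_params(space: SearchSpace, rng: np.random.Generator) -> tuple:
    while True:
        params = []
        n_inc = 0
        for cand in space.candidates:
            include = int(rng.random() < 0.5)
            n_inc += include
            params.append(include)
            grids = cand.grid()
            for k, (lo, hi) in enumerate(cand.ranges()):
                if grids is not None:
                    value = float(rng.choice(grids[k]))
                else:
                    value = float(rng.uniform(lo, hi))
                params.append(value if include else _mid(lo, hi))
        if n_inc == 0:
            continue
        if space.max_criteria is not None and n_inc > space.max_criteria:
            continue
        return tuple(round(p, 9) for p in params)


def _perturb_params(space: SearchSpace, params: tuple, rng: np.random.Generator) -> tuple:
    out, i = [], 0
    for cand in space.candidates:
        include = int(params[i])
        if rng.random() < 0.15:
            include = 1 - include
        out.append(include)
        grids = cand.grid()
        for k, (lo, hi) in enumerate(cand.ranges()):
            value = params[i + 1 + k]
            if include:
                if grids is not None:
                    g = grids[k]
                    pos = int(np.argmin(np.abs(g - value)))
                    pos = int(np.clip(pos + rng.integers(-2, 3), 0, len(g) - 1))
                    value = float(g[pos])
                else:
                    value = float(np.clip(value + rng.normal(0, 0.1 * (hi - lo)), lo, hi))
            out.append(value)
        i += 1 + cand.n_thresholds
    n_inc = _params_n_criteria(space, tuple(out))
    if n_inc == 0 or (space.max_criteria is not None and n_inc > space.max_criteria):
        return _random_params(space, rng)
    return tuple(round(p, 9) for p in out)


def _enumerate_params(space: SearchSpace):
    """All parameter vectors of a fully discretized space, in a fixed order."""
    per_candidate = []
    for cand in space.candidates:
        grids = cand.grid()
        options = [(0,) + tuple(_mid(lo, hi) for lo, hi in cand.ranges())]
        if cand.n_thresholds == 0:
            options.append((1,))
        elif cand.n_thresholds == 1:
            options.extend((1, float(t)) for t in grids[0])
        else:
            options.extend(
                (1, float(a), float(b)) for a in grids[0] for b in grids[1]
            )
        per_candidate.append(options)
    out: list[tuple] = [()]
    for options in per_candidate:
        out = [prefix + opt for prefix in out for opt in options]
    result = []
    for params in out:
        n_inc = _params_n_criteria(space, params)
        if n_inc == 0:
            continue
        if space.max_criteria is not None and n_inc > space.max_criteria:
            continue
        result.append(tuple(round(p, 9) for p in params))
    return result


def _scale_matrix(space: SearchSpace, rows: list[tuple]) -> np.ndarray:
    """Surrogate design matrix with thresholds scaled to [0, 1]."""
    x = np.asarray(rows, dtype=float)
    i = 0
    for cand in space.candidates:
        for k, (lo, hi) in enumerate(cand.ranges()):
            x[:, i + 1 + k] = (x[:, i + 1 + k] - lo) / (hi - lo)
        i += 1 + cand.n_thresholds
    return x


# -- the optimizer -----------------------------------------------------------


def optimize(space: SearchSpace, frame: pd.DataFrame, outcome: str,
             config: OptimizerConfig) -> tuple[RuleSet, SearchTrace]:
    """Search the space for the rule set maximizing CV-mean F2.

    Fully reproducible under ``config.seed``.  With ``budget == n_initial``
    or ``surrogate="random"`` the procedure degenerates to reproducible
    random search; on a fully discretized space whose size fits inside the
    budget it evaluates every candidate exactly once.
    """
    rng = np.random.default_rng(config.seed)
    trace = SearchTrace()
    evaluated: dict[tuple, float] = {}

    def evaluate(params: tuple) -> float:
        rule_set = build_rule_set(space, params)
        fold_scores = cv_fold_scores(
            rule_set, frame, outcome, config.cv_folds, config.beta, config.seed
        )
        score = float(np.mean(fold_scores))
        evaluated[params] = score
        incumbent = max(score, trace.entries[-1].incumbent_score) if trace.entries else score
        trace.entries.append(
            TraceEntry(
                iteration=len(trace.entries),
                params=params,
                n_criteria=_params_n_criteria(space, params),
                fold_scores=tuple(fold_scores),
                mean_score=score,
                incumbent_score=incumbent,
            )
        )
        return score

    size = space.enumerable_size()
    if size is not None and size <= config.budget:
        for params in _enumerate_params(space):
            evaluate(params)
    else:
        n_initial = min(config.n_initial, config.budget)
        while len(evaluated) < n_initial:
            params = _random_params(space, rng)
            if params not in evaluated:
                evaluate(params)
        while len(evaluated) < config.budget:
            if config.surrogate == "random":
                params = _random_params(space, rng)
                if params in evaluated:
                    continue
                evaluate(params)
                continue
            params = _propose(space, evaluated, rng)
            if params is None:
                break
            evaluate(params)

    best = max(
        trace.entries, key=lambda e: (e.mean_score, -e.n_criteria, -e.iteration)
    )
    trace.best_index = best.iteration
    rule_set = build_rule_set(space, best.params, name="optimized")
    log.info(
        "optimize: %d evaluations, best mean F2 %.4f with %d criteria",
        len(trace.entries), best.mean_score, best.n_criteria,
    )
    return rule_set, trace


def _propose(space: SearchSpace, evaluated: dict[tuple, float],
             rng: np.random.Generator):
    """Next parameter vector by expected improvement under an RF surrogate."""
    xs = list(evaluated.keys())
    ys = np.array([evaluated[p] for p in xs])
    forest = RandomForestRegressor(
        n_estimators=64, min_samples_leaf=2, random_state=int(rng.integers(2**31))
    )
    forest.fit(_scale_matrix(space, xs), ys)

    incumbent_params = xs[int(np.argmax(ys))]
    pool: list[tuple] = []
    seen = set(evaluated)
    for _ in range(512):
        p = _random_params(space, rng)
        if p not in seen:
            pool.append(p)
            seen.add(p)
    for _ in range(128):
        p = _perturb_params(space, incumbent_params, rng)
        if p not in seen:
            pool.append(p)
            seen.add(p)
    if not pool:
        return None
    x_pool = _scale_matrix(space, pool)
    per_tree = np.stack([tree.predict(x_pool) for tree in forest.estimators_])
    mu = per_tree.mean(axis=0)
    sigma = np.maximum(per_tree.std(axis=0), 1e-6)
    best = ys.max()
    z = (mu - best) / sigma
    from scipy.stats import norm

    ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
    return pool[int(np.argmax(ei))]


def finalize(best: RuleSet, train_frame: pd.DataFrame, test_frame: pd.DataFrame,
             outcome: str, beta: float = 2.0):
    """Single-pass evaluation of the chosen rule set on the untouched test set.

    Raises if the test set is empty or shares record ids with training.
    """
    from fieldtriage.report import evaluate_cell

    if len(test_frame) == 0:
        raise ValidationError("test set is empty")
    overlap = set(train_frame["id"]) & set(test_frame["id"])
    if overlap:
        raise ValidationError(
            f"train and test sets share {len(overlap)} record ids (e.g. {sorted(overlap)[:3]})"
        )
    return evaluate_cell(best, test_frame, outcome, beta=beta)


__all__ = [
    "CandidateCriterion",
    "SearchSpace",
    "OptimizerConfig",
    "TraceEntry",
    "SearchTrace",
    "cv_fold_scores",
    "objective",
    "build_rule_set",
    "optimize",
    "finalize",
]
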