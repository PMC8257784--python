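"""Motor-learning scores and their relation to axonal swelling density.

Cerebellar learning is scored per animal from raw task tables: accelerating
rotarod (latency to fall, trials x days), Erasmus ladder (short-step counts
per day), or a precomputed vestibulo-ocular-reflex gain change.  Scores are
then correlated with the density of Purkinje-cell axonal swellings, cohorts
are split into low/high learners, and groups are compared with standard
parametric or nonparametric tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "BehaviorRecord",
    "CorrelationResult",
    "LearnerSplit",
    "GroupComparison",
    "rotarod_learning_score",
    "erasmus_learning_score",
    "pearson_with_p",
    "split_learners",
    "compare_groups",
]

TASKS = ("rotarod", "erasmus", "vor")


@dataclass(frozen=True)
class BehaviorRecord:
    """Per-animal task performance plus axonal swelling density.

    ``per_day_scores`` is a day x trial matrix: rotarod latencies in
    seconds (7 days x 4 trials in the standard protocol), Erasmus-ladder
    short-step counts as a day x 1 column, or empty for a precomputed VOR
    score carried in ``precomputed_score``.
    """

    animal_id: str
    task: str
    per_day_scores: np.ndarray
    swelling_density_pct: float
    region: str = "lobule_III"
    precomputed_score: Optional[float] = None
    ground_truth: Optional[dict] = None

    def __post_init__(self):
        if self.task not in TASKS:
            raise InvalidParameterError(f"unknown task {self.task!r}")
        if not 0.0 <= self.swelling_density_pct <= 100.0:
            raise InvalidParameterError("swelling_density_pct must be in [0, 100]")
        object.__setattr__(
            self, "per_day_scores", np.atleast_2d(np.asarray(self.per_day_scores, dtype=float))
        )

    def learning_score(self) -> float:
        """Task-appropriate learning score for this animal."""
        if self.task == "rotarod":
            return rotarod_learning_score(self.per_day_scores)
        if self.task == "erasmus":
            return erasmus_learning_score(self.per_day_scores[:, 0])
        if self.precomputed_score is None:
            raise InvalidInputError("VOR record lacks a precomputed score")
        return float(self.precomputed_score)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its exact two-tailed p-value.

    The p-value comes from the t transform ``t = r * sqrt(n-2) / sqrt(1-r^2)``
    referred to a Student t distribution with ``n - 2`` degrees of freedom.
    """

    r: float
    n: int
    t_stat: float
    p_two_tailed: float

    @classmethod
    def from_r(cls, r: float, n: int) -> "CorrelationResult":
        """Recompute t and p for a given sample correlation and size."""
        if not -1.0 <= r <= 1.0:
            raise InvalidParameterError("r must lie in [-1, 1]")
        if n < 3:
            raise InsufficientDataError("need n >= 3 for a correlation p-value")
        if abs(r) == 1.0:
            return cls(r=float(r), n=int(n), t_stat=float("inf") * np.sign(r), p_two_tailed=0.0)
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        return cls(r=float(r), n=int(n), t_stat=float(t), p_two_tailed=float(p))


@dataclass(frozen=True)
class LearnerSplit:
    """Partition of a cohort into low and high learners."""

    low: tuple
    high: tuple
    split_rule: str
    median_score: float


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# learning scores


def rotarod_learning_score(
    latencies_s: np.ndarray, first_day: int = 0, last_day: int = -1
) -> float:
    """Rotarod learning: gain in latency to fall across training.

    The score is the mean of the last two trials on the final day minus the
    mean of the last two trials on the first day, in seconds.  Day indices
    are configurable for truncated protocols.
    """
    m = np.atleast_2d(np.asarray(latencies_s, dtype=float))
    if m.shape[0] < 2:
        raise InvalidInputError("need at least 2 days of rotarod trials")
    if m.shape[1] < 2:
        raise InvalidInputError("need at least 2 trials per day")
    first = m[first_day, -2:]
    last = m[last_day, -2:]
    if np.any(~np.isfinite(first)) or np.any(~np.isfinite(last)):
        raise InvalidInputError("scored trials must be finite")
    return float(np.mean(last) - np.mean(first))


def erasmus_learning_score(short_steps: Sequence[float], method: str = "difference") -> float:
    """Erasmus-ladder learning: change in short-step count across days.

    ``difference`` (default) is final-day minus first-day count; ``slope``
    fits a per-day least-squares slope instead.
    """
    counts = np.asarray(short_steps, dtype=float).ravel()
    if counts.size < 2:
        raise InvalidInputError("need at least 2 days of ladder counts")
    if np.any(~np.isfinite(counts)):
        raise InvalidInputError("missing days in ladder counts")
    if method == "difference":
        return float(counts[-1] - counts[0])
    if method == "slope":
        days = np.arange(counts.size, dtype=float)
        return float(np.polyfit(days, counts, 1)[0])
    raise InvalidParameterError("method must be 'difference' or 'slope'")


# ---------------------------------------------------------------------------
# statistics


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with exact two-tailed p.

    Requires n >= 3, finite values and non-zero variance in both inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError("need n >= 3 for a correlation")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise InvalidInputError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    return CorrelationResult.from_r(r, n)


def split_learners(
    cohort: Union[Sequence[BehaviorRecord], Mapping[str, float]],
    tie_to: str = "high",
) -> LearnerSplit:
    """Median split of a cohort into low and high learners.

    Animals scoring strictly below the median are low learners; animals at
    or above the median are high learners (ties go to the high group by
    default).  The rule is recorded in the result so downstream tables can
    report it.
    """
    if isinstance(cohort, Mapping):
        ids = list(cohort.keys())
        scores = np.asarray([cohort[k] for k in ids], dtype=float)
    else:
        ids = [rec.animal_id for rec in cohort]
        scores = np.asarray([rec.learning_score() for rec in cohort], dtype=float)
    if len(ids) < 4:
        raise InsufficientDataError("need at least 4 animals to split")
    if np.all(scores == scores[0]):
        raise DegenerateDataError("all learning scores identical; split undefined")
    med = float(np.median(scores))
    if tie_to == "high":
        high_mask = scores >= med
    elif tie_to == "low":
        high_mask = scores > med
    else:
        raise InvalidParameterError("tie_to must be 'high' or 'low'")
    low = tuple(i for i, h in zip(ids, high_mask) if not h)
    high = tuple(i for i, h in zip(ids, high_mask) if h)
    return LearnerSplit(
        low=low,
        high=high,
        split_rule=f"median split, ties to {tie_to}",
        median_score=med,
    )


def compare_groups(a: Sequence[float], b: Sequence[float], method: str = "t_two_tailed") -> GroupComparison:
    """Two-group comparison.

    ``t_two_tailed``: unpaired Student's t-test (equal variances).
    ``mannwhitney_two_tailed`` / ``mannwhitney_one_tailed``: Mann-Whitney
    U-test; the exact null distribution is used when the combined sample
    size is at most 20 and there are no ties, otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    if method == "t_two_tailed":
        if a.size < 2 or b.size < 2:
            raise InsufficientDataError("t-test needs n >= 2 per group")
        res = stats.ttest_ind(a, b, equal_var=True)
        return GroupComparison(float(res.statistic), float(res.pvalue), method, a.size, b.size)
    if method in ("mannwhitney_two_tailed", "mannwhitney_one_tailed"):
        alternative = "two-sided" if method.endswith("two_tailed") else "greater"
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        mw_method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative=alternative, method=mw_method)
        return GroupComparison(float(res.statistic), float(res.pvalue), method, a.size, b.size)
    raise InvalidParameterError(f"unknown method {method!r}")
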