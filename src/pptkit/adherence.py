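"""Diet-adherence feedback grading.

Two 0-100 grades summarise each 2-week feedback period:

* the **composition grade** converts each meal's predictor score (1 best .. 5
  worst) to a grade via a fixed map (1->100, 2->80, 3->50, 4->25, 5->0) and
  averages the grades calorie-wise, with each meal's energy clamped into the
  (100, 500) kcal interval before weighting;
* the **calorie grade** penalises deviation of mean daily energy intake from
  the prescribed caloric target: 100 up to 15% deviation, 0 from 60%
  deviation, linear in between.

Feedback reports additionally list the k best and worst logged meals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import MealEvent

DEFAULT_GRADE_MAP = {1: 100.0, 2: 80.0, 3: 50.0, 4: 25.0, 5: 0.0}


@dataclass
class AdherenceConfig:
    caloric_target: float = 2000.0  # kcal/day
    trim_kcal: tuple[float, float] = (100.0, 500.0)
    min_logged_kcal: float = 100.0
    grade_map: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_GRADE_MAP))
    # deviation fractions where the linear calorie penalty starts and bottoms out
    penalty_knots: tuple[float, float] = (0.15, 0.60)

    def __post_init__(self) -> None:
        g = [self.grade_map[s] for s in sorted(self.grade_map)]
        if any(not (0 <= v <= 100) for v in g):
            raise ValueError("grade map values must lie in [0, 100]")
        if any(b > a for a, b in zip(g, g[1:])):
            raise ValueError("grade map must be non-increasing in meal score")
        lo, hi = self.penalty_knots
        if not (0 <= lo < hi):
            raise ValueError("penalty knots must satisfy 0 <= lo < hi")


@dataclass
class AdherenceReport:
    period: str
    composition_grade: float | None
    calorie_grade: float | None
    best_meals: list[MealEvent]
    worst_meals: list[MealEvent]
    n_unscored: int = 0


def meal_grade(score: int, config: AdherenceConfig | None = None) -> float:
    """Grade for one meal score via the configured lookup table."""
    config = config or AdherenceConfig()
    if score not in config.grade_map:
        raise ValueError(f"meal score {score!r} outside {sorted(config.grade_map)}")
    return config.grade_map[score]


def composition_grade(
    meals: Sequence[MealEvent], config: AdherenceConfig | None = None
) -> tuple[float | None, int]:
    """Calorie-weighted mean meal grade, or None if too little was logged.

    Each meal's weight is its energy clamped into the trim interval; the
    minimum-logging rule uses the untrimmed total. Meals without a score are
    excluded; their count is returned alongside the grade.
    """
    config = config or AdherenceConfig()
    scored = [m for m in meals if m.meal_score is not None]
    n_unscored = len(meals) - len(scored)
    total_kcal = sum(m.kcal for m in scored)
    if total_kcal < config.min_logged_kcal or not scored:
        return None, n_unscored
    lo, hi = config.trim_kcal
    w = np.clip([m.kcal for m in scored], lo, hi)
    g = np.array([meal_grade(m.meal_score, config) for m in scored])
    return float(np.dot(w, g) / w.sum()), n_unscored


def calorie_grade(
    mean_daily_intake: float, caloric_target: float | None = None,
    config: AdherenceConfig | None = None,
) -> float:
    """Linear-penalty grade for deviation of intake from the caloric target."""
    config = config or AdherenceConfig()
    ct = config.caloric_target if caloric_target is None else caloric_target
    if ct <= 0:
        raise ValueError("caloric target must be positive")
    if mean_daily_intake < 0:
        raise ValueError("intake must be >= 0")
    lo, hi = config.penalty_knots
    d = abs(mean_daily_intake - ct) / ct
    if d <= lo:
        return 100.0
    if d >= hi:
        return 0.0
    return 100.0 * (hi - d) / (hi - lo)


def feedback_report(
    meals: Sequence[MealEvent],
    config: AdherenceConfig | None = None,
    period: str = "period",
    period_days: float = 14.0,
    k: int = 5,
) -> AdherenceReport:
    """One 2-week feedback report: both grades plus best/worst meal lists.

    Best meals are the k lowest-score meals (ties broken by ascending kcal),
    worst the k highest-score meals (ties by descending kcal); unscored
    meals are omitted from both lists.
    """
    config = config or AdherenceConfig()
    comp, n_unscored = composition_grade(meals, config)
    if meals:
        intake = sum(m.kcal for m in meals) / period_days
        cal = calorie_grade(intake, config=config)
    else:
        cal = None
    scored = [m for m in meals if m.meal_score is not None]
    best = sorted(scored, key=lambda m: (m.meal_score, m.kcal))[:k]
    worst = sorted(scored, key=lambda m: (-m.meal_score, -m.kcal))[:k]
    return AdherenceReport(
        period=period,
        composition_grade=comp,
        calorie_grade=cal,
        best_meals=best,
        worst_meals=worst,
        n_unscored=n_unscored,
    )


def mean_feedback_grade(
    reports: Mapping[str, Iterable[AdherenceReport]],
) -> dict[str, float]:
    """Unweighted mean composition grade per participant across periods.

    Participants whose reports all lack a composition grade are omitted.
    The adherence subgroup analysis splits participants at the group median
    of this mean.
    """
    out: dict[str, float] = {}
    for pid, reps in reports.items():
        grades = [r.composition_grade for r in reps if r.composition_grade is not None]
        if grades:
            out[pid] = float(np.mean(grades))
    return out
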