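"""Menu construction and validation for the two study diets.

The Mediterranean-style (MED) arm prescribes macronutrient bounds as
percentages of energy (carbohydrate 45-65%, protein 15-20%, fat < 35%,
saturated fat < 10%); menus are validated by their energy-weighted
macronutrient split over the candidate pool. The personalized
postprandial-targeting (PPT) arm ranks candidate meals 1..5 by each
person's predicted PPGR and fills menu slots with the best-scoring meals.

The score thresholds are person-relative percentile cut-points (default
quintiles of the person's predicted-PPGR reference distribution) and are
fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MealEvent

MED_BOUNDS = {
    # % of energy: (low, high, upper_strict)
    "carb": (45.0, 65.0, False),
    "protein": (15.0, 20.0, False),
    "fat": (0.0, 35.0, True),
    "sat_fat": (0.0, 10.0, True),
}

#: crossover menus hold 4-5 meal options per main slot, 10-12 per snack slot
DEFAULT_SLOT_COUNTS = {"breakfast": 5, "lunch": 5, "dinner": 5, "snack": 10}

KCAL_PER_G = {"carb": 4.0, "protein": 4.0, "fat": 9.0, "sat_fat": 9.0}


@dataclass
class DietSpec:
    name: str  # "MED" or "PPT"
    bounds: dict[str, tuple[float, float, bool]] = field(default_factory=lambda: dict(MED_BOUNDS))
    max_meal_score: int = 2  # PPT only

    def __post_init__(self) -> None:
        for k, (lo, hi, _) in self.bounds.items():
            if not (0 <= lo <= hi <= 100):
                raise ValueError(f"bound {k} = ({lo}, {hi}) outside [0, 100]")


@dataclass
class MenuValidation:
    valid: bool
    percentages: dict[str, float]
    violations: list[str]
    n_excluded_zero_kcal: int = 0


@dataclass
class Menu:
    slots: dict[str, list[MealEvent]]

    def all_meals(self) -> list[MealEvent]:
        return [m for meals in self.slots.values() for m in meals]


def assign_meal_score(
    predicted_ppgr: float,
    person_reference: np.ndarray,
    cut_percentiles: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0),
) -> int:
    """Rank a predicted PPGR within the person's reference distribution.

    Returns 1 + the number of percentile cut-points the prediction strictly
    exceeds, i.e. the quintile rank by default (1 = lowest-response fifth).
    Ties at a cut-point take the lower score.
    """
    ref = np.asarray(person_reference, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference distribution")
    if ref.size < 5:
        raise ValueError("reference distribution needs at least 5 values")
    cuts = np.percentile(ref, cut_percentiles)
    return int(1 + np.sum(predicted_ppgr > cuts))


def _energy_percentages(meals: list[MealEvent]) -> tuple[dict[str, float], int]:
    usable = [m for m in meals if m.kcal > 0]
    n_excluded = len(meals) - len(usable)
    total = sum(m.kcal for m in usable)
    if total <= 0:
        raise ValueError("menu has no energy")
    grams = {
        "carb": sum(m.carb_g for m in usable),
        "protein": sum(m.protein_g for m in usable),
        "fat": sum(m.fat_g for m in usable),
        "sat_fat": sum(m.sat_fat_g for m in usable),
    }
    pct = {k: 100.0 * KCAL_PER_G[k] * g / total for k, g in grams.items()}
    return pct, n_excluded


def validate_menu(menu: Menu, spec: DietSpec) -> MenuValidation:
    """Check a menu's energy-weighted macronutrient split against diet bounds.

    The split is computed over the whole candidate pool. Carbohydrate and
    protein bounds are inclusive ranges; fat and saturated-fat upper bounds
    are strict (`< 35%`, `< 10%`).
    """
    pct, n_excluded = _energy_percentages(menu.all_meals())
    violations = []
    for k, (lo, hi, upper_strict) in spec.bounds.items():
        v = pct[k]
        if v < lo or (v >= hi if upper_strict else v > hi):
            op = "<" if upper_strict else "<="
            violations.append(f"{k} = {v:.1f}% outside [{lo}, {hi}{')' if upper_strict else ']'} ({op} bound)")
    return MenuValidation(valid=not violations, percentages=pct,
                          violations=violations, n_excluded_zero_kcal=n_excluded)


def dominant_food(meal: MealEvent, threshold: float = 0.70) -> str | None:
    """The single food strictly exceeding ``threshold`` of meal calories.

    Returns None when no food dominates. Errors when the foods' energies
    exceed the meal's stated energy by more than 10%.
    """
    if not meal.foods:
        raise ValueError("meal has no component foods")
    food_kcal = sum(k for _, k in meal.foods)
    if meal.kcal > 0 and food_kcal > 1.10 * meal.kcal:
        raise ValueError(
            f"component foods sum to {food_kcal:.0f} kcal, exceeding meal "
            f"energy {meal.kcal:.0f} kcal by more than 10%"
        )
    ref = meal.kcal if meal.kcal > 0 else food_kcal
    name, kcal = max(meal.foods, key=lambda fk: fk[1])
    return name if kcal > threshold * ref else None


def build_ppt_menu(
    candidates: list[tuple[MealEvent, float]],
    person_reference: np.ndarray,
    slots: dict[str, list[int]] | None = None,
    max_score: int = 2,
    slot_counts: dict[str, int] | None = None,
) -> Menu:
    """Fill menu slots with the best-scoring candidate meals for a person.

    ``candidates`` pairs each meal with its predicted PPGR; ``slots`` maps a
    slot name to candidate indices eligible for it (default: every candidate
    eligible for every slot). Qualifying meals (score <= ``max_score``) are
    taken lowest score first, ties broken by lower predicted PPGR then by
    name. Raises when a slot cannot be filled.
    """
    slot_counts = dict(DEFAULT_SLOT_COUNTS) if slot_counts is None else slot_counts
    if slots is None:
        slots = {s: list(range(len(candidates))) for s in slot_counts}
    scored = [
        (assign_meal_score(pred, person_reference), pred, meal.name, i)
        for i, (meal, pred) in enumerate(candidates)
    ]
    menu_slots: dict[str, list[MealEvent]] = {}
    for slot, idxs in slots.items():
        want = slot_counts.get(slot, 0)
        pool = sorted(s for s in scored if s[3] in set(idxs) and s[0] <= max_score)
        if len(pool) < want:
            raise ValueError(
                f"slot {slot!r}: only {len(pool)} candidates with score <= "
                f"{max_score}, need {want}"
            )
        menu_slots[slot] = [candidates[i][0] for (_, _, _, i) in pool[:want]]
    return Menu(slots=menu_slots)
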