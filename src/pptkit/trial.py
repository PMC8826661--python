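"""Crossover and longitudinal trial statistics.

Covers the statistical battery of a two-period crossover diet comparison
followed by a single-arm 6-month intervention:

* within-person crossover effects (paired t, paired rank test, and a
  linear-mixed-model sensitivity suite with period/sequence terms plus a
  first-period parallel-groups check);
* one-sample pre/post tests of 6-month changes (rank alternative for
  HOMA-IR);
* HOMA-IR from fasting glucose and insulin;
* diabetes-remission rate (end HbA1c below the diagnostic threshold among
  participants starting at or above it);
* adherence median-split subgroup comparison;
* intra- vs inter-person coefficient of variation of PPGRs to meals
  sharing a dominant food.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CROSSOVER_MODELS = ("paired_t", "mann_whitney", "lmm", "lmm_period", "lmm_sequence", "first_period")

SEQUENCES = ("PPT-MED", "MED-PPT")


@dataclass(frozen=True)
class CrossoverRecord:
    """One participant's two-period outcomes for a single endpoint."""

    participant_id: str
    sequence: str  # "PPT-MED" or "MED-PPT"
    ppt_value: float
    med_value: float

    def __post_init__(self) -> None:
        if self.sequence not in SEQUENCES:
            raise ValueError(f"sequence must be one of {SEQUENCES}")

    @property
    def period1_diet(self) -> str:
        return self.sequence.split("-")[0]


@dataclass
class EffectEstimate:
    outcome: str
    model: str
    estimate: float
    dispersion: float | None  # SD of within-person differences, or model SE
    p_value: float | None
    n: int

    def ci95(self) -> tuple[float, float] | None:
        """95% CI of the mean within-person difference (paired-t model)."""
        if self.model != "paired_t" or self.dispersion is None or self.n < 2:
            return None
        half = stats.t.ppf(0.975, self.n - 1) * self.dispersion / np.sqrt(self.n)
        return (self.estimate - half, self.estimate + half)


def _records_long(records: list[CrossoverRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for diet, val in (("PPT", r.ppt_value), ("MED", r.med_value)):
            period = 1 if diet == r.period1_diet else 2
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "diet": diet,
                    "treat": 1.0 if diet == "PPT" else 0.0,
                    "period": float(period),
                    "sequence": r.sequence,
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


def crossover_effect(
    records: list[CrossoverRecord],
    outcome: str = "outcome",
    model: str = "paired_t",
) -> EffectEstimate:
    """Treatment effect (PPT minus MED) for one crossover endpoint.

    Models
    ------
    ``paired_t``
        Mean and SD of within-person PPT-MED differences; two-sided
        one-sample t test of the differences against zero.
    ``mann_whitney``
        The paired rank alternative: Wilcoxon signed-rank test of the
        within-person differences against zero (estimate stays the mean
        difference).
    ``lmm`` / ``lmm_period`` / ``lmm_sequence``
        Linear mixed model with participant random intercept and treatment
        fixed effect, optionally adding period and sequence fixed effects
        (the crossover sensitivity suite); dispersion is the treatment SE.
    ``first_period``
        Parallel-groups check: two-sample t test of period-1 values, PPT
        sequence group vs MED sequence group.
    """
    records = [r for r in records if np.isfinite(r.ppt_value) and np.isfinite(r.med_value)]
    n = len(records)
    if n < 3:
        raise ValueError("need >= 3 participants with both periods")
    if model not in CROSSOVER_MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {CROSSOVER_MODELS}")

    diffs = np.array([r.ppt_value - r.med_value for r in records])

    if model == "paired_t":
        est = float(diffs.mean())
        sd = float(diffs.std(ddof=1))
        if sd == 0:
            p = 1.0
        else:
            p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
        return EffectEstimate(outcome, model, est, sd, p, n)

    if model == "mann_whitney":
        est = float(diffs.mean())
        sd = float(diffs.std(ddof=1))
        nz = diffs[diffs != 0]
        p = 1.0 if nz.size == 0 else float(stats.wilcoxon(nz).pvalue)
        return EffectEstimate(outcome, model, est, sd, p, n)

    if model == "first_period":
        long = _records_long(records)
        p1 = long[long["period"] == 1]
        a = p1.loc[p1["diet"] == "PPT", "value"].to_numpy()
        b = p1.loc[p1["diet"] == "MED", "value"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError("first-period model needs >= 2 participants per sequence")
        res = stats.ttest_ind(a, b)
        se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
        return EffectEstimate(outcome, model, float(a.mean() - b.mean()), se, float(res.pvalue), n)

    # mixed models
    import statsmodels.formula.api as smf

    long = _records_long(records)
    formula = {"lmm": "value ~ treat",
               "lmm_period": "value ~ treat + period",
               "lmm_sequence": "value ~ treat + period + C(sequence)"}[model]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm(formula, long, groups=long["participant_id"]).fit(reml=True)
    return EffectEstimate(
        outcome, model,
        float(fit.params["treat"]),
        float(fit.bse["treat"]),
        float(fit.pvalues["treat"]),
        n,
    )


def longitudinal_change(
    before: np.ndarray,
    after: np.ndarray,
    outcome: str = "outcome",
    test: str = "t",
) -> EffectEstimate:
    """Mean +/- SD of (after - before) with a two-sided test against zero.

    ``test="t"`` is the one-sample t test; ``test="rank"`` the Wilcoxon
    signed-rank alternative used for skewed endpoints such as HOMA-IR.
    Participants missing either timepoint are dropped.
    """
    before = np.asarray(before, float)
    after = np.asarray(after, float)
    ok = np.isfinite(before) & np.isfinite(after)
    d = (after - before)[ok]
    if len(d) < 3:
        raise ValueError("need >= 3 participants with both timepoints")
    est = float(d.mean())
    sd = float(d.std(ddof=1))
    if test == "t":
        p = 1.0 if sd == 0 else float(stats.ttest_1samp(d, 0.0).pvalue)
    elif test == "rank":
        nz = d[d != 0]
        p = 1.0 if nz.size == 0 else float(stats.wilcoxon(nz).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return EffectEstimate(outcome, f"one_sample_{test}", est, sd, p, len(d))


def homa_ir(fpg_mgdl: float, insulin_uUml: float) -> float:
    """Homeostatic model assessment of insulin resistance (mass units):
    fasting glucose (mg/dl) x fasting insulin (uU/ml) / 405."""
    if fpg_mgdl <= 0 or insulin_uUml <= 0:
        raise ValueError("FPG and insulin must be positive")
    return fpg_mgdl * insulin_uUml / 405.0


@dataclass
class RemissionResult:
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float | None:
        return self.numerator / self.denominator if self.denominator else None


def remission_rate(
    baseline_hba1c: np.ndarray,
    end_hba1c: np.ndarray,
    threshold: float = 6.5,
) -> RemissionResult:
    """Diabetes remission: end HbA1c strictly below ``threshold`` among
    participants whose baseline HbA1c was at or above it."""
    b = np.asarray(baseline_hba1c, float)
    e = np.asarray(end_hba1c, float)
    ok = np.isfinite(b) & np.isfinite(e)
    b, e = b[ok], e[ok]
    denom = b >= threshold
    num = denom & (e < threshold)
    return RemissionResult(int(num.sum()), int(denom.sum()))


def adherence_subgroup_compare(
    changes: pd.DataFrame,
    grades: dict[str, float],
) -> pd.DataFrame:
    """Compare 6-month outcome changes between high- and low-adherence halves.

    Participants (rows of ``changes``, one column per outcome change) are
    split at the median of their mean feedback grade; ties at the median
    join the high group. Each outcome gets a two-sample t test. Returns one
    row per outcome with group means/SDs and p.
    """
    common = [p for p in changes.index if p in grades]
    if len(common) < 4:
        raise ValueError("need >= 2 participants per subgroup")
    g = pd.Series({p: grades[p] for p in common})
    med = float(g.median())
    high = g.index[g >= med]
    low = g.index[g < med]
    if len(high) < 2 or len(low) < 2:
        raise ValueError(
            f"degenerate median split at grade {med:.1f}: "
            f"{len(high)} high vs {len(low)} low"
        )
    rows = []
    for col in changes.columns:
        a = changes.loc[high, col].dropna().to_numpy(float)
        b = changes.loc[low, col].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            continue
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p = float(stats.ttest_ind(a, b).pvalue)
        rows.append(
            {
                "outcome": col,
                "high_mean": a.mean(), "high_sd": a.std(ddof=1), "n_high": len(a),
                "low_mean": b.mean(), "low_sd": b.std(ddof=1), "n_low": len(b),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["median_grade"] = med
    return out


@dataclass
class IntraInterCV:
    mean_intra_cv: float
    mean_inter_cv: float
    p_value: float | None
    per_food: pd.DataFrame  # food, intra_cv (person-mean), inter_cv, n_persons
    skipped_foods: list[str]


def intra_inter_cv(ppgrs: pd.DataFrame, min_meals: int = 2, min_persons: int = 2) -> IntraInterCV:
    """Within- vs between-person variability of PPGRs to a shared dominant food.

    ``ppgrs`` needs columns participant_id, food, iauc. For each
    (participant, food) cell with >= ``min_meals`` meals the intra CV is
    sd/mean of that cell's iAUCs; the overall intra CV averages the cells.
    Per food, the inter CV is sd/mean across participants of the per-person
    median iAUC; the overall inter CV averages foods with >=
    ``min_persons`` qualifying participants. p is a two-sided paired t test
    of per-food (intra, inter) pairs (None with fewer than 2 foods).
    """
    cells = []
    per_food_rows = []
    skipped = []
    for food, grp in ppgrs.groupby("food"):
        cell_cvs = {}
        medians = {}
        for pid, sub in grp.groupby("participant_id"):
            vals = sub["iauc"].to_numpy(float)
            if len(vals) >= min_meals:
                m = vals.mean()
                cell_cvs[pid] = 0.0 if m == 0 else vals.std(ddof=1) / m
                medians[pid] = float(np.median(vals))
        if len(cell_cvs) < min_persons:
            skipped.append(food)
            continue
        cells.extend(cell_cvs.values())
        med_vals = np.array(list(medians.values()))
        mm = med_vals.mean()
        inter = 0.0 if mm == 0 else med_vals.std(ddof=1) / mm
        per_food_rows.append(
            {
                "food": food,
                "intra_cv": float(np.mean(list(cell_cvs.values()))),
                "inter_cv": float(inter),
                "n_persons": len(cell_cvs),
            }
        )
    if not per_food_rows:
        raise ValueError("no food has enough replicated meals across participants")
    per_food = pd.DataFrame(per_food_rows)
    if len(per_food) >= 2 and not np.allclose(per_food["intra_cv"], per_food["inter_cv"]):
        p = float(stats.ttest_rel(per_food["intra_cv"], per_food["inter_cv"]).pvalue)
    elif len(per_food) >= 2:
        p = 1.0
    else:
        p = None
    return IntraInterCV(
        mean_intra_cv=float(np.mean(cells)),
        mean_inter_cv=float(per_food["inter_cv"].mean()),
        p_value=p,
        per_food=per_food,
        skipped_foods=skipped,
    )
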