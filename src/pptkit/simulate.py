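"""Synthetic trial-cohort generation with known ground truth.

Emulates the data streams of a CGM-monitored crossover + 6-month dietary
intervention at desk scale: multi-day 15-min CGM traces with meal-locked
glucose excursions, logged meals with macronutrients and predictor scores,
clinical panels with injected pre/post effects, and compositional taxa
tables with injected change-outcome correlations.

Default parameter scales are pinned to a newly diagnosed T2DM cohort
(fasting glucose ~150 +/- 19 mg/dl, HbA1c ~6.8 +/- 0.4%, ~96 readings/day,
~16,600 readings over a full study) so synthetic outputs are realistic in
magnitude. Meal excursions are log-normal-density-shaped bumps scaled so
the generative 2-h iAUC is available in closed form, which makes the CGM
metrics exactly falsifiable by round-trip tests.

Every generator is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ClinicalPanel, GlucoseTrace, MealEvent, TaxaTable, TrialBundle
from .trial import CrossoverRecord

# ---------------------------------------------------------------------------
# configuration

#: small food bank: name, kcal, carb g, protein g, fat g, sat-fat g.
#: macros are energy-consistent (4/4/9 kcal per g).
FOOD_BANK = (
    ("whole-wheat bread", 386, 52.0, 13.0, 14.0, 3.0),
    ("white rice", 360, 78.0, 7.0, 2.2, 0.6),
    ("oatmeal", 300, 50.0, 10.0, 6.7, 1.2),
    ("chicken salad", 420, 12.0, 40.0, 23.1, 5.0),
    ("salmon and greens", 450, 8.0, 35.0, 30.9, 6.0),
    ("lentil soup", 340, 45.0, 18.0, 9.8, 1.5),
    ("greek yogurt", 180, 12.0, 17.0, 7.1, 4.5),
    ("omelette", 320, 4.0, 22.0, 24.0, 8.0),
    ("pasta with tomato", 480, 80.0, 15.0, 11.1, 2.5),
    ("mixed nuts", 280, 8.0, 8.0, 24.0, 3.5),
)

#: per-outcome injected 6-month effects (mean, sd of change) on the scale
#: a successful personalized intervention produces in this population
DEFAULT_CLINICAL_EFFECTS = {
    "hba1c_pct": (-0.39, 0.48),
    "fpg_mgdl": (-16.4, 24.2),
    "fructosamine_umoll": (-26.7, 22.5),
    "insulin_uUml": (-2.3, 4.0),
    "triglycerides_mgdl": (-49.0, 46.0),
    "weight_kg": (-3.0, 3.5),
}

DEFAULT_BASELINE_CLINICAL = {
    # mean, sd at T0
    "hba1c_pct": (6.8, 0.4),
    "fpg_mgdl": (149.7, 19.0),
    "fructosamine_umoll": (295.1, 35.5),
    "insulin_uUml": (15.0, 5.0),
    "total_chol_mgdl": (200.7, 40.0),
    "ldl_mgdl": (125.6, 30.0),
    "hdl_mgdl": (47.4, 10.0),
    "triglycerides_mgdl": (153.5, 60.0),
    "weight_kg": (87.5, 21.5),
    "body_fat_pct": (33.7, 10.9),
    "waist_cm": (102.0, 14.8),
}


@dataclass
class SyntheticCohortConfig:
    """All simulation knobs. Defaults reproduce the study conditions."""

    n_participants: int = 23
    n_ppt_first: int = 11  # crossover sequence split (11 PPT-MED / 12 MED-PPT)
    days_per_period: int = 14
    sampling_interval_min: int = 15

    # CGM model
    glucose_mean: float = 149.7  # per-person mean level, mg/dl
    glucose_between_sd: float = 19.0  # between-person SD of mean level
    ar1_phi: float = 0.9
    ar1_sd: float = 5.0  # stationary within-person SD around the mean

    # meal-response model (generative iAUC, mg/dl x h)
    meal_response_intercept: float = 40.0  # carb-independent response floor
    carb_slope: float = 1.0  # per g carbohydrate
    person_effect_sd: float = 15.0
    person_food_sd: float = 15.0  # person x food interaction SD (tau)
    residual_sd: float = 10.0  # per-meal residual SD (sigma)
    diet_effect_ppgr: float = -20.0  # additive PPT shift
    crossover_noise_sd: float = 16.0  # SD of within-person period differences

    # excursion shape: log-normal density bump, median/sd on the hour scale
    bump_median_h: float = 0.75
    bump_sigma: float = 0.5

    meals_per_day: int = 4
    caloric_target: float = 2000.0

    clinical_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_EFFECTS)
    )
    baseline_clinical: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_CLINICAL)
    )

    # taxa model
    n_genera: int = 30
    dirichlet_concentration: float = 0.5
    #: injected change-change correlations: (taxon, outcome, rho)
    injected_correlations: tuple[tuple[str, str, float], ...] = (
        ("genus_01", "fpg_mgdl", 0.7),
        ("genus_02", "hba1c_pct", -0.7),
    )
    taxa_delta_scale: float = 0.02

    def __post_init__(self) -> None:
        for name in ("ar1_sd", "person_effect_sd", "person_food_sd",
                     "residual_sd", "crossover_noise_sd", "glucose_between_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if (24 * 60) % self.sampling_interval_min != 0:
            raise ValueError("sampling interval must divide 24 h")


# ---------------------------------------------------------------------------
# meal excursion shape


def _bump_norm(config: SyntheticCohortConfig, window_h: float = 2.0) -> float:
    """Mass of the log-normal bump kernel inside the 2-h window (closed form)."""
    return float(stats.lognorm.cdf(window_h, s=config.bump_sigma,
                                   scale=config.bump_median_h))


def excursion(
    hours_since_meal: np.ndarray, iauc: float, config: SyntheticCohortConfig
) -> np.ndarray:
    """Glucose excursion (mg/dl) at given lags, scaled so the exact integral
    over the first 2 h equals ``iauc`` (mg/dl x h)."""
    u = np.asarray(hours_since_meal, dtype=float)
    out = np.zeros_like(u)
    pos = u > 0
    out[pos] = stats.lognorm.pdf(u[pos], s=config.bump_sigma,
                                 scale=config.bump_median_h)
    return iauc / _bump_norm(config) * out


# ---------------------------------------------------------------------------
# person / meal level draws


def _draw_person_params(config: SyntheticCohortConfig, rng: np.random.Generator, n: int):
    return {
        "glucose_mean": config.glucose_mean + config.glucose_between_sd * rng.standard_normal(n),
        "person_effect": config.person_effect_sd * rng.standard_normal(n),
        "person_food": config.person_food_sd * rng.standard_normal((n, len(FOOD_BANK))),
    }


def generative_iauc(
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    person_effect: float,
    person_food_effect: float,
    carb_g: float,
    on_ppt: bool,
) -> float:
    mu = (
        config.meal_response_intercept
        + config.carb_slope * carb_g
        + person_effect
        + person_food_effect
        + (config.diet_effect_ppgr if on_ppt else 0.0)
    )
    return max(0.0, mu + config.residual_sd * rng.standard_normal())


def generate_meal_log(
    participant_id: str,
    start: pd.Timestamp,
    n_days: int,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    food_indices: np.ndarray | None = None,
) -> list[MealEvent]:
    """Logged meals at realistic times (07-22 h) drawn from the food bank.

    Meal slots are breakfast/lunch/dinner plus an afternoon snack; each meal
    is one dominant food (80% of energy) with a generic side. Daily energy
    lands near the caloric target on average.
    """
    slot_hours = [7.5, 13.0, 19.0, 16.5][: config.meals_per_day]
    meals: list[MealEvent] = []
    for day in range(n_days):
        for hour in slot_hours:
            fi = (
                int(rng.integers(len(FOOD_BANK)))
                if food_indices is None
                else int(rng.choice(food_indices))
            )
            name, kcal, carb, protein, fat, sat = FOOD_BANK[fi]
            jitter = float(rng.uniform(-0.5, 0.5))
            t = start + pd.Timedelta(days=day) + pd.Timedelta(hours=hour + jitter)
            # scale portion so daily totals track the caloric target
            portion = config.caloric_target / config.meals_per_day / 400.0
            meals.append(
                MealEvent(
                    participant_id=participant_id,
                    timestamp=t.floor("min"),
                    name=name,
                    kcal=kcal * portion,
                    carb_g=carb * portion,
                    protein_g=protein * portion,
                    fat_g=fat * portion,
                    sat_fat_g=sat * portion,
                    dominant_food_label=name,
                    foods=((name, 0.8 * kcal * portion), ("side", 0.2 * kcal * portion)),
                )
            )
    meals.sort(key=lambda m: m.timestamp)
    return meals


def generate_trace(
    participant_id: str,
    glucose_mean: float,
    meal_responses: list[tuple[pd.Timestamp, float]],
    start: pd.Timestamp,
    n_days: int,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    connection_days: int | None = None,
) -> GlucoseTrace:
    """AR(1) glucose around the person's mean plus meal-locked excursions.

    ``meal_responses`` pairs each meal time with its generative 2-h iAUC.
    ``connection_days`` splits the trace into sensor connections of that
    many days (default: one connection per 14 days, the sensor wear time).
    """
    step_h = config.sampling_interval_min / 60.0
    n = int(round(n_days * 24 / step_h))
    t_h = np.arange(n) * step_h
    ts = start + pd.to_timedelta(t_h, unit="h")

    if config.ar1_sd > 0:
        innov_sd = config.ar1_sd * np.sqrt(1 - config.ar1_phi**2)
        noise = np.empty(n)
        noise[0] = config.ar1_sd * rng.standard_normal()
        eps = innov_sd * rng.standard_normal(n - 1)
        for i in range(1, n):
            noise[i] = config.ar1_phi * noise[i - 1] + eps[i - 1]
    else:
        noise = np.zeros(n)

    glucose = glucose_mean + noise
    for meal_time, iauc in meal_responses:
        lag = t_h - (meal_time - start).total_seconds() / 3600.0
        near = (lag > 0) & (lag < 6.0)
        glucose[near] += excursion(lag[near], iauc, config)
    glucose = np.clip(glucose, 40.0, 550.0)

    conn_days = connection_days or 14
    per_conn = int(round(conn_days * 24 / step_h))
    connections = [(a, min(a + per_conn, n)) for a in range(0, n, per_conn)]
    return GlucoseTrace(participant_id, ts, glucose, connections)


# ---------------------------------------------------------------------------
# outcome-level generators (crossover, clinical, taxa)


def generate_crossover_outcomes(
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    effect: float | None = None,
) -> list[CrossoverRecord]:
    """Per-period averaged-PPGR outcomes with an injected diet effect.

    Within-person PPT-MED differences are N(effect, crossover_noise_sd);
    between-person spread comes from the person random effect.
    """
    effect = config.diet_effect_ppgr if effect is None else effect
    n = config.n_participants
    base = 60.0 + config.person_effect_sd * rng.standard_normal(n)
    diffs = effect + config.crossover_noise_sd * rng.standard_normal(n)
    recs = []
    for i in range(n):
        seq = "PPT-MED" if i < config.n_ppt_first else "MED-PPT"
        med = base[i]
        recs.append(CrossoverRecord(f"p{i:02d}", seq, med + diffs[i], med))
    return recs


def generate_clinical_panels(
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    participants: list[str],
) -> dict[tuple[str, str], ClinicalPanel]:
    """T0/T3/T6 panels: T6 = T0 + injected effect + noise, T3 halfway."""
    out: dict[tuple[str, str], ClinicalPanel] = {}
    n = len(participants)
    base = {
        k: np.maximum(mu + sd * rng.standard_normal(n), 0.05 * mu if mu > 0 else 0.0)
        for k, (mu, sd) in config.baseline_clinical.items()
    }
    base["hba1c_pct"] = np.clip(base["hba1c_pct"], 3.1, 19.9)
    deltas = {
        k: mu + sd * rng.standard_normal(n)
        for k, (mu, sd) in config.clinical_effects.items()
    }
    for i, pid in enumerate(participants):
        for tp, frac in (("T0", 0.0), ("T3", 0.5), ("T6", 1.0)):
            vals = {}
            for k, b in base.items():
                v = b[i] + frac * deltas.get(k, (0.0,))[i] if k in deltas else b[i]
                vals[k] = max(float(v), 0.0)
            vals["hba1c_pct"] = float(np.clip(vals["hba1c_pct"], 3.1, 19.9))
            vals["homa_ir"] = vals["fpg_mgdl"] * vals["insulin_uUml"] / 405.0
            out[(pid, tp)] = ClinicalPanel(**vals)
    return out


def _taxon_meta(config: SyntheticCohortConfig) -> pd.DataFrame:
    names = [f"genus_{i:02d}" for i in range(config.n_genera)]
    phyla = ["Firmicutes" if i % 2 == 0 else "Bacteroidetes" for i in range(config.n_genera)]
    tags = [("propionate_producer",) if i % 5 == 0 else () for i in range(config.n_genera)]
    return pd.DataFrame({"level": "genus", "phylum": phyla, "tags": tags}, index=names)


def generate_taxa_tables(
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    participants: list[str],
    delta_outcomes: pd.DataFrame | None = None,
) -> tuple[TaxaTable, TaxaTable]:
    """(baseline, T6) genus-level taxa tables from a Dirichlet model.

    For each configured (taxon, outcome, rho), the taxon's abundance change
    is constructed as rho * z_outcome + sqrt(1-rho^2) * noise on a small
    additive scale before renormalization, so the realized change-change
    Pearson correlation approaches rho.
    """
    meta = _taxon_meta(config)
    n = len(participants)
    alpha = np.full(config.n_genera, config.dirichlet_concentration)
    injected_idx: list[int] = []
    if delta_outcomes is not None:
        injected_idx = [
            meta.index.get_loc(t)
            for t, o, _ in config.injected_correlations
            if t in meta.index and o in delta_outcomes.columns
        ]
        # give injected taxa enough baseline mass that their constructed
        # change is rarely truncated at zero
        alpha[injected_idx] = max(2.0, config.dirichlet_concentration)
    base = rng.dirichlet(alpha, size=n)
    delta = 0.25 * config.taxa_delta_scale * rng.standard_normal((n, config.n_genera))
    if delta_outcomes is not None:
        for taxon, outcome, rho in config.injected_correlations:
            if taxon not in meta.index or outcome not in delta_outcomes.columns:
                continue
            j = meta.index.get_loc(taxon)
            z = delta_outcomes[outcome].reindex(participants).to_numpy(float)
            z = (z - np.nanmean(z)) / (np.nanstd(z) or 1.0)
            z = np.nan_to_num(z)
            delta[:, j] = config.taxa_delta_scale * (
                rho * z + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
            )
    # injected taxa realize their constructed change exactly; the remaining
    # taxa absorb the compositional closure
    end = np.clip(base + delta, 1e-6, None)
    if injected_idx:
        inj = np.array(injected_idx)
        others = np.setdiff1d(np.arange(config.n_genera), inj)
        end[:, inj] = np.clip(base[:, inj] + delta[:, inj], 1e-6, 0.8)
        budget = 1.0 - end[:, inj].sum(axis=1)
        end[:, others] *= (budget / end[:, others].sum(axis=1))[:, None]
    end = end / end.sum(axis=1, keepdims=True)
    idx = pd.Index(participants, name="participant_id")
    t_base = TaxaTable(pd.DataFrame(base, index=idx, columns=meta.index), meta, renormalize=True)
    t_end = TaxaTable(pd.DataFrame(end, index=idx, columns=meta.index), meta, renormalize=True)
    return t_base, t_end


# ---------------------------------------------------------------------------
# full bundle


def generate_bundle(
    config: SyntheticCohortConfig | None = None,
    seed: int = 0,
    start: str | pd.Timestamp = "2018-01-01",
) -> TrialBundle:
    """Complete synthetic crossover cohort: traces, meal logs with known
    generative PPGRs, clinical panels and taxa tables, plus a ground-truth
    record of every injected effect."""
    config = config or SyntheticCohortConfig()
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(start)
    n = config.n_participants
    pids = [f"p{i:02d}" for i in range(n)]
    params = _draw_person_params(config, rng, n)
    food_names = [f[0] for f in FOOD_BANK]

    from dataclasses import replace

    from .menu import assign_meal_score

    portion = config.caloric_target / config.meals_per_day / 400.0
    traces: dict[str, GlucoseTrace] = {}
    meals: dict[str, list[MealEvent]] = {}
    truth_meals = []
    for i, pid in enumerate(pids):
        seq = "PPT-MED" if i < config.n_ppt_first else "MED-PPT"
        # person-relative quintile scores over the food bank, from the
        # expected (noise-free) response to each food
        food_mu = np.array(
            [
                config.meal_response_intercept
                + config.carb_slope * f[2] * portion
                + params["person_effect"][i]
                + params["person_food"][i, j]
                for j, f in enumerate(FOOD_BANK)
            ]
        )
        food_scores = [assign_meal_score(mu, food_mu) for mu in food_mu]
        period_meals: list[MealEvent] = []
        responses: list[tuple[pd.Timestamp, float]] = []
        for period in (1, 2):
            diet = seq.split("-")[period - 1]
            p_start = start + pd.Timedelta(days=(period - 1) * config.days_per_period)
            evs = generate_meal_log(pid, p_start, config.days_per_period, config, rng)
            evs = [
                replace(ev, meal_score=food_scores[food_names.index(ev.name)])
                for ev in evs
            ]
            for ev in evs:
                fi = food_names.index(ev.name)
                iauc = generative_iauc(
                    config, rng,
                    params["person_effect"][i],
                    params["person_food"][i, fi],
                    ev.carb_g,
                    on_ppt=(diet == "PPT"),
                )
                responses.append((ev.timestamp, iauc))
                truth_meals.append(
                    {"participant_id": pid, "timestamp": ev.timestamp,
                     "diet": diet, "period": period, "food": ev.name,
                     "carb_g": ev.carb_g, "true_iauc": iauc}
                )
            period_meals.extend(evs)
        traces[pid] = generate_trace(
            pid, params["glucose_mean"][i], responses, start,
            2 * config.days_per_period, config, rng,
            connection_days=config.days_per_period,
        )
        meals[pid] = period_meals

    clinical = generate_clinical_panels(config, rng, pids)
    delta_outcomes = pd.DataFrame(
        {
            k: [
                (clinical[(p, "T6")].as_series()[k] - clinical[(p, "T0")].as_series()[k])
                for p in pids
            ]
            for k in config.clinical_effects
        },
        index=pd.Index(pids, name="participant_id"),
    )
    taxa_base, taxa_end = generate_taxa_tables(config, rng, pids, delta_outcomes)

    bundle = TrialBundle(
        participants=pids,
        traces=traces,
        meals=meals,
        clinical=clinical,
        taxa={"baseline": taxa_base, "T6": taxa_end},
        ground_truth={
            "seed": seed,
            "diet_effect_ppgr": config.diet_effect_ppgr,
            "clinical_effects": config.clinical_effects,
            "injected_correlations": list(config.injected_correlations),
            "sequences": {
                pid: ("PPT-MED" if i < config.n_ppt_first else "MED-PPT")
                for i, pid in enumerate(pids)
            },
            "meal_truth": pd.DataFrame(truth_meals),
        },
    )
    return bundle


def generate_prediction_dataset(
    n_persons: int = 30,
    meals_per_person: int = 20,
    interaction_scale: float = 0.0,
    carb_slope: float = 1.0,
    noise_sd: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Meal-level feature/target table for PPGR-model evaluation.

    The target is carb_slope x carbohydrate plus, when
    ``interaction_scale`` > 0, a person-level microbiome feature interacting
    with meal fat (non-carbohydrate signal a carbohydrate-only model cannot
    capture), plus Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_persons):
        hba1c = 6.8 + 0.4 * rng.standard_normal()
        fpg = 149.7 + 19.0 * rng.standard_normal()
        weight = 87.5 + 21.5 * rng.standard_normal()
        taxa_feat = rng.uniform(0, 1)
        for _ in range(meals_per_person):
            carb = rng.uniform(5, 90)
            fat = rng.uniform(2, 40)
            protein = rng.uniform(5, 45)
            kcal = 4 * carb + 4 * protein + 9 * fat
            y = (
                carb_slope * carb
                + interaction_scale * (taxa_feat - 0.5) * fat
                + noise_sd * rng.standard_normal()
            )
            rows.append(
                {
                    "participant_id": f"p{i:02d}",
                    "kcal": kcal, "carb_g": carb, "fat_g": fat, "protein_g": protein,
                    "hba1c_pct": hba1c, "fpg_mgdl": fpg, "weight_kg": weight,
                    "taxa_feature": taxa_feat,
                    "iauc": max(0.0, y),
                }
            )
    return pd.DataFrame(rows)


PREDICTION_FEATURES = [
    "kcal", "carb_g", "fat_g", "protein_g",
    "hba1c_pct", "fpg_mgdl", "weight_kg", "taxa_feature",
]
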