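"""Core domain containers shared across the pipeline.

Glucose traces, logged meals, clinical panels, compositional taxa tables and
the bundle object tying one simulated or ingested trial cohort together.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GLUCOSE_MIN_MGDL = 20.0
GLUCOSE_MAX_MGDL = 600.0

#: Ordered timepoint labels used throughout the trial analyses.
TIMEPOINTS = ("baseline", "T0", "T3", "T6", "period1", "period2")


@dataclass(frozen=True)
class MealEvent:
    """One logged meal: energy, macronutrients and optional predictor score.

    ``meal_score`` ranks the meal 1 (best predicted postprandial response)
    to 5 (worst) for the participant; absent when the meal was never scored.
    ``foods`` lists the component foods with their energy, used to identify
    a dominant food (> 70% of meal calories).
    """

    participant_id: str
    timestamp: pd.Timestamp
    name: str = "meal"
    kcal: float = 0.0
    carb_g: float = 0.0
    protein_g: float = 0.0
    fat_g: float = 0.0
    sat_fat_g: float = 0.0
    meal_score: int | None = None
    dominant_food_label: str | None = None
    foods: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.kcal < 0:
            raise ValueError(f"meal kcal must be >= 0, got {self.kcal}")
        if self.meal_score is not None and self.meal_score not in (1, 2, 3, 4, 5):
            raise ValueError(f"meal_score must be in 1..5, got {self.meal_score}")
        # 4/4/9 kcal per gram; allow 10% slack over total energy
        macro_kcal = 4.0 * self.carb_g + 4.0 * self.protein_g + 9.0 * self.fat_g
        if self.kcal > 0 and macro_kcal > 1.10 * self.kcal:
            raise ValueError(
                f"macronutrient energy {macro_kcal:.0f} kcal exceeds meal energy "
                f"{self.kcal:.0f} kcal by more than 10%"
            )


class GlucoseTrace:
    """One participant's CGM readings partitioned into sensor connections.

    Parameters
    ----------
    participant_id : str
    timestamps : sequence of datetime-like
        Reading times, strictly increasing within each connection.
    glucose : sequence of float
        Glucose in mg/dl, each within [20, 600].
    connections : sequence of (start, stop) index pairs, optional
        Half-open reading-index intervals; defaults to one connection
        spanning the whole trace.
    """

    def __init__(
        self,
        participant_id: str,
        timestamps: Sequence,
        glucose: Sequence[float],
        connections: Sequence[tuple[int, int]] | None = None,
    ) -> None:
        ts = pd.DatetimeIndex(pd.to_datetime(list(timestamps)))
        glu = np.asarray(glucose, dtype=float)
        if len(ts) != len(glu):
            raise ValueError("timestamps and glucose must have equal length")
        if np.any((glu < GLUCOSE_MIN_MGDL) | (glu > GLUCOSE_MAX_MGDL)):
            bad = glu[(glu < GLUCOSE_MIN_MGDL) | (glu > GLUCOSE_MAX_MGDL)]
            raise ValueError(f"glucose outside [{GLUCOSE_MIN_MGDL:.0f}, {GLUCOSE_MAX_MGDL:.0f}] mg/dl: {bad[:5]}")
        if connections is None:
            connections = [(0, len(glu))] if len(glu) else []
        conns = [(int(a), int(b)) for a, b in connections]
        for a, b in conns:
            if not (0 <= a < b <= len(glu)):
                raise ValueError(f"connection ({a}, {b}) out of bounds for {len(glu)} readings")
            seg = ts[a:b]
            if len(seg) > 1 and not (np.diff(seg.asi8) > 0).all():
                raise ValueError("timestamps must be strictly increasing within a connection")
        self.participant_id = participant_id
        self.timestamps = ts
        self.glucose = glu
        self.connections = conns

    def __len__(self) -> int:
        return len(self.glucose)

    def __repr__(self) -> str:
        return (
            f"GlucoseTrace({self.participant_id!r}, n={len(self)}, "
            f"connections={len(self.connections)})"
        )

    def times_hours(self, origin=None) -> np.ndarray:
        """Reading times as float hours since ``origin`` (default: first reading)."""
        if origin is None:
            origin = self.timestamps[0]
        return (self.timestamps - pd.Timestamp(origin)).total_seconds().to_numpy() / 3600.0

    def connection_slices(self) -> Iterable[slice]:
        for a, b in self.connections:
            yield slice(a, b)

    def restrict(self, start, stop) -> "GlucoseTrace":
        """Sub-trace with readings in [start, stop); connections re-clipped."""
        start = pd.Timestamp(start)
        stop = pd.Timestamp(stop)
        mask = (self.timestamps >= start) & (self.timestamps < stop)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return GlucoseTrace(self.participant_id, [], [], [])
        new_conns = []
        offset = idx[0]
        for a, b in self.connections:
            lo, hi = max(a, idx[0]), min(b, idx[-1] + 1)
            if lo < hi:
                new_conns.append((lo - offset, hi - offset))
        return GlucoseTrace(
            self.participant_id,
            self.timestamps[mask],
            self.glucose[mask],
            new_conns,
        )

    def to_frame(self) -> pd.DataFrame:
        conn_ids = np.empty(len(self), dtype=int)
        for i, (a, b) in enumerate(self.connections):
            conn_ids[a:b] = i
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "timestamp": self.timestamps,
                "glucose_mgdl": self.glucose,
                "connection": conn_ids,
            }
        )


@dataclass
class ClinicalPanel:
    """Blood/anthropometric panel at one timepoint. Units as labelled."""

    hba1c_pct: float | None = None
    fpg_mgdl: float | None = None
    fructosamine_umoll: float | None = None
    insulin_uUml: float | None = None
    homa_ir: float | None = None
    total_chol_mgdl: float | None = None
    ldl_mgdl: float | None = None
    hdl_mgdl: float | None = None
    triglycerides_mgdl: float | None = None
    weight_kg: float | None = None
    body_fat_pct: float | None = None
    waist_cm: float | None = None
    systolic_bp: float | None = None
    diastolic_bp: float | None = None

    def __post_init__(self) -> None:
        if self.hba1c_pct is not None and not (3.0 <= self.hba1c_pct <= 20.0):
            raise ValueError(f"HbA1c {self.hba1c_pct}% outside plausible range [3, 20]")
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)}, dtype=float)


class TaxaTable:
    """Per-sample relative abundances keyed by (taxon, phylogenetic level).

    ``abundances`` is a samples x taxa DataFrame; ``taxon_meta`` maps each
    taxon to its level (phylum/genus/species), its phylum lineage, and
    optional functional tags. Within each level every sample sums to 1.
    """

    def __init__(
        self,
        abundances: pd.DataFrame,
        taxon_meta: pd.DataFrame,
        renormalize: bool = False,
    ) -> None:
        missing = set(abundances.columns) - set(taxon_meta.index)
        if missing:
            raise ValueError(f"taxa without metadata: {sorted(missing)[:5]}")
        if (abundances.to_numpy() < 0).any():
            raise ValueError("negative relative abundance")
        abundances = abundances.astype(float).copy()
        for level, cols in self._level_groups(taxon_meta, abundances.columns):
            sums = abundances[cols].sum(axis=1)
            if (sums <= 0).any():
                bad = sums.index[sums <= 0].tolist()
                raise ValueError(f"zero-sum sample(s) at level {level!r}: {bad[:5]}")
            if renormalize:
                abundances[cols] = abundances[cols].div(sums, axis=0)
            elif not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError(
                    f"samples do not sum to 1 at level {level!r}; pass renormalize=True"
                )
        self.abundances = abundances
        self.taxon_meta = taxon_meta.loc[list(abundances.columns)].copy()

    @staticmethod
    def _level_groups(meta: pd.DataFrame, cols) -> list[tuple[str, list[str]]]:
        levels = meta.loc[list(cols), "level"]
        return [(lev, list(levels.index[levels == lev])) for lev in levels.unique()]

    @property
    def samples(self) -> pd.Index:
        return self.abundances.index

    def level(self, level: str) -> pd.DataFrame:
        cols = self.taxon_meta.index[self.taxon_meta["level"] == level]
        if len(cols) == 0:
            raise KeyError(f"no taxa at level {level!r}")
        return self.abundances[list(cols)]

    def taxa_with_tag(self, tag: str) -> list[str]:
        tags = self.taxon_meta.get("tags")
        if tags is None:
            return []
        return [t for t, ts in tags.items() if ts and tag in ts]


@dataclass
class TrialBundle:
    """One cohort's worth of trial data, keyed by participant id."""

    participants: list[str]
    traces: dict[str, GlucoseTrace] = field(default_factory=dict)
    meals: dict[str, list[MealEvent]] = field(default_factory=dict)
    clinical: dict[tuple[str, str], ClinicalPanel] = field(default_factory=dict)
    taxa: dict[str, TaxaTable] = field(default_factory=dict)  # timepoint -> table
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.participants)
        for pid, evs in self.meals.items():
            if pid not in known:
                raise ValueError(f"meals logged for unknown participant {pid!r}")
            for ev in evs:
                if ev.participant_id != pid:
                    raise ValueError("meal participant_id does not match bundle key")
        for (pid, tp) in self.clinical:
            if pid not in known:
                raise ValueError(f"clinical panel for unknown participant {pid!r}")
            if tp not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {tp!r}; expected one of {TIMEPOINTS}")

    def clinical_frame(self) -> pd.DataFrame:
        rows = {}
        for (pid, tp), panel in self.clinical.items():
            rows[(pid, tp)] = panel.as_series()
        out = pd.DataFrame(rows).T
        out.index.names = ["participant_id", "timepoint"]
        return out


def meals_frame(meals: Mapping[str, Sequence[MealEvent]] | Sequence[MealEvent]) -> pd.DataFrame:
    """Flatten meal events into a tidy DataFrame (one row per meal)."""
    if isinstance(meals, Mapping):
        events: list[MealEvent] = [e for evs in meals.values() for e in evs]
    else:
        events = list(meals)
    return pd.DataFrame(
        {
            "participant_id": [e.participant_id for e in events],
            "timestamp": [e.timestamp for e in events],
            "name": [e.name for e in events],
            "kcal": [e.kcal for e in events],
            "carb_g": [e.carb_g for e in events],
            "protein_g": [e.protein_g for e in events],
            "fat_g": [e.fat_g for e in events],
            "sat_fat_g": [e.sat_fat_g for e in events],
            "meal_score": [e.meal_score for e in events],
            "dominant_food": [e.dominant_food_label for e in events],
        }
    )
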