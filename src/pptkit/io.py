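"""Readers and writers for the pipeline's tabular formats.

All tabular I/O is UTF-8 CSV/TSV with a header row; timestamps are
timezone-naive ISO 8601 local time. Sensor connections are taken from an
explicit ``connection`` column when present, otherwise inferred from
inter-reading gaps larger than a configurable threshold (default 3 h —
unambiguous wear breaks at 15-min nominal sampling).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GLUCOSE_MAX_MGDL,
    GLUCOSE_MIN_MGDL,
    ClinicalPanel,
    GlucoseTrace,
    MealEvent,
    TaxaTable,
    TrialBundle,
)

DEFAULT_GAP_THRESHOLD_H = 3.0


def _read_table(path, **kw) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, **kw)


# ---------------------------------------------------------------------------
# CGM


def read_cgm(path, gap_threshold_h: float = DEFAULT_GAP_THRESHOLD_H) -> dict[str, GlucoseTrace]:
    """Read CGM readings into per-participant traces.

    Expects columns participant_id, timestamp, glucose_mgdl and optionally
    connection. Rows with glucose outside [20, 600] mg/dl are rejected with
    a summary warning; an unparseable timestamp is a hard error naming the
    row.
    """
    df = _read_table(path, dtype={"participant_id": str})
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad_ts = ts.isna() & df["timestamp"].notna()
    if bad_ts.any():
        row = int(np.flatnonzero(bad_ts)[0])
        raise ValueError(
            f"unparseable timestamp {df['timestamp'].iloc[row]!r} at row {row + 2} of {path}"
        )
    df = df.assign(timestamp=ts)
    glu = df["glucose_mgdl"].astype(float)
    bad = (glu < GLUCOSE_MIN_MGDL) | (glu > GLUCOSE_MAX_MGDL) | glu.isna()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} reading(s) outside [20, 600] mg/dl rejected")
        df = df[~bad]
    traces: dict[str, GlucoseTrace] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp")
        t = pd.DatetimeIndex(grp["timestamp"])
        g = grp["glucose_mgdl"].to_numpy(float)
        if "connection" in grp.columns and grp["connection"].notna().all():
            conn_ids = grp["connection"].to_numpy()
            breaks = np.flatnonzero(conn_ids[1:] != conn_ids[:-1]) + 1
        else:
            gaps_h = np.diff(t.asi8) / 3.6e12
            breaks = np.flatnonzero(gaps_h > gap_threshold_h) + 1
        bounds = [0, *breaks.tolist(), len(g)]
        conns = [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if a < b]
        traces[pid] = GlucoseTrace(pid, t, g, conns)
    return traces


def write_cgm(traces: dict[str, GlucoseTrace], path) -> None:
    frames = [traces[pid].to_frame() for pid in sorted(traces)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# meal logs

_MEAL_COLS = ["participant_id", "timestamp", "name", "kcal", "carb_g",
              "protein_g", "fat_g", "sat_fat_g", "meal_score", "dominant_food"]


def read_meal_log(path) -> dict[str, list[MealEvent]]:
    """Read a meal log CSV into per-participant, time-sorted meal events.

    ``meal_score`` may be blank (stored as absent); a value outside 1..5 is
    a hard error.
    """
    df = _read_table(path, dtype={"participant_id": str})
    df = df.assign(timestamp=pd.to_datetime(df["timestamp"], format="ISO8601"))
    out: dict[str, list[MealEvent]] = {}
    for _, row in df.sort_values(["participant_id", "timestamp"]).iterrows():
        score = row.get("meal_score")
        score = None if pd.isna(score) else int(score)
        if score is not None and score not in (1, 2, 3, 4, 5):
            raise ValueError(f"meal_score {score} outside 1..5 for participant {row['participant_id']}")
        dom = row.get("dominant_food")
        ev = MealEvent(
            participant_id=row["participant_id"],
            timestamp=row["timestamp"],
            name=str(row.get("name", "meal")),
            kcal=float(row["kcal"]),
            carb_g=float(row.get("carb_g", 0.0)),
            protein_g=float(row.get("protein_g", 0.0)),
            fat_g=float(row.get("fat_g", 0.0)),
            sat_fat_g=float(row.get("sat_fat_g", 0.0)),
            meal_score=score,
            dominant_food_label=None if pd.isna(dom) else str(dom),
        )
        out.setdefault(ev.participant_id, []).append(ev)
    return out


def write_meal_log(meals: dict[str, list[MealEvent]], path) -> None:
    from .core import meals_frame

    meals_frame(meals).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# taxa tables

# header token format: name|level|phylum[|tag1;tag2]


def read_taxa_table(path) -> TaxaTable:
    """Read a samples x taxa TSV whose column headers encode metadata as
    ``name|level|phylum[|tag1;tag2]``. Abundances are renormalized to sum
    to 1 per sample within each level; an all-zero sample or a negative
    abundance is an error."""
    df = _read_table(path, index_col=0)
    names, meta_rows = [], []
    for col in df.columns:
        parts = str(col).split("|")
        if len(parts) < 3:
            raise ValueError(f"taxa column {col!r} lacks name|level|phylum metadata")
        name, level, phylum = parts[:3]
        tags = tuple(parts[3].split(";")) if len(parts) > 3 and parts[3] else ()
        names.append(name)
        meta_rows.append({"level": level, "phylum": phylum, "tags": tags})
    abund = df.copy()
    abund.columns = names
    meta = pd.DataFrame(meta_rows, index=names)
    return TaxaTable(abund, meta, renormalize=True)


def write_taxa_table(table: TaxaTable, path) -> None:
    cols = []
    for t in table.abundances.columns:
        m = table.taxon_meta.loc[t]
        tag = ";".join(m.get("tags", ()) or ())
        cols.append(f"{t}|{m['level']}|{m['phylum']}|{tag}")
    out = table.abundances.copy()
    out.columns = cols
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# clinical panels


def read_clinical(path) -> dict[tuple[str, str], ClinicalPanel]:
    df = _read_table(path, dtype={"participant_id": str})
    out = {}
    fields = [c for c in df.columns if c not in ("participant_id", "timepoint")]
    for _, row in df.iterrows():
        vals = {f: (None if pd.isna(row[f]) else float(row[f])) for f in fields}
        out[(row["participant_id"], row["timepoint"])] = ClinicalPanel(**vals)
    return out


def write_clinical(clinical: dict[tuple[str, str], ClinicalPanel], path) -> None:
    rows = []
    for (pid, tp), panel in sorted(clinical.items()):
        s = panel.as_series()
        s["participant_id"] = pid
        s["timepoint"] = tp
        rows.append(s)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# bundle round trip


def write_bundle(bundle: TrialBundle, out_dir) -> None:
    """Write a bundle directory: cgm.csv, meals.csv, clinical.csv, per-
    timepoint taxa TSVs and a ground-truth JSON (DataFrames written as CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle.traces:
        write_cgm(bundle.traces, out / "cgm.csv")
    if bundle.meals:
        write_meal_log(bundle.meals, out / "meals.csv")
    if bundle.clinical:
        write_clinical(bundle.clinical, out / "clinical.csv")
    for tp, table in bundle.taxa.items():
        write_taxa_table(table, out / f"taxa_{tp}.tsv")
    truth = {}
    for k, v in bundle.ground_truth.items():
        if isinstance(v, pd.DataFrame):
            v.to_csv(out / f"truth_{k}.csv", index=False)
            truth[k] = f"truth_{k}.csv"
        else:
            truth[k] = v
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, default=str))


def read_bundle(out_dir) -> TrialBundle:
    out = Path(out_dir)
    traces = read_cgm(out / "cgm.csv") if (out / "cgm.csv").exists() else {}
    meals = read_meal_log(out / "meals.csv") if (out / "meals.csv").exists() else {}
    clinical = read_clinical(out / "clinical.csv") if (out / "clinical.csv").exists() else {}
    taxa = {
        p.stem.removeprefix("taxa_"): read_taxa_table(p)
        for p in sorted(out.glob("taxa_*.tsv"))
    }
    participants = sorted(
        set(traces) | set(meals) | {pid for pid, _ in clinical}
    )
    truth = {}
    gt = out / "ground_truth.json"
    if gt.exists():
        truth = json.loads(gt.read_text())
    return TrialBundle(
        participants=participants, traces=traces, meals=meals,
        clinical=clinical, taxa=taxa, ground_truth=truth,
    )
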