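"""Gut-microbiome composition summaries and change-outcome associations.

Starting from finished relative-abundance tables (no read-level
processing), this module computes Shannon diversity, the
Firmicutes/Bacteroidetes ratio, functional aggregates such as
propionate-producing bacteria, and Pearson correlations between per-person
6-month changes in taxa and changes in clinical outcomes, with
Benjamini-Hochberg FDR control at q = 0.15 applied within each
phylogenetic level separately.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import TaxaTable

DEFAULT_FDR_Q = 0.15

#: Default members of the propionate-producer aggregate. The membership is
#: a configurable, literature-derived choice (genera with well-documented
#: propionate production via the succinate or propanediol pathways), not a
#: canonical list.
PROPIONATE_PRODUCERS = (
    "Akkermansia",
    "Bacteroides",
    "Prevotella",
    "Veillonella",
    "Phascolarctobacterium",
    "Dialister",
    "Roseburia",
)


def shannon_diversity(sample: np.ndarray | pd.Series) -> float:
    """Shannon diversity index in nats: -sum p_i ln p_i, with 0 ln 0 = 0."""
    p = np.asarray(sample, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundance")
    total = p.sum()
    if total <= 0:
        raise ValueError("sample sums to zero")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def fb_ratio(table: TaxaTable, sample, level: str = "genus") -> float | None:
    """Firmicutes / Bacteroidetes summed-relative-abundance ratio.

    Returns None (with a warning) when the Bacteroidetes aggregate is zero;
    no pseudocount is applied.
    """
    df = table.level(level)
    phyla = table.taxon_meta.loc[df.columns, "phylum"]
    if phyla.isna().any():
        missing = list(phyla.index[phyla.isna()])
        raise ValueError(f"taxa missing phylum lineage: {missing[:5]}")
    row = df.loc[sample]
    firm = float(row[phyla == "Firmicutes"].sum())
    bact = float(row[phyla == "Bacteroidetes"].sum())
    if bact == 0:
        warnings.warn(f"sample {sample!r}: Bacteroidetes aggregate is zero; ratio undefined")
        return None
    return firm / bact


def functional_aggregate(
    table: TaxaTable, sample, taxa: tuple[str, ...] | list[str], level: str = "genus"
) -> float:
    """Summed relative abundance of a functional taxon set (e.g. propionate
    producers). Taxa absent from the table contribute zero."""
    if not taxa:
        raise ValueError("empty taxon set")
    df = table.level(level)
    present = [t for t in taxa if t in df.columns]
    return float(df.loc[sample, present].sum()) if present else 0.0


def change_outcome_associations(
    delta_taxa: pd.DataFrame,
    delta_outcomes: pd.DataFrame,
    levels: pd.Series | None = None,
    fdr_q: float = DEFAULT_FDR_Q,
    per_outcome: bool = False,
) -> pd.DataFrame:
    """Pearson correlations of per-person taxa changes vs outcome changes.

    Parameters
    ----------
    delta_taxa : DataFrame, participants x taxa (T6 - baseline abundance).
    delta_outcomes : DataFrame, participants x clinical outcomes.
    levels : Series mapping taxon -> phylogenetic level. BH adjustment is
        applied across all (taxon, outcome) pairs within each level
        (``per_outcome=True`` restricts each BH family to one outcome).
    fdr_q : significance is flagged at q <= this value (default 0.15).

    Returns one row per (taxon, outcome) with r, p, q, n and a
    ``significant`` flag; zero-variance pairs are skipped with a warning.
    """
    common = delta_taxa.index.intersection(delta_outcomes.index)
    if len(common) < 4:
        raise ValueError("need >= 4 participants with paired changes")
    dt = delta_taxa.loc[common]
    do = delta_outcomes.loc[common]
    if levels is None:
        levels = pd.Series("all", index=dt.columns)
    rows = []
    for taxon in dt.columns:
        x = dt[taxon].to_numpy(float)
        for outcome in do.columns:
            y = do[outcome].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 4:
                continue
            if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                warnings.warn(f"zero-variance pair ({taxon}, {outcome}); skipped")
                continue
            res = stats.pearsonr(x[ok], y[ok])
            rows.append(
                {
                    "taxon": taxon,
                    "outcome": outcome,
                    "level": levels.get(taxon, "all"),
                    "r": float(res.statistic),
                    "p": float(res.pvalue),
                    "n": int(ok.sum()),
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(q=[], significant=[])
    out["q"] = np.nan
    group_cols = ["level", "outcome"] if per_outcome else ["level"]
    for _, idx in out.groupby(group_cols).groups.items():
        out.loc[idx, "q"] = multipletests(out.loc[idx, "p"], method="fdr_bh")[1]
    out["q"] = np.maximum(out["q"], out["p"])  # BH q is never below p
    out["significant"] = out["q"] <= fdr_q
    return out.sort_values(["level", "q", "p"]).reset_index(drop=True)


def diversity_vs_outcome(
    diversities: pd.Series,
    outcome: pd.Series,
    window: int = 5,
) -> tuple[float | None, float | None, pd.DataFrame | None]:
    """Diversity-outcome association with a rolling-average display curve.

    Participants are sorted by the outcome; the curve is the ``window``-person
    rolling mean of diversity along that ordering. Returns (Pearson r, p,
    curve); r is None when either vector is constant or n < 3, the curve is
    None when n < window.
    """
    common = diversities.index.intersection(outcome.index)
    d = diversities.loc[common].astype(float)
    o = outcome.loc[common].astype(float)
    order = o.sort_values().index
    d, o = d.loc[order], o.loc[order]
    r = p = None
    if len(d) >= 3 and np.ptp(d) > 0 and np.ptp(o) > 0:
        res = stats.pearsonr(d, o)
        r, p = float(res.statistic), float(res.pvalue)
    curve = None
    if len(d) >= window:
        curve = pd.DataFrame(
            {
                "outcome": o.to_numpy(),
                "rolling_diversity": d.rolling(window, center=True, min_periods=window).mean().to_numpy(),
            },
            index=order,
        )
    return r, p, curve
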