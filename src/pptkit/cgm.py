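"""CGM-derived glycemic measures.

Implements the glycemic outcome battery of a CGM-monitored dietary trial:

* per-meal postprandial glucose response (PPGR) as the 2-h incremental
  area under the glucose curve (iAUC, mg/dl x h) above the at-meal baseline;
* "averaged PPGR" computed as the iAUC of every 9 consecutive glucose
  measurements within every sensor connection;
* glucose coefficient of variation (sd/mean);
* daily hours above glucose thresholds (140..180 mg/dl), with linear
  interpolation at threshold crossings;
* hour-of-day PPGR profile and PPGR percentiles.

All integrals treat the trace as piecewise linear between readings and are
computed in closed form, including at baseline/threshold crossings, so they
match arbitrarily fine numerical recomputation to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GlucoseTrace, MealEvent

DEFAULT_THRESHOLDS = (140.0, 150.0, 160.0, 170.0, 180.0)
DEFAULT_PPGR_WINDOW_H = 2.0
DEFAULT_MIN_COVERAGE = 0.75
DEFAULT_BLOCK_SIZE = 9
#: minimum readings for a calendar day to count toward daily metrics
#: (half of the 96 expected at 15-min sampling)
DEFAULT_MIN_DAY_READINGS = 48


@dataclass(frozen=True)
class PPGRResult:
    """Outcome of one meal's iAUC computation."""

    meal: MealEvent
    iauc: float | None
    coverage: float
    baseline: float | None
    reason: str | None = None  # set when the meal was uncomputable

    @property
    def computable(self) -> bool:
        return self.iauc is not None


@dataclass
class GlycemicSummary:
    """Per-participant (or per-period) glycemic summary."""

    mean_glucose: float | None
    cv: float | None
    time_above: dict[float, float | None]
    averaged_ppgr: float | None
    hourly_ppgr_profile: dict[int, float]
    ppgr_percentiles: dict[float, float]
    n_meals_computable: int = 0
    n_meals_uncomputable: int = 0


def positive_area(t_hours: np.ndarray, y: np.ndarray) -> float:
    """Exact integral of max(0, y(t)) for the piecewise-linear curve through
    (t_hours, y), handling sign changes analytically."""
    t = np.asarray(t_hours, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 2:
        return 0.0
    dt = np.diff(t)
    y0, y1 = y[:-1], y[1:]
    both_pos = (y0 >= 0) & (y1 >= 0)
    both_neg = (y0 <= 0) & (y1 <= 0)
    area = np.where(both_pos, 0.5 * (y0 + y1) * dt, 0.0)
    mixed = ~(both_pos | both_neg)
    if mixed.any():
        # one endpoint above zero, one strictly below: triangle on the
        # positive side of the crossing
        pos = np.maximum(y0[mixed], y1[mixed])
        neg = np.minimum(y0[mixed], y1[mixed])
        area[mixed] = 0.5 * pos * (pos / (pos - neg)) * dt[mixed]
    return float(area.sum())


def net_area(t_hours: np.ndarray, y: np.ndarray) -> float:
    """Signed trapezoidal integral (no below-baseline clipping)."""
    if len(t_hours) < 2:
        return 0.0
    return float(np.trapezoid(np.asarray(y, float), np.asarray(t_hours, float)))


def _connection_containing(trace: GlucoseTrace, when: pd.Timestamp) -> tuple[int, int] | None:
    for a, b in trace.connections:
        if trace.timestamps[a] <= when <= trace.timestamps[b - 1]:
            return a, b
    return None


def meal_ppgr(
    trace: GlucoseTrace,
    meal: MealEvent,
    window_h: float = DEFAULT_PPGR_WINDOW_H,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    clip_below_baseline: bool = True,
) -> PPGRResult:
    """Incremental AUC (mg/dl x h) in the ``window_h`` hours after a meal.

    Baseline is the glucose at the meal-log time, linearly interpolated
    between the neighbouring readings of the sensor connection containing
    the meal. Area below baseline contributes zero unless
    ``clip_below_baseline=False`` (net AUC).
    """
    t_meal = pd.Timestamp(meal.timestamp)
    conn = _connection_containing(trace, t_meal)
    if conn is None:
        return PPGRResult(meal, None, 0.0, None, reason="meal outside any sensor connection")
    a, b = conn
    ts = trace.timestamps[a:b]
    glu = trace.glucose[a:b]
    th = (ts - t_meal).total_seconds().to_numpy() / 3600.0  # hours since meal

    baseline = float(np.interp(0.0, th, glu))
    in_win = (th >= 0.0) & (th <= window_h)
    if int(in_win.sum()) < 2:
        return PPGRResult(meal, None, 0.0, baseline, reason="fewer than 2 readings in window")

    t_in = th[in_win]
    g_in = glu[in_win]
    # anchor the curve at the meal time and, when the connection extends
    # past the window, at the window end
    if t_in[0] > 0.0:
        t_in = np.concatenate([[0.0], t_in])
        g_in = np.concatenate([[baseline], g_in])
    if th[-1] > window_h:
        g_end = float(np.interp(window_h, th, glu))
        t_in = np.concatenate([t_in, [window_h]])
        g_in = np.concatenate([g_in, [g_end]])

    coverage = float((t_in[-1] - 0.0) / window_h)
    if coverage < min_coverage:
        return PPGRResult(meal, None, coverage, baseline, reason="insufficient window coverage")

    excess = g_in - baseline
    iauc = positive_area(t_in, excess) if clip_below_baseline else net_area(t_in, excess)
    return PPGRResult(meal, float(iauc), coverage, baseline)


def averaged_ppgr(
    trace: GlucoseTrace,
    block_size: int = DEFAULT_BLOCK_SIZE,
    sliding: bool = False,
    clip_below_baseline: bool = True,
) -> float | None:
    """Mean iAUC over blocks of ``block_size`` consecutive readings.

    Each sensor connection is partitioned into consecutive non-overlapping
    blocks (default 9 readings, ~2 h at 15-min sampling); a trailing
    remainder shorter than a block is discarded. The block baseline is its
    first reading. ``sliding=True`` instead evaluates every window of
    ``block_size`` consecutive readings. Returns None when no connection
    holds a complete block.
    """
    areas: list[float] = []
    origin = trace.timestamps[0] if len(trace) else None
    for sl in trace.connection_slices():
        th = trace.times_hours(origin)[sl]
        glu = trace.glucose[sl]
        n = len(glu)
        if n < block_size:
            continue
        starts = range(0, n - block_size + 1) if sliding else range(0, n - block_size + 1, block_size)
        for s in starts:
            t_blk = th[s : s + block_size]
            g_blk = glu[s : s + block_size]
            excess = g_blk - g_blk[0]
            areas.append(
                positive_area(t_blk, excess) if clip_below_baseline else net_area(t_blk, excess)
            )
    return float(np.mean(areas)) if areas else None


def glucose_cv(trace: GlucoseTrace, start=None, stop=None) -> float | None:
    """Coefficient of variation (sample sd / mean) of readings in a period."""
    glu = trace.glucose
    if start is not None or stop is not None:
        mask = np.ones(len(trace), dtype=bool)
        if start is not None:
            mask &= (trace.timestamps >= pd.Timestamp(start)).to_numpy()
        if stop is not None:
            mask &= (trace.timestamps < pd.Timestamp(stop)).to_numpy()
        glu = glu[mask]
    if len(glu) < 2:
        return None
    return float(np.std(glu, ddof=1) / np.mean(glu))


def mean_glucose(trace: GlucoseTrace) -> float | None:
    return float(np.mean(trace.glucose)) if len(trace) else None


def _segments_with_midnights(trace: GlucoseTrace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-connection piecewise-linear samples with interpolated points
    inserted at every local-midnight crossing.

    Returns concatenated (epoch_hours, glucose, segment_break) arrays where
    ``segment_break[i]`` is True when point i does NOT connect to point i+1
    (connection boundary)."""
    ts_all: list[np.ndarray] = []
    glu_all: list[np.ndarray] = []
    brk_all: list[np.ndarray] = []
    epoch = pd.Timestamp("1970-01-01")
    for sl in trace.connection_slices():
        th = (trace.timestamps[sl] - epoch).total_seconds().to_numpy() / 3600.0
        glu = trace.glucose[sl]
        if len(th) == 0:
            continue
        # midnights (in hours since epoch, multiples of 24) inside the span
        first_mid = (np.floor(th[0] / 24.0) + 1) * 24.0
        mids = np.arange(first_mid, th[-1], 24.0)
        mids = mids[(mids > th[0]) & (mids < th[-1])]
        if mids.size:
            g_mid = np.interp(mids, th, glu)
            th = np.concatenate([th, mids])
            glu = np.concatenate([glu, g_mid])
            order = np.argsort(th, kind="stable")
            th, glu = th[order], glu[order]
        brk = np.zeros(len(th), dtype=bool)
        brk[-1] = True
        ts_all.append(th)
        glu_all.append(glu)
        brk_all.append(brk)
    if not ts_all:
        return np.array([]), np.array([]), np.array([], dtype=bool)
    return np.concatenate(ts_all), np.concatenate(glu_all), np.concatenate(brk_all)


def _hours_above_segments(t: np.ndarray, y: np.ndarray, thr: float) -> np.ndarray:
    """Per-segment duration (hours) with y(t) strictly above thr."""
    dt = np.diff(t)
    d0 = y[:-1] - thr
    d1 = y[1:] - thr
    out = np.zeros_like(dt)
    both_above = (d0 > 0) & (d1 > 0)
    out[both_above] = dt[both_above]
    mixed = ((d0 > 0) | (d1 > 0)) & ~both_above
    if mixed.any():
        hi = np.maximum(d0[mixed], d1[mixed])
        lo = np.minimum(d0[mixed], d1[mixed])
        out[mixed] = dt[mixed] * hi / (hi - lo)
    return out


def time_above(
    trace: GlucoseTrace,
    thresholds=DEFAULT_THRESHOLDS,
    min_day_readings: int = DEFAULT_MIN_DAY_READINGS,
) -> dict[float, float | None]:
    """Daily hours with glucose strictly above each threshold (mg/dl).

    Calendar days are split at local midnight (interpolating the trace at
    the crossing). Within a day, time above threshold is summed over the
    piecewise-linear segments of each connection, interpolating at threshold
    crossings, then rescaled from the covered span to a 24-h day. Days with
    fewer than ``min_day_readings`` readings are dropped; the result is the
    mean over qualifying days, or None when no day qualifies.
    """
    if len(trace) == 0:
        return {float(t): None for t in thresholds}
    t, y, brk = _segments_with_midnights(trace)
    if len(t) < 2:
        return {float(t0): None for t0 in thresholds}
    seg_ok = ~brk[:-1]  # segment i connects point i to i+1
    dt = np.diff(t)
    # guard against segments spanning a midnight boundary exactly at a point
    day_of_seg = np.floor(t[:-1] / 24.0).astype(int)
    covered = {}
    for d in np.unique(day_of_seg):
        m = seg_ok & (day_of_seg == d)
        covered[d] = dt[m].sum()
    # qualifying days by raw reading count (not interpolated points)
    days_of_readings = np.floor(
        (trace.timestamps - pd.Timestamp("1970-01-01")).total_seconds().to_numpy() / 3600.0 / 24.0
    ).astype(int)
    counts = pd.Series(days_of_readings).value_counts()
    qualifying = [d for d in covered if counts.get(d, 0) >= min_day_readings and covered[d] > 0]
    out: dict[float, float | None] = {}
    for thr in thresholds:
        if not qualifying:
            out[float(thr)] = None
            continue
        above = _hours_above_segments(t, y, float(thr))
        per_day = []
        for d in qualifying:
            m = seg_ok & (day_of_seg == d)
            per_day.append(above[m].sum() * 24.0 / covered[d])
        out[float(thr)] = float(np.mean(per_day))
    return out


def meal_ppgrs(
    trace: GlucoseTrace,
    meals: list[MealEvent],
    window_h: float = DEFAULT_PPGR_WINDOW_H,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    clip_below_baseline: bool = True,
) -> list[PPGRResult]:
    return [
        meal_ppgr(trace, m, window_h=window_h, min_coverage=min_coverage,
                  clip_below_baseline=clip_below_baseline)
        for m in meals
    ]


def hourly_ppgr_profile(results: list[PPGRResult]) -> dict[int, float]:
    """Mean computable iAUC bucketed by local hour of the meal timestamp."""
    buckets: dict[int, list[float]] = {}
    for r in results:
        if r.computable:
            buckets.setdefault(pd.Timestamp(r.meal.timestamp).hour, []).append(r.iauc)
    return {h: float(np.mean(v)) for h, v in sorted(buckets.items())}


def ppgr_percentiles(values, percentiles=(10, 25, 50, 75, 90)) -> dict[float, float]:
    """Linear-interpolation empirical percentiles of iAUC values."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        return {}
    return {float(p): float(np.percentile(vals, p)) for p in percentiles}


def summarize(
    trace: GlucoseTrace,
    meals: list[MealEvent] | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    **ppgr_kwargs,
) -> GlycemicSummary:
    """Full glycemic summary for one participant-period."""
    results = meal_ppgrs(trace, meals or [], **ppgr_kwargs)
    computable = [r.iauc for r in results if r.computable]
    return GlycemicSummary(
        mean_glucose=mean_glucose(trace),
        cv=glucose_cv(trace),
        time_above=time_above(trace, thresholds),
        averaged_ppgr=averaged_ppgr(trace),
        hourly_ppgr_profile=hourly_ppgr_profile(results),
        ppgr_percentiles=ppgr_percentiles(computable),
        n_meals_computable=len(computable),
        n_meals_uncomputable=len(results) - len(computable),
    )
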