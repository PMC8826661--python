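"""Independent brute-force recomputations used to check the CGM metrics.

These oracles treat the trace as a piecewise-linear curve, resample it on a
dense grid augmented with the original nodes and the exact
threshold/baseline crossings, and integrate/classify numerically — a code
path deliberately different from the package's segment-wise closed forms.
"""

from __future__ import annotations

import numpy as np


def _dense_grid(t: np.ndarray, step_h: float) -> np.ndarray:
    lo, hi = t[0], t[-1]
    grid = np.arange(lo, hi, step_h)
    return np.unique(np.concatenate([grid, t, [hi]]))


def _with_crossings(tg: np.ndarray, yg: np.ndarray, level: float):
    """Insert exact crossing points of the sampled piecewise-linear curve."""
    d = yg - level
    sign_change = d[:-1] * d[1:] < 0
    idx = np.flatnonzero(sign_change)
    if idx.size:
        frac = d[idx] / (d[idx] - d[idx + 1])
        tc = tg[idx] + frac * (tg[idx + 1] - tg[idx])
        tg = np.concatenate([tg, tc])
        yg = np.concatenate([yg, np.full(tc.shape, level)])
        order = np.argsort(tg, kind="stable")
        tg, yg = tg[order], yg[order]
    return tg, yg


def area_above(t_h: np.ndarray, y: np.ndarray, baseline: float, step_h: float = 1e-4) -> float:
    """Integral of max(0, y - baseline) by dense-grid trapezoid."""
    t_h = np.asarray(t_h, float)
    y = np.asarray(y, float)
    if len(t_h) < 2:
        return 0.0
    tg = _dense_grid(t_h, step_h)
    yg = np.interp(tg, t_h, y)
    tg, yg = _with_crossings(tg, yg, baseline)
    return float(np.trapezoid(np.clip(yg - baseline, 0.0, None), tg))


def hours_above(t_h: np.ndarray, y: np.ndarray, thr: float, step_h: float = 1e-4) -> float:
    """Duration with y strictly above thr, by dense-grid classification."""
    t_h = np.asarray(t_h, float)
    y = np.asarray(y, float)
    if len(t_h) < 2:
        return 0.0
    tg = _dense_grid(t_h, step_h)
    yg = np.interp(tg, t_h, y)
    tg, yg = _with_crossings(tg, yg, thr)
    dt = np.diff(tg)
    mid_above = 0.5 * (yg[:-1] + yg[1:]) > thr
    return float(dt[mid_above].sum())


def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up rule."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
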