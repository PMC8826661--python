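"""Glycemic metrics: worked examples, brute-force oracle agreement and
structural invariants."""

import numpy as np
import pandas as pd
import pytest

import oracles
from pptkit import cgm
from pptkit.core import GlucoseTrace

from conftest import make_meal


class TestMealPPGR:
    def test_no_excursion_gives_zero(self, quarter_hour_grid):
        tr = GlucoseTrace("p00", quarter_hour_grid(9), [100] * 9)
        r = cgm.meal_ppgr(tr, make_meal())
        assert r.iauc == 0.0
        assert r.baseline == 100.0

    def test_triangular_excursion_area(self, triangular_trace):
        # linear rise +60 over 1 h then back: triangle area 0.5 * 2 h * 60
        r = cgm.meal_ppgr(triangular_trace, make_meal())
        assert r.iauc == pytest.approx(60.0, rel=1e-12)

    def test_dip_below_baseline_clipped_to_zero(self, quarter_hour_grid):
        tr = GlucoseTrace("p00", quarter_hour_grid(9), [100, 90, 80, 90, 100, 100, 100, 100, 100])
        assert cgm.meal_ppgr(tr, make_meal()).iauc == 0.0
        # net-AUC sensitivity flag sees the negative area
        assert cgm.meal_ppgr(tr, make_meal(), clip_below_baseline=False).iauc < 0

    def test_insufficient_coverage_flagged(self, quarter_hour_grid):
        tr = GlucoseTrace("p00", quarter_hour_grid(3), [100, 120, 110])  # 30 min of a 2-h window
        r = cgm.meal_ppgr(tr, make_meal())
        assert not r.computable
        assert "coverage" in r.reason

    def test_invariant_to_readings_after_window(self, triangular_trace):
        base = cgm.meal_ppgr(triangular_trace, make_meal()).iauc
        ts = list(triangular_trace.timestamps) + [
            triangular_trace.timestamps[-1] + pd.Timedelta(minutes=15 * (i + 1))
            for i in range(4)
        ]
        extended = GlucoseTrace("p00", ts, list(triangular_trace.glucose) + [200, 250, 220, 180])
        assert cgm.meal_ppgr(extended, make_meal()).iauc == pytest.approx(base, rel=1e-12)

    def test_baseline_interpolated_between_neighbours(self, quarter_hour_grid):
        tr = GlucoseTrace("p00", quarter_hour_grid(12), [100, 120] + [120] * 10)
        r = cgm.meal_ppgr(tr, make_meal(when="2020-01-01 08:07:30"))
        assert r.baseline == pytest.approx(110.0)


class TestAveragedPPGR:
    def test_constant_trace_zero(self, quarter_hour_grid):
        tr = GlucoseTrace("p00", quarter_hour_grid(18), [120] * 18)
        assert cgm.averaged_ppgr(tr) == 0.0

    def test_two_blocks_mean(self, quarter_hour_grid):
        # block 1 flat; block 2 a symmetric bump peaking +40 at its centre
        bump = [100, 110, 120, 130, 140, 130, 120, 110, 100]
        tr = GlucoseTrace("p00", quarter_hour_grid(18), [100] * 9 + bump)
        t_h = np.arange(9) * 0.25
        expected_block2 = oracles.area_above(t_h, np.array(bump, float), 100.0)
        assert cgm.averaged_ppgr(tr) == pytest.approx((0.0 + expected_block2) / 2, rel=1e-9)

    def test_incomplete_block_absent(self, quarter_hour_grid):
        tr = GlucoseTrace("p00", quarter_hour_grid(8), [120] * 8)
        assert cgm.averaged_ppgr(tr) is None

    def test_no_blocks_cross_connections(self, quarter_hour_grid):
        # 12 + 6 readings in two connections: only the first holds a block
        ts = quarter_hour_grid(18)
        glu = np.linspace(100, 180, 18)
        split = GlucoseTrace("p00", ts, glu, [(0, 12), (12, 18)])
        merged_first = GlucoseTrace("p00", ts[:12], glu[:12])
        assert cgm.averaged_ppgr(split) == pytest.approx(
            cgm.averaged_ppgr(merged_first), rel=1e-12
        )


class TestCVAndPercentiles:
    def test_cv_constant_and_scale_invariance(self, quarter_hour_grid):
        tr = GlucoseTrace("p00", quarter_hour_grid(10), [130] * 10)
        assert cgm.glucose_cv(tr) == 0.0
        rng = np.random.default_rng(3)
        g = rng.uniform(80, 200, 48)
        a = cgm.glucose_cv(GlucoseTrace("p00", quarter_hour_grid(48), g))
        b = cgm.glucose_cv(GlucoseTrace("p00", quarter_hour_grid(48), 1.7 * g))
        assert a == pytest.approx(b, rel=1e-12)

    def test_cv_alternating_readings(self, quarter_hour_grid):
        g = np.array([90.0, 110.0] * 48)
        got = cgm.glucose_cv(GlucoseTrace("p00", quarter_hour_grid(96), g))
        assert got == pytest.approx(np.std(g, ddof=1) / g.mean(), rel=1e-12)
        assert got == pytest.approx(0.1005, abs=5e-4)

    def test_single_reading_absent(self, quarter_hour_grid):
        assert cgm.glucose_cv(GlucoseTrace("p00", quarter_hour_grid(1), [100])) is None

    def test_percentiles(self):
        assert cgm.ppgr_percentiles([42.0]) == {p: 42.0 for p in (10.0, 25.0, 50.0, 75.0, 90.0)}
        vals = np.linspace(0, 100, 101)
        assert cgm.ppgr_percentiles(vals)[50.0] == pytest.approx(50.0)
        rng = np.random.default_rng(1)
        sample = rng.gamma(2, 20, 200)
        got = cgm.ppgr_percentiles(sample)
        for p, v in got.items():
            assert v == pytest.approx(float(np.percentile(sample, p)), rel=1e-12)


class TestTimeAbove:
    def test_constant_full_day(self):
        day = [pd.Timestamp("2020-01-01") + pd.Timedelta(minutes=15 * i) for i in range(96)]
        ta = cgm.time_above(GlucoseTrace("p00", day, [150] * 96))
        assert ta[140.0] == pytest.approx(24.0)
        assert ta[150.0] == 0.0  # strictly above
        assert ta[160.0] == 0.0

    def test_constant_below_all_thresholds(self):
        day = [pd.Timestamp("2020-01-01") + pd.Timedelta(minutes=15 * i) for i in range(96)]
        ta = cgm.time_above(GlucoseTrace("p00", day, [130] * 96))
        assert all(v == 0.0 for v in ta.values())

    def test_step_with_linear_transition(self):
        # 12 h at 160, one 15-min linear drop, then 120: crossing of the
        # 140 threshold sits inside the transition segment
        day = [pd.Timestamp("2020-01-01") + pd.Timedelta(minutes=15 * i) for i in range(96)]
        glu = np.where(np.arange(96) < 48, 160.0, 120.0)
        tr = GlucoseTrace("p00", day, glu)
        t_h = np.arange(96) * 0.25
        expected = oracles.hours_above(t_h, glu, 140.0) * 24.0 / t_h[-1]
        got = cgm.time_above(tr)[140.0]
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(12.0 * 24 / 23.75, abs=0.2)

    def test_monotone_in_threshold(self, random_day_trace):
        rng = np.random.default_rng(7)
        for _ in range(10):
            ta = cgm.time_above(random_day_trace(rng))
            vals = [ta[t] for t in sorted(ta)]
            vals = [v for v in vals if v is not None]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
            assert all(0.0 <= v <= 24.0 + 1e-9 for v in vals)

    def test_sparse_day_absent(self):
        day = [pd.Timestamp("2020-01-01") + pd.Timedelta(hours=i) for i in range(10)]
        ta = cgm.time_above(GlucoseTrace("p00", day, [150] * 10))
        assert all(v is None for v in ta.values())


class TestHourlyProfile:
    def test_single_and_averaged_buckets(self, quarter_hour_grid):
        tr = GlucoseTrace("p00", quarter_hour_grid(96, "2020-01-01 00:00"),
                          [100] * 96)
        meals = [make_meal(when="2020-01-01 12:00"), make_meal(when="2020-01-01 12:30")]
        results = cgm.meal_ppgrs(tr, meals)
        prof = cgm.hourly_ppgr_profile(results)
        assert set(prof) == {12}
        assert prof[12] == pytest.approx(0.0)

    def test_bucketed_means_match_groupby_oracle(self, random_day_trace):
        rng = np.random.default_rng(11)
        tr = random_day_trace(rng, n_readings=96)
        meals = [
            make_meal(when=tr.timestamps[int(rng.integers(0, 80))])
            for _ in range(15)
        ]
        results = cgm.meal_ppgrs(tr, meals)
        prof = cgm.hourly_ppgr_profile(results)
        df = pd.DataFrame(
            {
                "hour": [pd.Timestamp(r.meal.timestamp).hour for r in results if r.computable],
                "iauc": [r.iauc for r in results if r.computable],
            }
        )
        expected = df.groupby("hour")["iauc"].mean()
        assert prof == pytest.approx(expected.to_dict())


class TestOracleSuite:
    """All metrics vs dense-grid brute-force recomputation on random traces."""

    def test_metrics_match_brute_force(self, random_day_trace):
        rng = np.random.default_rng(2024)
        for rep in range(50):
            tr = random_day_trace(rng)
            origin = tr.timestamps[0]
            t_h = tr.times_hours(origin)

            # meal PPGR at a random on-trace meal time
            i0 = int(rng.integers(0, max(1, len(tr) - 10)))
            meal = make_meal(when=tr.timestamps[i0])
            r = cgm.meal_ppgr(tr, meal)
            if r.computable:
                a, b = next(
                    (c for c in tr.connections if c[0] <= i0 < c[1]), tr.connections[0]
                )
                lo = t_h[i0]
                hi = min(lo + 2.0, t_h[b - 1])
                seg = (t_h >= lo) & (t_h <= hi) & (np.arange(len(tr)) >= a) & (np.arange(len(tr)) < b)
                expected = oracles.area_above(t_h[seg], tr.glucose[seg], r.baseline)
                assert r.iauc == pytest.approx(expected, rel=1e-9, abs=1e-9)

            # averaged PPGR block oracle
            got_avg = cgm.averaged_ppgr(tr)
            blocks = []
            for a, b in tr.connections:
                for s in range(a, b - 8, 9):
                    tt, gg = t_h[s : s + 9], tr.glucose[s : s + 9]
                    blocks.append(oracles.area_above(tt, gg, gg[0]))
            if blocks:
                rel = abs(got_avg - np.mean(blocks)) / max(1e-9, abs(np.mean(blocks)))
                assert rel < 1e-6 or abs(got_avg - np.mean(blocks)) < 1e-9

            # CV
            assert cgm.glucose_cv(tr) == pytest.approx(
                np.std(tr.glucose, ddof=1) / np.mean(tr.glucose), rel=1e-12
            )

            # time above threshold, per qualifying day
            ta = cgm.time_above(tr, min_day_readings=48)
            days = tr.timestamps.normalize()
            for thr, got in ta.items():
                per_day = []
                for day in days.unique():
                    day_expected = 0.0
                    covered = 0.0
                    count = int((days == day).sum())
                    if count < 48:
                        continue
                    nxt = day + pd.Timedelta(days=1)
                    for a, b in tr.connections:
                        ts = tr.timestamps[a:b]
                        th = t_h[a:b]
                        gl = tr.glucose[a:b]
                        lo = max(th[0], (day - origin).total_seconds() / 3600.0)
                        hi = min(th[-1], (nxt - origin).total_seconds() / 3600.0)
                        if hi <= lo:
                            continue
                        grid = np.unique(np.concatenate([[lo, hi], th[(th > lo) & (th < hi)]]))
                        gg = np.interp(grid, th, gl)
                        day_expected += oracles.hours_above(grid, gg, thr)
                        covered += hi - lo
                    if covered > 0:
                        per_day.append(day_expected * 24.0 / covered)
                if per_day:
                    expected = float(np.mean(per_day))
                    assert got == pytest.approx(expected, rel=1e-6, abs=1e-9), (rep, thr)
                else:
                    assert got is None
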