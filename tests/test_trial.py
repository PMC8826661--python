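"""Crossover and longitudinal statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pptkit import trial
from pptkit.simulate import SyntheticCohortConfig, generate_crossover_outcomes


def records_from_diffs(diffs, base=60.0, n_ppt_first=None):
    n = len(diffs)
    n_ppt_first = n // 2 if n_ppt_first is None else n_ppt_first
    return [
        trial.CrossoverRecord(
            f"p{i:02d}",
            "PPT-MED" if i < n_ppt_first else "MED-PPT",
            base + d,
            base,
        )
        for i, d in enumerate(diffs)
    ]


class TestCrossoverEffect:
    def test_identical_outcomes_null(self):
        recs = records_from_diffs(np.zeros(6))
        e = trial.crossover_effect(recs, model="paired_t")
        assert e.estimate == 0.0 and e.p_value == 1.0

    def test_paired_t_is_mean_of_differences(self):
        rng = np.random.default_rng(4)
        diffs = rng.normal(-15, 10, 12)
        e = trial.crossover_effect(records_from_diffs(diffs), model="paired_t")
        assert e.estimate == pytest.approx(diffs.mean(), rel=1e-12)
        assert e.dispersion == pytest.approx(diffs.std(ddof=1), rel=1e-12)
        assert e.p_value == pytest.approx(stats.ttest_1samp(diffs, 0).pvalue, rel=1e-12)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(8)
        diffs = rng.normal(-10, 8, 10)
        recs = records_from_diffs(diffs)
        swapped = [
            trial.CrossoverRecord(
                r.participant_id,
                "MED-PPT" if r.sequence == "PPT-MED" else "PPT-MED",
                r.med_value,
                r.ppt_value,
            )
            for r in recs
        ]
        for model in ("paired_t", "mann_whitney"):
            a = trial.crossover_effect(recs, model=model)
            b = trial.crossover_effect(swapped, model=model)
            assert a.estimate == pytest.approx(-b.estimate, rel=1e-12)
            assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_p_invariant_to_participant_order(self):
        rng = np.random.default_rng(12)
        recs = records_from_diffs(rng.normal(-5, 10, 9))
        for model in trial.CROSSOVER_MODELS:
            a = trial.crossover_effect(recs, model=model)
            b = trial.crossover_effect(recs[::-1], model=model)
            assert a.p_value == pytest.approx(b.p_value, rel=1e-6)
            assert 0.0 <= a.p_value <= 1.0

    def test_lmm_suite_recovers_injected_effect(self):
        cfg = SyntheticCohortConfig()
        recs = generate_crossover_outcomes(cfg, np.random.default_rng(30))
        for model in ("lmm", "lmm_period", "lmm_sequence"):
            e = trial.crossover_effect(recs, model=model)
            assert e.estimate == pytest.approx(-20.0, abs=12.0)
            assert e.p_value < 0.05

    def test_too_few_participants(self):
        with pytest.raises(ValueError, match=">= 3"):
            trial.crossover_effect(records_from_diffs([1.0, 2.0]))


class TestLongitudinal:
    def test_no_change_null(self):
        x = np.array([6.5, 7.0, 7.5, 6.8])
        e = trial.longitudinal_change(x, x)
        assert e.estimate == 0.0 and e.p_value == 1.0

    def test_common_shift_zero_noise(self):
        x = np.array([6.5, 7.0, 7.5, 6.8])
        e = trial.longitudinal_change(x, x - 0.4)
        assert e.estimate == pytest.approx(-0.4)

    def test_t_statistic_matches_closed_form(self):
        before = np.array([100.0, 110.0, 120.0, 130.0, 140.0])
        after = np.array([90.0, 108.0, 111.0, 125.0, 128.0])
        d = after - before
        e = trial.longitudinal_change(before, after)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * stats.t.sf(abs(t), len(d) - 1)
        assert e.p_value == pytest.approx(p, rel=1e-12)

    def test_rank_alternative(self):
        rng = np.random.default_rng(2)
        before = rng.normal(5, 1, 10)
        after = before - rng.gamma(2, 0.5, 10)
        e = trial.longitudinal_change(before, after, test="rank")
        assert e.model == "one_sample_rank"
        assert e.p_value == pytest.approx(stats.wilcoxon(after - before).pvalue, rel=1e-9)


class TestHomaIR:
    def test_calibration_point(self):
        assert trial.homa_ir(90.0, 4.5) == pytest.approx(1.0)

    def test_linear_in_insulin(self):
        assert trial.homa_ir(120.0, 10.0) == pytest.approx(2 * trial.homa_ir(120.0, 5.0))

    def test_random_inputs_vs_formula(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            g, i = rng.uniform(70, 200), rng.uniform(2, 40)
            assert trial.homa_ir(g, i) == pytest.approx(g * i / 405.0, rel=1e-12)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            trial.homa_ir(0.0, 5.0)


class TestRemission:
    def test_everyone_crosses(self):
        r = trial.remission_rate([7.0, 6.8], [6.0, 6.2])
        assert (r.numerator, r.denominator) == (2, 2)
        assert r.fraction == 1.0

    def test_boundary_convention(self):
        # baseline exactly 6.5 is in the denominator; end exactly 6.5 is not remitted
        r = trial.remission_rate([6.5], [6.5])
        assert (r.numerator, r.denominator) == (0, 1)

    def test_eight_of_thirteen(self):
        baseline = [6.4, 6.4, 6.4] + [6.6] * 13
        end = [6.0] * 3 + [6.1] * 8 + [6.9] * 5
        r = trial.remission_rate(baseline, end)
        assert (r.numerator, r.denominator) == (8, 13)
        assert int(100 * r.fraction) == 61

    def test_empty_denominator(self):
        assert trial.remission_rate([6.0], [5.9]).fraction is None


class TestAdherenceSubgroups:
    def test_identical_changes_null(self):
        changes = pd.DataFrame({"hba1c": [-0.3] * 8}, index=[f"p{i}" for i in range(8)])
        grades = {f"p{i}": float(g) for i, g in enumerate([70, 75, 80, 82, 85, 88, 90, 95])}
        out = trial.adherence_subgroup_compare(changes, grades)
        assert out.loc[0, "p_value"] == 1.0

    def test_degenerate_split_errors(self):
        changes = pd.DataFrame({"hba1c": np.arange(6.0)}, index=[f"p{i}" for i in range(6)])
        grades = {f"p{i}": 84.4 for i in range(6)}
        with pytest.raises(ValueError, match="degenerate"):
            trial.adherence_subgroup_compare(changes, grades)

    def test_median_ties_go_high_and_split_matches_brute_force(self):
        rng = np.random.default_rng(13)
        grades = {f"p{i}": float(g) for i, g in enumerate(rng.uniform(60, 100, 10))}
        changes = pd.DataFrame(
            {"fpg": rng.normal(-10, 5, 10)}, index=list(grades)
        )
        out = trial.adherence_subgroup_compare(changes, grades)
        med = np.median(list(grades.values()))
        n_high = sum(g >= med for g in grades.values())
        assert out.loc[0, "n_high"] == n_high
        assert out.attrs["median_grade"] == pytest.approx(med)


class TestIntraInterCV:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["participant_id", "food", "iauc"])

    def test_identical_meals_zero_everywhere(self):
        rows = [("a", "bread", 50), ("a", "bread", 50), ("b", "bread", 50), ("b", "bread", 50)]
        r = trial.intra_inter_cv(self._frame(rows))
        assert r.mean_intra_cv == 0.0 and r.mean_inter_cv == 0.0

    def test_pure_between_person_signal(self):
        rows = [("a", "bread", 30), ("a", "bread", 30), ("b", "bread", 90), ("b", "bread", 90)]
        r = trial.intra_inter_cv(self._frame(rows))
        assert r.mean_intra_cv == 0.0
        assert r.mean_inter_cv > 0.0

    def test_recovers_ordering_when_person_variance_dominates(self):
        """With person x food SD well above residual SD, within-person CV
        should fall below between-person CV in most seeded replicates."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rows = []
            for food in ("bread", "rice", "pasta"):
                person_medians = 60 + 25 * rng.standard_normal(6)  # tau = 25
                for i, mu in enumerate(person_medians):
                    for _ in range(4):
                        rows.append((f"p{i}", food, max(1.0, mu + 8 * rng.standard_normal())))
            r = trial.intra_inter_cv(self._frame(rows))
            wins += r.mean_intra_cv < r.mean_inter_cv
        assert wins > n_seeds / 2

    def test_insufficient_replication_skipped(self):
        rows = [("a", "bread", 50), ("a", "bread", 60),
                ("a", "rice", 40), ("b", "rice", 55), ("a", "rice", 45), ("b", "rice", 50)]
        r = trial.intra_inter_cv(self._frame(rows))
        assert "bread" in r.skipped_foods
        assert list(r.per_food["food"]) == ["rice"]
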