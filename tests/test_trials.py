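"""Trial classification geometry and the behavioral statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saccatk import trials as T
from saccatk.eyekin import SaccadeEvent
from saccatk.trials import Outcome, TargetLayout, TrialEvents

import oracles


def make_events(direction=0.0, ecc=10.0, go=1000.0):
    return TrialEvents(
        task="step", fix_on_ms=0.0, fix_off_ms=go, target_on_ms=go,
        target_direction_deg=direction, target_eccentricity_deg=ecc,
    )


def sacc(onset, end, start=(0.0, 0.0), dur=40.0):
    return SaccadeEvent(onset, onset + dur, start=start, end=end)


class TestWindowRadius:
    def test_printed_formula_at_10deg(self):
        assert T.window_radius(10.0) == pytest.approx(3.8268, abs=1e-4)
        assert T.window_radius(10.0) == 10.0 * math.sin(math.radians(22.5))

    @given(st.floats(min_value=1e-4, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_adjacent_windows_tangent_never_overlapping(self, ecc):
        # chord between 45-deg-spaced targets equals 2 * ecc * sin(22.5 deg):
        # adjacent windows touch exactly and never overlap
        r = T.window_radius(ecc)
        chord = 2 * ecc * math.sin(math.radians(22.5))
        assert 2 * r == pytest.approx(chord, rel=1e-12)

    @given(st.floats(min_value=1e-3, max_value=100.0), st.floats(min_value=1e-3, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, a, b):
        if a < b:
            assert T.window_radius(a) < T.window_radius(b)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            T.window_radius(0.0)


class TestClassifyTrial:
    layout = TargetLayout(eccentricity_deg=10.0)

    def test_clean_success(self):
        ev = make_events()
        rec = T.classify_trial(ev, [sacc(1150.0, (10.0, 0.0))], self.layout)
        assert rec.outcome is Outcome.SUCCESS
        assert rec.reaction_time_ms == 150.0
        assert rec.direction_error_deg == pytest.approx(0.0)
        assert rec.eccentricity_error_deg == pytest.approx(0.0)

    def test_anticipatory_excluded(self):
        rec = T.classify_trial(make_events(), [sacc(1080.0, (10.0, 0.0))], self.layout)
        assert rec.outcome is Outcome.ANTICIPATORY_EXCLUDED

    def test_fixation_break_excluded(self):
        sacs = [sacc(500.0, (5.0, 5.0)), sacc(1150.0, (10.0, 0.0))]
        rec = T.classify_trial(make_events(), sacs, self.layout)
        assert rec.outcome is Outcome.FIXATION_BREAK_EXCLUDED

    def test_offtarget_error_outside_window(self):
        r = self.layout.window_radius_deg
        end = (10.0 + 1.2 * r, 0.0)
        rec = T.classify_trial(make_events(), [sacc(1150.0, end)], self.layout)
        assert rec.outcome is Outcome.ERROR_OFFTARGET

    def test_multistep_error_when_corrective_reaches_window(self):
        r = self.layout.window_radius_deg
        sacs = [
            sacc(1150.0, (10.0 + 1.5 * r, 0.0)),
            sacc(1300.0, (10.0, 0.0), start=(10.0 + 1.5 * r, 0.0)),
        ]
        rec = T.classify_trial(make_events(), sacs, self.layout)
        assert rec.outcome is Outcome.ERROR_MULTISTEP

    def test_late_saccade_is_timing_error(self):
        rec = T.classify_trial(make_events(), [sacc(2100.0, (10.0, 0.0))], self.layout)
        assert rec.outcome is Outcome.ERROR_TIMING

    def test_slow_window_entry_is_timing_error(self):
        rec = T.classify_trial(make_events(), [sacc(1150.0, (10.0, 0.0), dur=250.0)], self.layout)
        assert rec.outcome is Outcome.ERROR_TIMING

    def test_no_saccade_is_timing_error(self):
        rec = T.classify_trial(make_events(), [], self.layout)
        assert rec.outcome is Outcome.ERROR_TIMING


class TestSuccessRate:
    def _recs(self, outcomes):
        return [
            T.TrialRecord(events=make_events(), saccades=[], outcome=o) for o in outcomes
        ]

    def test_simple_ratio(self):
        recs = self._recs([Outcome.SUCCESS] * 19 + [Outcome.ERROR_OFFTARGET])
        rate, ns, nc = T.success_rate(recs)
        assert (rate, ns, nc) == (0.95, 19, 20)

    def test_exclusions_leave_denominator(self):
        base = [Outcome.SUCCESS] * 3 + [Outcome.ERROR_OFFTARGET]
        recs = self._recs(base)
        rate0 = T.success_rate(recs)[0]
        recs += self._recs([Outcome.ANTICIPATORY_EXCLUDED, Outcome.FIXATION_BREAK_EXCLUDED] * 5)
        assert T.success_rate(recs)[0] == rate0

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError):
            T.success_rate(self._recs([Outcome.ANTICIPATORY_EXCLUDED]))


class TestRepresentativeTarget:
    def test_argmin_delta(self):
        dirs = [0.0, 45.0, 90.0, 135.0]
        before = dict(zip(dirs, [0.9, 0.9, 0.9, 0.9]))
        after = dict(zip(dirs, [0.5, 0.8, 0.9, 1.0]))
        assert T.select_representative_target(before, after, dirs) == 0.0

    def test_tie_breaks_to_lowest_angle(self):
        dirs = [45.0, 0.0, 90.0]
        before = dict.fromkeys(dirs, 0.9)
        after = dict.fromkeys(dirs, 0.6)
        assert T.select_representative_target(before, after, dirs) == 0.0

    def test_chosen_delta_is_minimal(self, rng):
        dirs = [0.0, 45.0, 90.0, 135.0]
        for _ in range(50):
            before = {d: rng.random() for d in dirs}
            after = {d: rng.random() for d in dirs}
            rep = T.select_representative_target(before, after, dirs)
            deltas = {d: after[d] - before[d] for d in dirs}
            assert deltas[rep] <= min(deltas.values()) + 1e-15

    def test_empty_hemifield_rejected(self):
        with pytest.raises(ValueError):
            T.select_representative_target({}, {}, [])


class TestFisher:
    def test_small_table_exact_value(self):
        assert T.fisher_exact_one_tailed(2, 0, 0, 2) == pytest.approx(1 / 6, abs=1e-12)

    def test_identical_rows_not_significant(self):
        assert T.fisher_exact_one_tailed(8, 2, 8, 2) >= 0.5

    def test_matches_enumeration_oracle_small_margins(self):
        for nb in range(1, 9):
            for na in range(1, 9):
                for sb in range(nb + 1):
                    for sa in range(na + 1):
                        got = T.fisher_exact_one_tailed(sb, nb - sb, sa, na - sa)
                        want = oracles.fisher_one_tailed_enum(sb, nb - sb, sa, na - sa)
                        assert got == pytest.approx(want, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            T.fisher_exact_one_tailed(-1, 2, 3, 4)


class TestRankSum:
    def test_identical_samples(self):
        p = T.compare_reaction_times([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_fully_separated_exact_p(self):
        # smallest possible two-sided p for n=3 vs 3 is 2/20 = 0.1
        assert T.compare_reaction_times([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_type_i_error_calibrated(self, rng):
        n_sig = 0
        n_rep = 500
        for _ in range(n_rep):
            a, b = rng.normal(size=12), rng.normal(size=12)
            if T.compare_reaction_times(a, b) < 0.05:
                n_sig += 1
        assert n_sig / n_rep <= 0.07

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            T.compare_reaction_times([], [1.0])


class TestIqrBootstrap:
    def test_constant_sample(self):
        iqr, (lo, hi) = T.iqr_bootstrap_ci(np.full(20, 3.3), seed=1)
        assert iqr == 0.0 and (lo, hi) == (0.0, 0.0)

    def test_seed_reproducible(self):
        x = np.random.default_rng(0).normal(size=100)
        assert T.iqr_bootstrap_ci(x, seed=42) == T.iqr_bootstrap_ci(x, seed=42)

    def test_uniform_iqr_coverage(self, rng):
        # analytic IQR of U(0,1) is 0.5; CI should cover it in most replicates
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            x = rng.random(2000)
            _, (lo, hi) = T.iqr_bootstrap_ci(x, n_boot=400, seed=int(rng.integers(2**31)))
            hits += lo <= 0.5 <= hi
        assert hits / n_rep >= 0.90

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            T.iqr_bootstrap_ci(np.array([1.0, 2.0, 3.0]))


class TestRankAnova:
    def test_all_equal_gives_zero_f(self):
        v = np.ones(40)
        a = np.repeat(["pre", "post"], 20)
        b = np.tile(np.repeat(["L", "R"], 10), 2)
        res = T.rank_two_way_anova(v, a, b)
        assert (res["anova"]["F"].iloc[:3] == 0.0).all()

    def test_detects_shift_in_one_factor(self, rng):
        n = 50
        a = np.repeat(["pre", "post"], 2 * n)
        b = np.tile(np.repeat(["L", "R"], n), 2)
        v = rng.normal(size=4 * n)
        v[a == "post"] += 3.0
        res = T.rank_two_way_anova(v, a, b)
        anova = res["anova"]
        assert anova.loc["C(A)", "PR(>F)"] < 0.001
        assert anova.loc["C(B)", "PR(>F)"] > 0.1

    def test_bonferroni_multiplies_raw_p(self, rng):
        # adjusted p of every pair equals min(1, raw * number of pairs)
        from scipy import stats as ss

        n = 12
        a = np.repeat(["pre", "post"], 2 * n)
        b = np.tile(np.repeat(["L", "R"], n), 2)
        v = rng.normal(size=4 * n)
        res = T.rank_two_way_anova(v, a, b)
        pairs = list(res["posthoc"])
        assert len(pairs) == 6
        (ci, cj) = pairs[0]
        vi = v[(a == ci[0]) & (b == ci[1])]
        vj = v[(a == cj[0]) & (b == cj[1])]
        raw = ss.mannwhitneyu(vi, vj, alternative="two-sided").pvalue
        assert res["posthoc"][(ci, cj)] == pytest.approx(min(1.0, raw * 6))

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            T.rank_two_way_anova([1, 2, 3, 4], ["x", "x", "y", "y"], ["u", "u", "u", "u"])


class TestSessionComparison:
    def test_end_to_end_significant_drop(self):
        counts_before = {0.0: (19, 20), 45.0: (18, 20)}
        counts_after = {0.0: (8, 20), 45.0: (17, 20)}
        rep = T.session_comparison(counts_before, counts_after, [0.0, 45.0])
        assert rep["representative_target_deg"] == 0.0
        assert rep["significant"]
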