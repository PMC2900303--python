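"""Stage-window rates, Fisher exact test, ANOVA + Tukey HSD."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from furatrack import (
    DegenerateInputError,
    EventTable,
    StageClock,
    TransientEvent,
    ValidationError,
    anova_oneway_tukey,
    fisher_exact_2x2,
    rate_per_hour,
    summarize_groups,
    window_hours,
)
from oracles import anova_f_by_hand, fisher_two_tailed_enumeration


def event_at_frame(i, frame, label="transient"):
    return TransientEvent(
        id=i, onset_frame=frame, offset_frame=frame + 1, duration_s=30.0,
        centroid=(1.0, 1.0), area_px=4, peak_delta_ratio=0.5, label=label,
    )


def table_with_onsets(onsets, labels=None, n_frames=480, dt_s=15.0):
    labels = labels or ["transient"] * len(onsets)
    events = [event_at_frame(i, f, lab) for i, (f, lab) in enumerate(zip(sorted(onsets), labels))]
    return EventTable(events=events, dt_s=dt_s, n_frames=n_frames, height=16, width=16)


class TestStageWindow:
    def test_window_hours_forced_arithmetic(self):
        assert window_hours(StageClock(somites_per_hour=3.0), 6, 12) == pytest.approx(2.0)
        assert window_hours(StageClock(somites_per_hour=6.0), 6, 12) == pytest.approx(1.0)

    def test_reversed_window_rejected(self):
        with pytest.raises(ValidationError):
            window_hours(StageClock(), 12, 6)

    def test_zero_events_gives_zero_rate(self):
        assert rate_per_hour(table_with_onsets([]), StageClock(), 6, 12) == 0.0

    def test_rate_is_count_over_window_hours(self):
        """4 transients in a 0.75-h window -> 5.333/h."""
        clock = StageClock(s0=0.0, somites_per_hour=4.0)  # window [0,3) = 0.75 h
        frames = [10, 50, 100, 150]  # all inside first 0.75 h (t < 2700 s)
        rate = rate_per_hour(table_with_onsets(frames), clock, 0.0, 3.0)
        assert rate == pytest.approx(4 / 0.75)

    def test_sustained_events_excluded(self):
        clock = StageClock(s0=0.0, somites_per_hour=2.0)  # window [0,2) = 1 h
        frames = list(range(10, 110, 10))
        labels = ["sustained"] * 3 + ["transient"] * 7
        rate = rate_per_hour(table_with_onsets(frames, labels), clock, 0.0, 2.0)
        assert rate == pytest.approx(7.0)

    def test_window_outside_session_rejected(self):
        with pytest.raises(ValidationError):
            rate_per_hour(table_with_onsets([], n_frames=10), StageClock(), 6, 12)

    def test_rate_additive_over_adjacent_windows(self):
        clock = StageClock(s0=2.0, somites_per_hour=5.0)
        table = table_with_onsets([5, 100, 200, 288, 300, 400])
        r_ab = rate_per_hour(table, clock, 2, 7)
        r_bc = rate_per_hour(table, clock, 7, 12)
        total = rate_per_hour(table, clock, 2, 12)
        assert r_ab * window_hours(clock, 2, 7) + r_bc * window_hours(clock, 7, 12) == \
            pytest.approx(total * window_hours(clock, 2, 12))


class TestFisherExact:
    def test_balanced_table_gives_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        """Only the two extreme tables qualify: p = 2 / C(20, 10)."""
        from math import comb
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(2 / comb(20, 10), rel=1e-12)

    @pytest.mark.parametrize("table", [
        [[8, 2], [1, 9]], [[3, 7], [6, 2]], [[1, 11], [9, 2]], [[2, 2], [3, 11]],
    ])
    def test_matches_enumeration_oracle(self, table):
        (a, b), (c, d) = table
        assert fisher_exact_2x2(table) == pytest.approx(
            fisher_two_tailed_enumeration(a, b, c, d), abs=1e-12
        )

    def test_matches_scipy_reference(self):
        """Independent cross-check against scipy's two-sided implementation."""
        for table in ([[8, 2], [1, 9]], [[5, 1], [2, 7]], [[12, 3], [4, 9]]):
            assert fisher_exact_2x2(table) == pytest.approx(
                stats.fisher_exact(table, alternative="two-sided")[1], rel=1e-7
            )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    def test_invariance_under_transposition_and_row_col_swap(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        p = fisher_exact_2x2([[a, b], [c, d]])
        assert fisher_exact_2x2([[a, c], [b, d]]) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_2x2([[d, c], [b, a]]) == pytest.approx(p, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[0, 0], [3, 4]])

    def test_negative_entry_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


class TestAnovaTukey:
    def test_identical_group_means_give_f_zero_p_one(self):
        res = anova_oneway_tukey({"a": [1, 3], "b": [1, 3], "c": [1, 3]})
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        """{1,2,3},{2,3,4},{3,4,5}: SS_b = 6, SS_w = 6, F = 3.0."""
        groups = {"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]}
        res = anova_oneway_tukey(groups)
        f_hand, ss_b, ss_w = anova_f_by_hand([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert (ss_b, ss_w) == (6.0, 6.0)
        assert res.f_statistic == pytest.approx(3.0)
        assert res.f_statistic == pytest.approx(f_hand)
        assert res.df_between == 2
        assert res.df_within == 6
        assert res.p_value == pytest.approx(stats.f.sf(3.0, 2, 6))

    def test_matches_scipy_f_oneway(self, rng):
        groups = {k: rng.normal(m, 1.0, size=5).tolist() for k, m in zip("abc", (0, 1, 3))}
        res = anova_oneway_tukey(groups)
        f_ref, p_ref = stats.f_oneway(*groups.values())
        assert res.f_statistic == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)

    def test_tukey_matches_statsmodels(self, rng):
        """Adjusted pairwise p-values agree with an independent HSD
        implementation."""
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        data = {
            "a": rng.normal(5.0, 1.0, 4),
            "b": rng.normal(8.0, 1.0, 4),
            "c": rng.normal(5.5, 1.0, 4),
        }
        res = anova_oneway_tukey(data)
        values = np.concatenate(list(data.values()))
        labels = np.repeat(list(data), [len(v) for v in data.values()])
        ref = statsmodels.pairwise_tukeyhsd(values, labels)
        for row in ref.summary().data[1:]:
            g1, g2, p_adj = row[0], row[1], float(row[3])
            key = (g1, g2) if (g1, g2) in res.tukey_p else (g2, g1)
            assert res.tukey_p[key] == pytest.approx(p_adj, abs=1e-3)

    def test_scale_and_shift_invariance_of_f(self, rng):
        groups = {k: rng.normal(m, 1.0, 5) for k, m in zip("ab", (0, 2))}
        res = anova_oneway_tukey(groups)
        shifted = {k: v + 100.0 for k, v in groups.items()}
        scaled = {k: v * 7.0 for k, v in groups.items()}
        assert anova_oneway_tukey(shifted).f_statistic == pytest.approx(res.f_statistic)
        assert anova_oneway_tukey(scaled).f_statistic == pytest.approx(res.f_statistic)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            anova_oneway_tukey({"a": [1.0], "b": [1, 2]})

    def test_zero_within_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            anova_oneway_tukey({"a": [1, 1], "b": [2, 2]})


class TestSummarizeGroups:
    def test_single_embryo_group_no_anova(self):
        clock = StageClock(s0=0.0, somites_per_hour=2.0)  # [0,2) = 1 h
        table = table_with_onsets([10, 20, 30, 40, 50])
        summaries, anova = summarize_groups({"wt": [table]}, clock, 0.0, 2.0)
        assert summaries["wt"].n == 1
        assert summaries["wt"].mean_rate == pytest.approx(5.0)
        assert anova is None

    def test_identical_groups_give_degenerate_or_f_zero(self):
        clock = StageClock(s0=0.0, somites_per_hour=2.0)
        t1 = table_with_onsets([10, 20, 30])
        t2 = table_with_onsets([15, 25, 35, 45])
        summaries, anova = summarize_groups(
            {"g1": [t1, t2], "g2": [t1, t2]}, clock, 0.0, 2.0
        )
        assert summaries["g1"].mean_rate == summaries["g2"].mean_rate
        assert anova is not None
        assert anova.f_statistic == pytest.approx(0.0)
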