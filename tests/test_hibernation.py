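import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hiberlitter.hibernation import (
    detect_torpor_bouts,
    exclude_isolated_bouts,
    phenology_table,
    summarize_hibernation,
)
from hiberlitter.trace_io import ValidationError

from conftest import brute_force_bouts


class TestDetectTorporBouts:
    def test_all_euthermic_no_bouts(self, make_trace):
        assert detect_torpor_bouts(make_trace([37.0] * 50)) == []

    def test_twelve_cold_samples_is_27h_bout(self, winter_trace):
        bouts = detect_torpor_bouts(winter_trace)
        assert len(bouts) == 1
        assert bouts[0].duration == pytest.approx(27.0)  # 12 x 135 min
        assert bouts[0].n_samples == 12
        assert bouts[0].min_temperature == 12.0

    def test_ten_cold_samples_too_short(self, make_trace):
        # 10 x 135 min = 22.5 h < 24 h
        trace = make_trace([37.0] * 5 + [12.0] * 10 + [37.0] * 5)
        assert detect_torpor_bouts(trace) == []

    def test_eleven_samples_is_minimal_bout(self, make_trace):
        # 11 x 135 min = 1485 min >= 1440 min
        trace = make_trace([37.0] * 5 + [12.0] * 11 + [37.0] * 5)
        bouts = detect_torpor_bouts(trace)
        assert len(bouts) == 1
        assert bouts[0].duration == pytest.approx(24.75)

    def test_sample_exactly_at_threshold_is_euthermic(self, make_trace):
        trace = make_trace([37.0] * 5 + [30.0] * 20 + [37.0] * 5)
        assert detect_torpor_bouts(trace, threshold=30.0) == []

    def test_single_warm_sample_splits_runs(self, make_trace):
        trace = make_trace([12.0] * 12 + [37.0] + [12.0] * 12)
        bouts = detect_torpor_bouts(trace)
        assert len(bouts) == 2
        assert [b.n_samples for b in bouts] == [12, 12]

    def test_gap_terminates_run(self, make_trace):
        temps = [12.0] * 12 + [np.nan] + [12.0] * 12
        bouts = detect_torpor_bouts(make_trace(temps))
        assert len(bouts) == 2

    def test_gap_never_fabricates_torpor(self, make_trace):
        # two sub-24h cold runs separated by a gap must not merge into a bout
        temps = [12.0] * 6 + [np.nan] + [12.0] * 6
        assert detect_torpor_bouts(make_trace(temps)) == []

    @given(
        st.lists(
            st.one_of(
                st.floats(min_value=5.0, max_value=40.0),
                st.just(float("nan")),
            ),
            min_size=1,
            max_size=300,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_enumerator(self, temps):
        import hiberlitter.trace_io as tio

        trace = tio.TemperatureTrace(
            "x", pd.Timestamp("2021-10-19"), np.asarray(temps), sampling_period=135.0
        )
        got = [(b.start_index, b.end_index) for b in detect_torpor_bouts(trace)]
        assert got == brute_force_bouts(np.asarray(temps))

    def test_monotonic_in_min_duration_and_threshold(self, make_trace):
        rng = np.random.default_rng(42)
        temps = rng.uniform(5, 40, size=500)
        trace = make_trace(temps)
        loose = {(b.start_index, b.end_index) for b in detect_torpor_bouts(trace, min_duration=12)}
        strict = {(b.start_index, b.end_index) for b in detect_torpor_bouts(trace, min_duration=24)}
        assert strict <= loose  # lowering min_duration never removes a bout
        total = lambda th: sum(b.duration for b in detect_torpor_bouts(trace, threshold=th))
        assert total(32.0) >= total(30.0)  # raising threshold never shortens torpor


class TestExcludeIsolatedBouts:
    def _bout(self, make_trace, start_day, n_days):
        # helper: fabricate a bout via detection on a positioned cold run
        samples_per_day = 1440 / 135
        n = int(200 * samples_per_day)
        temps = np.full(n, 37.0)
        s = int(start_day * samples_per_day)
        e = s + int(n_days * samples_per_day)
        temps[s:e] = 12.0
        return detect_torpor_bouts(make_trace(temps))[0]

    def test_single_bout_retained(self, make_trace):
        b = self._bout(make_trace, 10, 3)
        retained, excluded = exclude_isolated_bouts([b])
        assert retained == [b] and excluded == []

    @pytest.mark.parametrize("gap_days,expect_excluded", [(10, 0), (14, 0), (15, 0), (16, 1), (19, 1)])
    def test_gap_rule(self, make_trace, gap_days, expect_excluded):
        b1 = self._bout(make_trace, 10, 3)
        b2 = self._bout(make_trace, 10 + 3 + gap_days, 3)
        retained, excluded = exclude_isolated_bouts([b1, b2], max_gap=15.0)
        assert len(excluded) == expect_excluded
        assert len(retained) + len(excluded) == 2

    def test_chain_breaks_once(self, make_trace):
        # third bout close to second, but second already excluded -> both out
        b1 = self._bout(make_trace, 5, 3)
        b2 = self._bout(make_trace, 40, 3)  # 32-day gap -> excluded
        b3 = self._bout(make_trace, 45, 3)  # close to b2 but chain broken
        retained, excluded = exclude_isolated_bouts([b1, b2, b3])
        assert retained == [b1]
        assert excluded == [b2, b3]

    def test_idempotent(self, make_trace):
        bouts = [self._bout(make_trace, d, 3) for d in (5, 12, 60)]
        retained, _ = exclude_isolated_bouts(bouts)
        again, excluded = exclude_isolated_bouts(retained)
        assert again == retained and excluded == []

    def test_empty_input(self):
        assert exclude_isolated_bouts([]) == ([], [])


class TestSummarize:
    def test_no_bouts(self):
        s = summarize_hibernation("h1", [], excluded_count=1)
        assert not s.did_hibernate
        assert s.total_torpor == 0.0
        assert s.hibernation_start is None
        assert s.excluded_bouts == 1

    def test_additivity_and_duration(self, make_trace):
        temps = [37.0] * 10 + [12.0] * 12 + [37.0] * 30 + [12.0] * 22 + [37.0] * 10
        bouts = detect_torpor_bouts(make_trace(temps))
        s = summarize_hibernation("h1", bouts)
        assert s.n_bouts == 2
        assert s.total_torpor == pytest.approx(27.0 + 49.5)
        assert s.hibernation_duration >= s.total_torpor / 24.0

    def test_calendar_span_oct_to_march(self, make_trace):
        # bouts spanning 23 Oct 2021 .. 14 Mar 2022 -> ~142 days
        samples_per_day = 1440 / 135
        n = int(160 * samples_per_day)
        temps = np.full(n, 37.0)
        day0 = pd.Timestamp("2021-10-19")
        s1 = int((pd.Timestamp("2021-10-23") - day0).days * samples_per_day)
        temps[s1 : s1 + 20] = 12.0
        s2 = int((pd.Timestamp("2022-03-12") - day0).days * samples_per_day)
        temps[s2 : s2 + int(2 * samples_per_day)] = 12.0
        bouts = detect_torpor_bouts(make_trace(temps, start=str(day0.date())))
        s = summarize_hibernation("h1", bouts)
        assert abs((s.hibernation_start - pd.Timestamp("2021-10-23")).days) <= 1
        assert abs((s.hibernation_end - pd.Timestamp("2022-03-14")).days) <= 1
        assert s.hibernation_duration == pytest.approx(142, abs=1)


class TestPhenologyTable:
    def test_single_animal_group_mean_is_animal(self, make_trace):
        temps = [37.0] * 10 + [12.0] * 12 + [37.0] * 10
        s = summarize_hibernation("h1", detect_torpor_bouts(make_trace(temps)))
        animals, groups = phenology_table([s], {"h1": "W"})
        assert groups.loc[0, "total_torpor_h_mean"] == pytest.approx(27.0)

    def test_two_animal_sem(self):
        s1 = summarize_hibernation("a", [])
        s2 = summarize_hibernation("b", [])
        s1.total_torpor, s1.n_bouts, s1.did_hibernate = 100.0, 1, True
        s2.total_torpor, s2.n_bouts, s2.did_hibernate = 200.0, 1, True
        animals, groups = phenology_table([s1, s2], {"a": "W", "b": "W"})
        assert groups.loc[0, "total_torpor_h_mean"] == pytest.approx(150.0)
        assert groups.loc[0, "total_torpor_h_sem"] == pytest.approx(50.0)
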