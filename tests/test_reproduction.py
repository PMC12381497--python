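from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from hiberlitter.reproduction import (
    DailyMeanSeries,
    ParturitionEvent,
    apply_removal_rule,
    assign_pups,
    daily_means,
    detect_parturitions,
    fit_growth_models,
    flag_certain_first_litter,
    growth_points,
    infer_birth_date,
    litter_table,
    season_mass,
)
from hiberlitter.trace_io import CaptureEvent, ValidationError


def _series(means, start="2022-04-19"):
    d0 = date.fromisoformat(start)
    return DailyMeanSeries(
        "f1", [d0 + timedelta(days=i) for i in range(len(means))], np.asarray(means, float)
    )


def _capture(pup, day, mass, sex="female", mother="f1", group="WS"):
    return CaptureEvent(pup, date.fromisoformat(day), mass, sex, mother, group)


class TestDailyMeans:
    def test_constant_trace(self, make_trace):
        s = daily_means(make_trace([37.0] * 64))
        assert np.allclose(s.mean_temps, 37.0)

    def test_alternating_symmetric(self, make_trace):
        # 144-min sampling: exactly 10 samples/day, so alternation cancels
        s = daily_means(make_trace([36.0, 38.0] * 20, period=144.0))
        assert np.allclose(s.mean_temps, 37.0, atol=1e-9)

    def test_undersampled_day_omitted(self, make_trace):
        temps = np.full(32, 37.0)
        temps[11:21] = np.nan  # second day keeps ~1 of its ~10-11 samples
        s = daily_means(make_trace(temps))
        # the gutted day is dropped; surrounding days survive
        assert len(s.dates) < len(set(d for d in daily_means(make_trace(np.full(32, 37.0))).dates))


class TestDetectParturitions:
    def test_flat_series_no_events(self):
        assert detect_parturitions(_series([36.0] * 60)) == []

    def test_single_step_detected_on_jump_day(self):
        means = [36.0] * 20 + [37.2] * 20
        events = detect_parturitions(_series(means))
        assert len(events) == 1
        ev = events[0]
        assert ev.date == date.fromisoformat("2022-04-19") + timedelta(days=20)
        assert ev.jump_magnitude == pytest.approx(1.2)
        assert ev.litter_number == 1

    def test_previous_day_differencing_mode(self):
        means = [36.0] * 10 + [37.2] * 10
        events = detect_parturitions(_series(means), pre_window=1, post_window=1)
        assert len(events) == 1
        assert events[0].jump_magnitude == pytest.approx(1.2)

    def test_two_jumps_numbered_sequentially(self):
        means = [36.0] * 20 + [37.2] * 12 + [36.0] * 18 + [37.2] * 12
        events = detect_parturitions(_series(means))
        assert [e.litter_number for e in events] == [1, 2]
        assert (events[1].date - events[0].date).days == 30

    def test_refractory_suppresses_nearby_candidates(self):
        # double step within 10 days: only the larger contrast survives
        means = [36.0] * 20 + [37.1] * 10 + [38.4] * 20
        events = detect_parturitions(_series(means), refractory=18)
        assert len(events) == 1

    def test_too_short_series_raises(self):
        with pytest.raises(ValidationError):
            detect_parturitions(_series([36.0]))


class TestCertainFirstLitter:
    def _parts(self, *dates_):
        return {
            "f1": [
                ParturitionEvent("f1", date.fromisoformat(d), i + 1, 1.2)
                for i, d in enumerate(dates_)
            ]
        }

    def test_single_litter_all_certain(self):
        flags = flag_certain_first_litter(
            [_capture("p1", "2022-08-01", 60.0)], self._parts("2022-05-24")
        )
        assert flags == {"p1": True}

    def test_captured_before_second_emergence_certain(self):
        # second parturition 23 Jun; captured 10 d later < 18-d emergence age
        flags = flag_certain_first_litter(
            [_capture("p1", "2022-07-03", 60.0)], self._parts("2022-05-24", "2022-06-23")
        )
        assert flags["p1"] is True

    def test_captured_later_uncertain(self):
        flags = flag_certain_first_litter(
            [_capture("p1", "2022-07-18", 60.0)], self._parts("2022-05-24", "2022-06-23")
        )
        assert flags["p1"] is False


class TestGrowthModels:
    def test_noiseless_line_exact(self):
        rows = []
        for pup in range(3):
            for age in (20, 30, 40, 50):
                rows.append(
                    {"pup_id": f"p{pup}", "group": "WS", "sex": "female",
                     "age_d": age, "mass_g": 10.0 + 2.0 * age}
                )
        models = fit_growth_models(pd.DataFrame(rows))
        m = models[("WS", "female")]
        assert m.slope == pytest.approx(2.0)
        assert m.intercept == pytest.approx(10.0)
        assert m.r_squared == pytest.approx(1.0)

    def test_noisy_slope_within_bounds(self):
        rng = np.random.default_rng(11)
        rows = []
        for pup in range(200):
            age = rng.uniform(18, 60)
            rows.append(
                {"pup_id": f"p{pup}", "group": "WS", "sex": "female",
                 "age_d": age, "mass_g": 10.0 + 2.0 * age + rng.normal(0, 5)}
            )
        m = fit_growth_models(pd.DataFrame(rows))[("WS", "female")]
        assert 1.9 <= m.slope <= 2.1

    def test_single_capture_per_pup_matches_pooled_oracle(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(20, 60, 50)
        masses = 10 + 2.0 * ages + rng.normal(0, 5, 50)
        rows = [
            {"pup_id": f"p{i}", "group": "W", "sex": "male", "age_d": a, "mass_g": m}
            for i, (a, m) in enumerate(zip(ages, masses))
        ]
        m = fit_growth_models(pd.DataFrame(rows), trim_sd=None)[("W", "male")]
        slope_oracle, intercept_oracle = np.polyfit(ages, masses, 1)
        assert m.slope == pytest.approx(slope_oracle)
        assert m.intercept == pytest.approx(intercept_oracle)

    def test_underpopulated_stratum_falls_back_with_warning(self):
        rows = [
            {"pup_id": "p1", "group": "W", "sex": "male", "age_d": 20, "mass_g": 50},
            {"pup_id": "p2", "group": "W", "sex": "female", "age_d": 30, "mass_g": 70},
            {"pup_id": "p3", "group": "W", "sex": "female", "age_d": 40, "mass_g": 90},
        ]
        with pytest.warns(UserWarning, match="under-populated"):
            models = fit_growth_models(pd.DataFrame(rows))
        assert models[("W", "male")].n_pups == 3  # pooled group fit

    def test_trimming_resists_misdated_litter(self):
        rng = np.random.default_rng(8)
        rows = []
        for pup in range(40):
            for age in (20, 35, 50):
                rows.append(
                    {"pup_id": f"p{pup}", "group": "RF", "sex": "female",
                     "age_d": age, "mass_g": 10 + 3.0 * age + rng.normal(0, 5)}
                )
        # 6 pups with birth dates wrong by 30 days: masses lag the line by 90 g
        for pup in range(6):
            for age in (50, 65, 80):
                rows.append(
                    {"pup_id": f"bad{pup}", "group": "RF", "sex": "female",
                     "age_d": age, "mass_g": 10 + 3.0 * (age - 30) + rng.normal(0, 5)}
                )
        m = fit_growth_models(pd.DataFrame(rows))[("RF", "female")]
        assert m.slope == pytest.approx(3.0, rel=0.05)


class TestInferBirthDate:
    MODEL = None

    def _model(self):
        rows = [
            {"pup_id": "p1", "group": "WS", "sex": "female", "age_d": a, "mass_g": 10 + 2 * a}
            for a in (20, 30, 40)
        ] + [
            {"pup_id": "p2", "group": "WS", "sex": "female", "age_d": a, "mass_g": 10 + 2 * a}
            for a in (25, 35)
        ]
        return fit_growth_models(pd.DataFrame(rows))[("WS", "female")]

    def test_mass_at_intercept_is_capture_day(self):
        m = self._model()
        cap = _capture("p1", "2022-06-15", 10.0)
        assert infer_birth_date(cap, m) == cap.date

    def test_back_projection(self):
        m = self._model()
        cap = _capture("p1", "2022-06-15", 50.0)  # age 20
        assert infer_birth_date(cap, m) == cap.date - timedelta(days=20)

    def test_rounding_to_nearest_day(self):
        m = self._model()
        cap = _capture("p1", "2022-06-15", 50.9)  # age 20.45 -> 20
        assert infer_birth_date(cap, m) == cap.date - timedelta(days=20)

    def test_mass_below_intercept_clamps_with_warning(self):
        m = self._model()
        cap = _capture("p1", "2022-06-15", 5.0)
        with pytest.warns(UserWarning, match="clamping"):
            assert infer_birth_date(cap, m) == cap.date


class TestAssignPups:
    PARTS = {
        "f1": [
            ParturitionEvent("f1", date(2022, 5, 24), 1, 1.2),
            ParturitionEvent("f1", date(2022, 6, 23), 2, 1.1),
        ]
    }

    def test_single_parturition_always_assigned(self):
        parts = {"f1": [ParturitionEvent("f1", date(2022, 5, 24), 1, 1.2)]}
        [a] = assign_pups({"p1": ("f1", date(2022, 8, 1))}, parts)
        assert a.assigned_parturition_date == date(2022, 5, 24)
        assert a.discrepancy == 69

    def test_nearest_parturition_wins(self):
        [a] = assign_pups({"p1": ("f1", date(2022, 6, 5))}, self.PARTS)
        assert a.assigned_parturition_date == date(2022, 5, 24)  # 12 d < 18 d

    def test_tie_goes_to_earlier_litter(self):
        midpoint = date(2022, 6, 8)  # 15 d from both
        [a] = assign_pups({"p1": ("f1", midpoint)}, self.PARTS)
        assert a.assigned_litter_number == 1

    def test_no_pup_assigned_twice(self):
        inferred = {f"p{i}": ("f1", date(2022, 6, 1) + timedelta(days=3 * i)) for i in range(10)}
        assignments = assign_pups(inferred, self.PARTS)
        assert len({a.pup_id for a in assignments}) == 10


class TestLitterTable:
    def test_zero_pup_litter_counted(self):
        parts = {
            "f1": [
                ParturitionEvent("f1", date(2022, 5, 24), 1, 1.2),
                ParturitionEvent("f1", date(2022, 6, 23), 2, 1.1),
            ]
        }
        assignments = assign_pups(
            {"p1": ("f1", date(2022, 5, 25)), "p2": ("f1", date(2022, 5, 23))}, parts
        )
        records, metrics = litter_table(assignments, parts)
        assert len(records) == 2
        first, second = sorted(records, key=lambda r: r.litter_number)
        assert first.n_pups_assigned == 2 and first.successful
        assert second.n_pups_assigned == 0 and not second.successful
        assert metrics["interlitter_intervals_d"] == [30]
        assert metrics["pups_per_female"]["f1"] == 2

    def test_sex_ratio(self):
        parts = {"f1": [ParturitionEvent("f1", date(2022, 5, 24), 1, 1.2)]}
        inferred = {f"p{i}": ("f1", date(2022, 5, 24)) for i in range(10)}
        assignments = assign_pups(inferred, parts)
        sexes = {f"p{i}": ("male" if i < 5 else "female") for i in range(10)}
        _, metrics = litter_table(assignments, parts, sexes)
        assert metrics["sex_ratio_male_pct"] == pytest.approx(50.0)


class TestSeasonMassAndRemoval:
    WINDOW = (date(2022, 4, 19), date(2022, 10, 19))

    def test_single_capture_mean(self):
        animals, _ = season_mass([_capture("a1", "2022-06-01", 250.0)], self.WINDOW)
        assert animals.loc[0, "mean_mass_g"] == 250.0

    def test_group_mean_and_sem(self):
        caps = [
            _capture("a1", "2022-06-01", 290.0, group="RF"),
            _capture("a2", "2022-06-01", 310.0, group="RF"),
        ]
        _, groups = season_mass(caps, self.WINDOW)
        assert groups.loc[0, "mass_mean_g"] == pytest.approx(300.0)
        assert groups.loc[0, "mass_sem_g"] == pytest.approx(10.0)

    def test_removal_strictly_above_cutoff(self):
        caps = [
            _capture("p1", "2022-06-01", 120.0),
            _capture("p1", "2022-06-08", 140.0),  # exactly 140: stays
            _capture("p1", "2022-06-15", 145.0),  # removed here
            _capture("p1", "2022-06-22", 150.0),  # suppressed
        ]
        censor, kept = apply_removal_rule(caps, cutoff=140.0)
        assert censor["p1"] == date(2022, 6, 15)
        assert [c.date.day for c in kept] == [1, 8, 15]

    def test_never_exceeding_never_censored(self):
        caps = [_capture("p1", "2022-06-01", 120.0), _capture("p1", "2022-06-08", 130.0)]
        censor, kept = apply_removal_rule(caps)
        assert censor == {} and len(kept) == 2
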