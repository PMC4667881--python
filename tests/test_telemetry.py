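"""Data model, CSV round-trips, phase splitting and pooling."""

from __future__ import annotations

from datetime import date, time as dtime

import numpy as np
import pandas as pd
import pytest

import thermoloco as tl
from thermoloco.telemetry import TelemetryFormatError

from conftest import make_series


def constant_day_series(n_days=1, start="2015-01-05 06:00", **kwargs):
    n = n_days * 1440
    return make_series(np.full(n, 37.0), np.zeros(n), start=start, **kwargs)


class TestTelemetrySeries:
    def test_validation_rejects_mismatched_lengths(self):
        with pytest.raises(ValueError, match="equal length"):
            make_series([37.0, 37.1], [0.0])

    def test_validation_rejects_out_of_range_temperature(self):
        with pytest.raises(ValueError, match="physiological range"):
            make_series([37.0, 50.0])

    def test_validation_rejects_non_integer_activity(self):
        with pytest.raises(ValueError, match="non-negative integers"):
            make_series([37.0, 37.0], [0.0, 1.5])

    def test_event_outside_span_rejected(self):
        ev = tl.EventRecord(time=pd.Timestamp("2015-01-06 12:00"), kind="handling")
        with pytest.raises(ValueError, match="outside"):
            make_series([37.0] * 10, events=[ev])


class TestCsvRoundTrip:
    def test_round_trip_preserves_values_and_missing(self, tmp_path):
        cfg = tl.SyntheticConfig(
            n_animals_per_group=1,
            n_days=2,
            seed=3,
            events=[tl.EventSpec(day=1, time=dtime(10, 0), kind="handling")],
        )
        cohort = tl.simulate_cohort(cfg)
        # punch holes in both signals to exercise the missing-value policy
        cohort[0].temperature[100:103] = np.nan
        cohort[0].activity[200] = np.nan
        tl.write_telemetry_csv(cohort, tmp_path / "t.csv")
        tl.write_events_csv(cohort, tmp_path / "e.csv")
        back = tl.read_telemetry_csv(tmp_path / "t.csv", tmp_path / "e.csv")
        assert len(back) == len(cohort)
        for orig, rt in zip(sorted(cohort, key=lambda s: s.animal_id), back):
            assert rt.animal_id == orig.animal_id and rt.group == orig.group
            np.testing.assert_allclose(rt.temperature, orig.temperature, atol=1e-9)
            np.testing.assert_array_equal(np.isnan(rt.temperature), np.isnan(orig.temperature))
            np.testing.assert_array_equal(rt.activity, orig.activity)
            assert rt.events == orig.events

    def test_two_animals_yield_two_series_of_full_length(self, tmp_path):
        cohort = [
            constant_day_series(2, animal_id="a"),
            constant_day_series(2, animal_id="b"),
        ]
        tl.write_telemetry_csv(cohort, tmp_path / "t.csv")
        back = tl.read_telemetry_csv(tmp_path / "t.csv")
        assert [s.n_samples for s in back] == [2880, 2880]

    def test_blank_cell_becomes_single_missing(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "animal_id,group,timestamp,temperature_c,activity_counts\n"
            "a,control,2015-01-05T06:00,37.0,0\n"
            "a,control,2015-01-05T06:01,,3\n"
            "a,control,2015-01-05T06:02,37.1,0\n"
        )
        (series,) = tl.read_telemetry_csv(path)
        assert int(np.isnan(series.temperature).sum()) == 1

    def test_malformed_numeric_cell_becomes_missing(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "animal_id,group,timestamp,temperature_c,activity_counts\n"
            "a,control,2015-01-05T06:00,oops,0\n"
            "a,control,2015-01-05T06:01,37.0,1\n"
        )
        (series,) = tl.read_telemetry_csv(path)
        assert np.isnan(series.temperature[0]) and series.temperature[1] == 37.0

    def test_gap_minutes_filled_with_missing(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "animal_id,group,timestamp,temperature_c,activity_counts\n"
            "a,control,2015-01-05T06:00,37.0,0\n"
            "a,control,2015-01-05T06:03,37.1,2\n"
        )
        (series,) = tl.read_telemetry_csv(path)
        assert series.n_samples == 4
        assert int(np.isnan(series.temperature).sum()) == 2

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("animal_id,group,timestamp,temperature_c\na,control,2015-01-05T06:00,37\n")
        with pytest.raises(TelemetryFormatError, match="activity_counts"):
            tl.read_telemetry_csv(path)

    def test_duplicate_timestamp_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "animal_id,group,timestamp,temperature_c,activity_counts\n"
            "a,control,2015-01-05T06:00,37.0,0\n"
            "a,control,2015-01-05T06:00,37.1,1\n"
        )
        with pytest.raises(TelemetryFormatError, match="duplicate"):
            tl.read_telemetry_csv(path)


class TestSplitPhases:
    def test_complete_day_gives_720_per_phase(self):
        recs = tl.split_phases(constant_day_series(1))
        assert [(r.phase, r.n_samples, r.partial) for r in recs] == [
            ("light", 720, False),
            ("dark", 720, False),
        ]

    def test_series_starting_at_noon_has_partial_first_window(self):
        series = constant_day_series(1, start="2015-01-05 12:00")
        recs = tl.split_phases(series)
        assert recs[0].phase == "light" and recs[0].partial and recs[0].n_samples == 360

    def test_eight_days_give_eight_recordings_per_phase(self):
        recs = tl.split_phases(constant_day_series(8))
        assert sum(r.phase == "light" for r in recs) == 8
        assert sum(r.phase == "dark" for r in recs) == 8
        assert not any(r.partial for r in recs)

    def test_phases_partition_each_complete_day(self):
        series = constant_day_series(3)
        recs = tl.split_phases(series)
        assert sum(r.n_samples for r in recs) == series.n_samples
        by_day = {}
        for r in recs:
            by_day.setdefault(r.date, 0)
            by_day[r.date] += r.n_samples
        assert all(total == 1440 for total in by_day.values())

    def test_dark_phase_attributed_to_day_of_its_start(self):
        recs = tl.split_phases(constant_day_series(1))
        dark = next(r for r in recs if r.phase == "dark")
        assert dark.date == date(2015, 1, 5)

    def test_intervention_marks_both_phases_of_the_day_disturbed(self):
        ev = tl.EventRecord(time=pd.Timestamp("2015-01-05 08:45"), kind="injection")
        recs = tl.split_phases(constant_day_series(2, events=[ev]))
        by = {(r.date, r.phase): r.condition for r in recs}
        assert by[(date(2015, 1, 5), "light")] == "disturbed"
        assert by[(date(2015, 1, 5), "dark")] == "disturbed"
        assert by[(date(2015, 1, 6), "light")] == "undisturbed"

    def test_window_scoped_disturbance_policy(self):
        ev = tl.EventRecord(time=pd.Timestamp("2015-01-05 08:45"), kind="injection")
        recs = tl.split_phases(constant_day_series(1, events=[ev]), disturb_whole_day=False)
        by = {r.phase: r.condition for r in recs}
        assert by["light"] == "disturbed" and by["dark"] == "undisturbed"

    def test_lights_events_do_not_disturb(self):
        ev = tl.EventRecord(time=pd.Timestamp("2015-01-05 06:00"), kind="lights_on")
        recs = tl.split_phases(constant_day_series(1, events=[ev]))
        assert all(r.condition == "undisturbed" for r in recs)

    def test_equal_clock_times_rejected(self):
        with pytest.raises(ValueError):
            tl.split_phases(constant_day_series(1), dtime(6), dtime(6))


class TestPooling:
    def test_pooling_is_an_idempotent_pure_filter(self):
        recs = tl.split_phases(constant_day_series(4))
        pooled = tl.pool_recordings(recs, "light", "undisturbed")
        assert tl.pool_recordings(pooled, "light", "undisturbed") == pooled
        assert len(pooled) == 4

    def test_empty_filter_result_is_empty_not_error(self):
        recs = tl.split_phases(constant_day_series(2))
        assert tl.pool_recordings(recs, "dark", "disturbed") == []

    def test_partial_windows_excluded_by_default(self):
        recs = tl.split_phases(constant_day_series(1, start="2015-01-05 12:00"))
        pooled = tl.pool_recordings(recs, "light", "undisturbed")
        assert all(not r.partial for r in pooled)

    def test_high_missingness_recording_dropped(self):
        series = constant_day_series(1)
        series.temperature[:100] = np.nan  # ~14% of the light phase
        recs = tl.split_phases(series)
        pooled = tl.pool_recordings(recs, "light", "undisturbed")
        assert pooled == []
        kept = tl.pool_recordings(recs, "light", "undisturbed", max_missing_frac=0.2)
        assert len(kept) == 1

    def test_duplicate_recordings_rejected(self):
        recs = tl.split_phases(constant_day_series(1))
        with pytest.raises(ValueError, match="duplicate"):
            tl.pool_recordings(recs + recs, "light", "undisturbed")
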