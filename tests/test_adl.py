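"""Hand-traced fixtures for the seven ADL inference rules."""

import numpy as np
import pandas as pd
import pytest

from adlhome.adl import (
    detect_appliance_use,
    detect_chores,
    detect_cooking,
    detect_grooming,
    detect_medication,
    detect_outings,
    detect_wandering,
)
from adlhome.preprocess import UseEpisode


def ep(channel, start, end, kind="tilt_use"):
    return UseEpisode(channel, pd.Timestamp(start), pd.Timestamp(end), kind)


@pytest.fixture
def hh(household):
    return household


class TestCooking:
    def test_fridge_sink_stove_is_breakfast_cooking(self, hh):
        kitchen = {
            hh.role("refrigerator"): [ep("v1", "2021-03-01T08:00:00", "2021-03-01T08:00:40")],
            hh.role("kitchen_sink"): [ep("v3", "2021-03-01T08:03:00", "2021-03-01T08:04:00")],
        }
        rises = [ep("t1", "2021-03-01T08:05:00", "2021-03-01T08:20:00", "temp_rise")]
        out = detect_cooking(kitchen, rises, hh)
        assert len(out) == 1
        assert out[0].adl_type == "cooking"
        assert "breakfast" in out[0].tags
        assert "pair_fridge_sink" in out[0].tags

    def test_microwave_only_is_heating_food(self, hh):
        kitchen = {hh.role("microwave_door"): [ep("d2", "2021-03-01T12:10:00", "2021-03-01T12:12:00", "door_open")]}
        out = detect_cooking(kitchen, [], hh)
        assert [e.adl_type for e in out] == ["heating_food"]

    def test_stove_alone_is_nothing(self, hh):
        rises = [ep("t1", "2021-03-01T18:00:00", "2021-03-01T18:20:00", "temp_rise")]
        assert detect_cooking({}, rises, hh) == []

    def test_one_appliance_plus_stove_fails_two_appliance_rule(self, hh):
        kitchen = {hh.role("refrigerator"): [ep("v1", "2021-03-01T18:00:00", "2021-03-01T18:01:00")]}
        rises = [ep("t1", "2021-03-01T18:02:00", "2021-03-01T18:20:00", "temp_rise")]
        assert detect_cooking(kitchen, rises, hh) == []

    def test_long_cooking_tagged_over_30min(self, hh):
        kitchen = {
            hh.role("refrigerator"): [ep("v1", "2021-03-01T17:00:00", "2021-03-01T17:01:00")],
            hh.role("rice_cooker"): [ep("v2", "2021-03-01T17:05:00", "2021-03-01T17:06:00")],
        }
        rises = [ep("t1", "2021-03-01T17:02:00", "2021-03-01T17:45:00", "temp_rise")]
        out = detect_cooking(kitchen, rises, hh)
        assert len(out) == 1
        assert {"dinner", "over_30min"} <= out[0].tags

    def test_cooking_count_never_exceeds_stove_rises(self, hh, small_cohort_tables):
        raw, _, _, _ = small_cohort_tables
        stove = hh.role("stove_temp")
        per_person = raw.groupby("person_id")[["adl_count_cooking", f"iot_count_{stove}"]].sum()
        assert (per_person["adl_count_cooking"] <= per_person[f"iot_count_{stove}"]).all()


class TestMedication:
    def test_morning_use_tagged(self, hh):
        out = detect_medication([ep("v4", "2021-03-01T08:00:00", "2021-03-01T08:01:00")])
        assert len(out) == 1
        assert "morning" in out[0].tags

    def test_use_between_windows_untagged(self, hh):
        out = detect_medication([ep("v4", "2021-03-01T11:00:00", "2021-03-01T11:01:00")])
        assert len(out) == 1
        assert out[0].tags == set()

    def test_no_uses_no_episodes(self):
        assert detect_medication([]) == []


class TestApplianceUse:
    def test_evening_tv_has_no_window_tags(self, hh):
        plugs = {hh.role("tv_plug"): [ep("p1", "2021-03-01T20:00:00", "2021-03-01T21:30:00", "plug_on")]}
        out = detect_appliance_use(plugs, {}, hh)
        assert len(out) == 1
        assert out[0].tags == {"tv"}

    def test_tv_0300_0500_overlaps_night_window(self, hh):
        plugs = {hh.role("tv_plug"): [ep("p1", "2021-03-01T03:00:00", "2021-03-01T05:00:00", "plug_on")]}
        out = detect_appliance_use(plugs, {}, hh)
        assert "tv_night" in out[0].tags  # overlap rule: 03-04 falls in 00-04
        assert "tv_morning" in out[0].tags  # 04-05 falls in 04-12

    def test_empty_input(self, hh):
        assert detect_appliance_use({}, {}, hh) == []

    def test_fan_vibration_counts_as_appliance_use(self, hh):
        vib = {hh.role("fan"): [ep("v8", "2021-03-01T14:00:00", "2021-03-01T14:30:00")]}
        out = detect_appliance_use({}, vib, hh)
        assert len(out) == 1
        assert "fan" in out[0].tags


def _stamps(*times):
    return pd.DatetimeIndex(pd.to_datetime(list(times)))


class TestOutings:
    def test_clean_outing_lock_ok(self, hh):
        outs = detect_outings(
            _stamps("2021-03-01T10:00:00", "2021-03-01T12:00:00"),
            _stamps("2021-03-01T09:55:00", "2021-03-01T12:01:00"),
            {},
            hh,
        )
        assert len(outs) == 1
        assert outs[0].lock_ok
        assert outs[0].appliances_left_on == frozenset()

    def test_tv_left_on_fails_lock(self, hh):
        plugs = {hh.role("tv_plug"): [ep("p1", "2021-03-01T09:00:00", "2021-03-01T13:00:00", "plug_on")]}
        outs = detect_outings(
            _stamps("2021-03-01T10:00:00", "2021-03-01T12:00:00"),
            _stamps("2021-03-01T09:55:00", "2021-03-01T12:01:00"),
            plugs,
            hh,
        )
        assert len(outs) == 1
        assert not outs[0].lock_ok
        assert outs[0].appliances_left_on == frozenset({hh.role("tv_plug")})

    def test_interior_motion_breaks_the_quiet_gap(self, hh):
        outs = detect_outings(
            _stamps("2021-03-01T10:00:00", "2021-03-01T12:00:00"),
            _stamps("2021-03-01T10:01:00", "2021-03-01T12:01:00"),
            {},
            hh,
        )
        assert outs == []

    def test_tv_within_30min_of_return_flagged(self, hh):
        plugs = {hh.role("tv_plug"): [ep("p1", "2021-03-01T12:10:00", "2021-03-01T13:00:00", "plug_on")]}
        outs = detect_outings(
            _stamps("2021-03-01T10:00:00", "2021-03-01T12:00:00"),
            _stamps("2021-03-01T09:55:00", "2021-03-01T12:01:00"),
            plugs,
            hh,
        )
        assert len(outs) == 1
        assert outs[0].tv_after_return


class TestChores:
    def test_45s_sink_is_dishes(self):
        out = detect_chores([ep("v3", "2021-03-01T19:00:00", "2021-03-01T19:00:45")], [])
        assert len(out) == 1
        assert "dishes" in out[0].tags

    def test_20s_sink_below_threshold(self):
        assert detect_chores([ep("v3", "2021-03-01T19:00:00", "2021-03-01T19:00:20")], []) == []

    def test_washer_interval_is_laundering(self):
        out = detect_chores([], [ep("p3", "2021-03-01T10:00:00", "2021-03-01T10:40:00", "plug_on")])
        assert len(out) == 1
        assert "laundering" in out[0].tags

    def test_dishes_threshold_monotonicity(self):
        sink = [
            ep("v3", "2021-03-01T09:00:00", "2021-03-01T09:00:31"),
            ep("v3", "2021-03-01T12:00:00", "2021-03-01T12:01:30"),
            ep("v3", "2021-03-01T19:00:00", "2021-03-01T19:04:00"),
        ]
        counts = [
            sum("dishes" in e.tags for e in detect_chores(sink, [], dishes_min_s=t))
            for t in (30.0, 60.0, 120.0, 300.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestGrooming:
    def test_shower_episode(self):
        out = detect_grooming([], [ep("v6", "2021-03-01T07:00:00", "2021-03-01T07:10:00")], [])
        assert len(out) == 1
        assert "shower" in out[0].tags

    def test_90s_basin_gets_over_1min_tag(self):
        out = detect_grooming([ep("v5", "2021-03-01T07:00:00", "2021-03-01T07:01:30")], [], [])
        assert "over_1min" in out[0].tags

    def test_0200_basin_gets_nighttime_tag(self):
        out = detect_grooming([ep("v5", "2021-03-01T02:00:00", "2021-03-01T02:00:30")], [], [])
        assert "nighttime" in out[0].tags
        assert "over_1min" not in out[0].tags


class TestWandering:
    def _grid(self):
        return pd.date_range("2021-03-01", periods=24, freq="1h"), pd.Timedelta("1h")

    def test_silent_night_counts_zero(self, hh):
        grid, width = self._grid()
        w = detect_wandering(pd.DataFrame(), pd.DataFrame(), grid, width, hh)
        assert w["night_events"].sum() == 0

    def test_six_zone_changes_in_one_hour(self, hh):
        grid, width = self._grid()
        # alternate living room <-> kitchen: 6 boundary crossings of zone 2
        rows = []
        t = pd.Timestamp("2021-03-01T10:00:00")
        for i in range(7):
            z = 2 if i % 2 == 0 else 4
            rows.append({"zone_id": z, "start": t, "end": t + pd.Timedelta(minutes=7)})
            t += pd.Timedelta(minutes=8)
        visits = pd.DataFrame(rows)
        w = detect_wandering(visits, pd.DataFrame(), grid, width, hh)
        assert w["room_transitions"].sum() == 6

    def test_three_hour_stay_spans_bins(self, hh):
        grid, width = self._grid()
        visits = pd.DataFrame(
            [{"zone_id": 2, "start": pd.Timestamp("2021-03-01T13:00:00"), "end": pd.Timestamp("2021-03-01T16:00:00")}]
        )
        w = detect_wandering(visits, pd.DataFrame(), grid, width, hh)
        assert w["zone2_visits"].sum() == 1
        assert w["zone2_stay_s"].sum() == pytest.approx(3 * 3600)
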