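"""Per-sensor conversions: tilt uses, plug intervals, temperature rises,
binning arithmetic, lidar kinematics and zone visits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adlhome.household import reference_zone_map
from adlhome.preprocess import (
    bin_counts_durations,
    lidar_kinematics,
    plug_on_intervals,
    temp_rise_episodes,
    vibration_use_episodes,
    zone_visits,
)

from conftest import make_events, tilt_pair


class TestVibration:
    def test_deviate_then_restore_is_one_60s_use(self):
        ev = make_events(tilt_pair("v3", "2021-03-01T08:00:00", "2021-03-01T08:01:00"))
        eps = vibration_use_episodes(ev)
        assert len(eps) == 1
        assert eps[0].duration_s == 60.0
        assert eps[0].kind == "tilt_use"

    def test_constant_tilt_stream_has_no_uses(self):
        recs = []
        for i in range(10):
            for fld, v in (("x", 0.0), ("y", 0.0), ("z", 1.0)):
                recs.append((f"2021-03-01T08:{i:02d}:00", "v3", "vibration", fld, v))
        assert vibration_use_episodes(make_events(recs)) == []

    def test_unrestored_tilt_truncates_at_timeout(self):
        recs = []
        for fld, v in (("x", 0.8), ("y", 0.0), ("z", 0.6)):
            recs.append(("2021-03-01T08:00:00", "v3", "vibration", fld, v))
        eps = vibration_use_episodes(make_events(recs), timeout_s=600.0)
        assert len(eps) == 1
        assert eps[0].duration_s == 600.0

    def test_small_wobble_within_tolerance_ignored(self):
        # ~5 degrees off vertical: below the 10-degree tolerance
        recs = []
        for fld, v in (("x", 0.087), ("y", 0.0), ("z", 0.996)):
            recs.append(("2021-03-01T08:00:00", "v3", "vibration", fld, v))
        assert vibration_use_episodes(make_events(recs)) == []


class TestPlug:
    def test_90min_on_interval(self):
        ev = make_events(
            [
                ("2021-03-01T20:00:00", "p1", "plug", "power_w", 60.0),
                ("2021-03-01T21:30:00", "p1", "plug", "power_w", 0.0),
            ]
        )
        eps = plug_on_intervals(ev)
        assert len(eps) == 1
        assert eps[0].duration_s == 90 * 60

    def test_all_zero_power_has_no_intervals(self):
        ev = make_events(
            [(f"2021-03-01T{h:02d}:00:00", "p1", "plug", "power_w", 0.0) for h in range(6)]
        )
        assert plug_on_intervals(ev) == []

    def test_short_gap_debounced(self):
        ev = make_events(
            [
                ("2021-03-01T20:00:00", "p1", "plug", "power_w", 60.0),
                ("2021-03-01T20:10:00", "p1", "plug", "power_w", 0.0),
                ("2021-03-01T20:10:30", "p1", "plug", "power_w", 60.0),
                ("2021-03-01T20:20:00", "p1", "plug", "power_w", 0.0),
            ]
        )
        eps = plug_on_intervals(ev, debounce_s=60.0)
        assert len(eps) == 1
        assert eps[0].duration_s == 20 * 60

    def test_negative_threshold_rejected(self):
        ev = make_events([("2021-03-01T20:00:00", "p1", "plug", "power_w", 60.0)])
        with pytest.raises(ValueError):
            plug_on_intervals(ev, on_threshold_watts=-1.0)


def _temp_events(temps, t0="2021-03-01T08:00:00", cadence_s=60):
    start = pd.Timestamp(t0)
    recs = [
        (str(start + pd.Timedelta(seconds=i * cadence_s)), "t1", "temp_humidity", "temp_c", float(v))
        for i, v in enumerate(temps)
    ]
    return make_events(recs)


class TestTempRise:
    def test_flat_trace_has_no_episodes(self):
        assert temp_rise_episodes(_temp_events([22.0] * 30)) == []

    def test_single_ramp_and_decay_is_one_episode(self):
        temps = [22.0] * 10 + list(np.linspace(22, 27, 10)) + [27.0] * 10 + list(np.linspace(27, 22, 6)) + [22.0] * 5
        eps = temp_rise_episodes(_temp_events(temps), delta_c=2.0)
        assert len(eps) == 1

    def test_two_separated_ramps_are_two_episodes(self):
        ramp = list(np.linspace(22, 27, 8)) + [27.0] * 5 + list(np.linspace(27, 22, 6))
        temps = [22.0] * 12 + ramp + [22.0] * 30 + ramp + [22.0] * 12
        eps = temp_rise_episodes(_temp_events(temps), delta_c=2.0)
        assert len(eps) == 2


class TestBinning:
    def test_90min_interval_split_over_hour_bins(self):
        ev = make_events(
            [
                ("2021-03-01T20:15:00", "p1", "plug", "power_w", 60.0),
                ("2021-03-01T21:45:00", "p1", "plug", "power_w", 0.0),
            ]
        )
        eps = {"p1": plug_on_intervals(ev)}
        grid = pd.date_range("2021-03-01", periods=24, freq="1h")
        binned = bin_counts_durations(eps, None, "1h", grid)
        assert binned.durations.loc["2021-03-01 20:00", "p1"] == 45 * 60
        assert binned.durations.loc["2021-03-01 21:00", "p1"] == 45 * 60
        assert binned.counts.loc["2021-03-01 20:00", "p1"] == 1
        assert binned.counts.loc["2021-03-01 21:00", "p1"] == 0

    def test_point_events_count_only(self):
        stamps = pd.DatetimeIndex([f"2021-03-01T{h:02d}:30:00" for h in (8, 9, 9, 15, 23)])
        grid = pd.date_range("2021-03-01", periods=1, freq="1D")
        binned = bin_counts_durations({}, {"d1": stamps}, "1d", grid)
        assert binned.counts.iloc[0, 0] == 5
        assert binned.durations.iloc[0, 0] == 0.0

    def test_episode_filling_a_bin_has_full_duration(self):
        from adlhome.preprocess import UseEpisode

        ep = UseEpisode("p1", pd.Timestamp("2021-03-01T05:00:00"), pd.Timestamp("2021-03-01T06:00:00"), "plug_on")
        grid = pd.date_range("2021-03-01", periods=24, freq="1h")
        binned = bin_counts_durations({"p1": [ep]}, None, "1h", grid)
        assert binned.durations.loc["2021-03-01 05:00", "p1"] == 3600.0

    @given(
        start_min=st.integers(0, 1380),
        dur_min=st.integers(1, 300),
    )
    @settings(max_examples=50, deadline=None)
    def test_duration_conservation_and_refinement(self, start_min, dur_min):
        """Summed per-bin durations equal episode time; daily counts equal
        the sum of hourly counts, which equal the sum of 10-min counts."""
        from adlhome.preprocess import UseEpisode

        day = pd.Timestamp("2021-03-01")
        start = day + pd.Timedelta(minutes=start_min)
        end = min(start + pd.Timedelta(minutes=dur_min), day + pd.Timedelta(days=1))
        ep = {"p1": [UseEpisode("p1", start, end, "plug_on")]}
        total = (end - start).total_seconds()
        per = {}
        for width, periods in (("1d", 1), ("1h", 24), ("10min", 144)):
            grid = pd.date_range(day, periods=periods, freq=width.replace("1d", "1D"))
            b = bin_counts_durations(ep, None, width, grid)
            assert b.durations["p1"].sum() == pytest.approx(total)
            per[width] = b.counts["p1"].sum()
        assert per["1d"] == per["1h"] == per["10min"] == 1


class TestLidar:
    def test_unit_conversion_identity(self):
        track = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(["2021-03-01T08:00:00", "2021-03-01T08:00:01"]),
                "x": [0.0, 1.0],
                "y": [0.0, 0.0],
            }
        )
        gait, dist = lidar_kinematics(track, min_speed_kmh=0.0)
        assert gait["speed_kmh"].iloc[0] == pytest.approx(3.6)

    def test_stationary_track_yields_no_gait_samples(self):
        track = pd.DataFrame(
            {
                "timestamp": pd.date_range("2021-03-01T08:00:00", periods=30, freq="1s"),
                "x": 2.0,
                "y": 3.0,
            }
        )
        gait, dist = lidar_kinematics(track, min_speed_kmh=0.6)
        assert gait.empty

    def test_square_path_total_distance(self):
        # 4 m x 5 m rectangle walked at 1 m/s, sampled at 1 Hz -> 18 m
        xs, ys = [], []
        for seg in [((0, 0), (4, 0)), ((4, 0), (4, 5)), ((4, 5), (0, 5)), ((0, 5), (0, 0))]:
            (x0, y0), (x1, y1) = seg
            n = int(np.hypot(x1 - x0, y1 - y0))
            for i in range(n):
                xs.append(x0 + (x1 - x0) * i / n)
                ys.append(y0 + (y1 - y0) * i / n)
        xs.append(0.0)
        ys.append(0.0)
        track = pd.DataFrame(
            {
                "timestamp": pd.date_range("2021-03-01T08:00:00", periods=len(xs), freq="1s"),
                "x": xs,
                "y": ys,
            }
        )
        gait, dist = lidar_kinematics(track, min_speed_kmh=0.0)
        assert dist.sum() == pytest.approx(18.0)

    def test_distance_invariant_to_min_speed_and_gait_monotone(self, rng):
        t = pd.date_range("2021-03-01T09:00:00", periods=200, freq="1s")
        track = pd.DataFrame(
            {"timestamp": t, "x": np.cumsum(rng.uniform(0, 0.6, 200)), "y": 0.0}
        )
        dists, counts = [], []
        for ms in (0.0, 0.6, 1.2, 2.0):
            gait, dist = lidar_kinematics(track, min_speed_kmh=ms)
            dists.append(dist.sum())
            counts.append(len(gait))
        assert all(d == pytest.approx(dists[0]) for d in dists)
        assert counts == sorted(counts, reverse=True)


class TestZoneVisits:
    def _track(self, points):
        ts = pd.date_range("2021-03-01T10:00:00", periods=len(points), freq="1s")
        return pd.DataFrame({"timestamp": ts, "x": [p[0] for p in points], "y": [p[1] for p in points]})

    def test_single_zone_track_is_one_visit(self):
        zm = reference_zone_map()
        track = self._track([(7.0, 2.0)] * 60)  # living room
        visits = zone_visits(track, zm)
        assert len(visits) == 1
        assert visits["zone_id"].iloc[0] == 2

    def test_two_dwells_are_two_visits(self):
        zm = reference_zone_map()
        track = self._track([(9.0, 6.0)] * 600 + [(7.0, 2.0)] * 300)  # entrance then living
        visits = zone_visits(track, zm)
        assert list(visits["zone_id"]) == [3, 2]
        durs = (visits["end"] - visits["start"]).dt.total_seconds().tolist()
        assert durs[0] == pytest.approx(599, abs=1)
        assert durs[1] == pytest.approx(299, abs=1)

    def test_brief_excursion_discarded_and_merged(self):
        zm = reference_zone_map()
        track = self._track([(7.0, 2.0)] * 30 + [(6.0, 6.0)] * 2 + [(7.0, 2.0)] * 30)
        visits = zone_visits(track, zm, min_dwell_s=5.0)
        assert len(visits) == 1
        assert visits["zone_id"].iloc[0] == 2
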