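"""Raw sensor streams -> use episodes, binned count/duration series,
lidar kinematics and zone visits.

Per-sensor conversions follow the study design: a vibration (tilt) sensor
use opens when the tilt leaves the resting pose by more than an angular
tolerance and closes when it returns; a smart-plug use is an interval of
power draw at or above an on-threshold; a gas-stove/bathroom use is a
temperature rise of at least ``delta_c`` over a rolling baseline; door
and motion sensors contribute point detections, with motion activity
additionally merged into episodes for duration accounting.

Counts and durations are aggregated on a fixed half-open bin grid
[start, start + width), labelled by bin start; 10-minute, hourly and
daily grids are supported.  An episode spanning a boundary contributes
duration to every bin it overlaps and count 1 to its start bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .household import HouseholdConfig, ZoneMap
from .simulate import RESTING_TILT

logger = logging.getLogger(__name__)

BIN_WIDTHS = {"10min": pd.Timedelta(minutes=10), "1h": pd.Timedelta(hours=1), "1d": pd.Timedelta(days=1)}

# rule defaults (configurable per call)
TILT_TOLERANCE_DEG = 10.0
TILT_TIMEOUT_S = 600.0
PLUG_ON_THRESHOLD_W = 5.0
PLUG_DEBOUNCE_S = 60.0
TEMP_DELTA_C = 2.0
TEMP_WINDOW_S = 600.0
MOTION_MERGE_GAP_S = 60.0
GAIT_MIN_SPEED_KMH = 0.6
ZONE_MIN_DWELL_S = 5.0


@dataclass(frozen=True)
class UseEpisode:
    channel_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    kind: str  # tilt_use | plug_on | door_open | motion_active | temp_rise

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("episode end precedes start")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class BinnedSeries:
    """Per-person counts and active durations on a fixed time grid.

    ``counts`` and ``durations`` are DataFrames indexed by bin start with
    one column per channel; durations are seconds and never exceed the
    bin width.
    """

    person_id: str
    bin_width: pd.Timedelta
    counts: pd.DataFrame
    durations: pd.DataFrame

    def __post_init__(self) -> None:
        width_s = self.bin_width.total_seconds()
        if (self.durations.to_numpy() > width_s + 1e-6).any():
            raise ValueError("bin duration exceeds bin width")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative count")


def _pivot_channel(events: pd.DataFrame) -> pd.DataFrame:
    """Wide per-sample table (one row per timestamp) for a single channel."""
    return events.pivot_table(index="timestamp", columns="field", values="value", aggfunc="last")


def vibration_use_episodes(
    events: pd.DataFrame,
    tolerance_deg: float = TILT_TOLERANCE_DEG,
    timeout_s: float = TILT_TIMEOUT_S,
    resting: tuple[float, float, float] = RESTING_TILT,
) -> list[UseEpisode]:
    """Tilt-change/tilt-restore uses of one vibration channel.

    An episode opens when the tilt vector deviates from the resting pose
    by more than ``tolerance_deg`` and closes when it returns within
    tolerance; an unclosed episode is truncated at ``timeout_s``.
    """
    if events.empty:
        return []
    channel = events["channel_id"].iloc[0]
    wide = _pivot_channel(events)
    if not {"x", "y", "z"} <= set(wide.columns):
        return []
    v = wide[["x", "y", "z"]].to_numpy(dtype=float)
    norms = np.linalg.norm(v, axis=1)
    norms[norms == 0] = 1.0
    r = np.asarray(resting, dtype=float)
    r = r / np.linalg.norm(r)
    cosang = np.clip(v @ r / norms, -1.0, 1.0)
    deviated = np.degrees(np.arccos(cosang)) > tolerance_deg
    times = wide.index
    episodes: list[UseEpisode] = []
    open_t: pd.Timestamp | None = None
    for t, dev in zip(times, deviated):
        if dev and open_t is None:
            open_t = t
        elif not dev and open_t is not None:
            end = min(t, open_t + pd.Timedelta(seconds=timeout_s))
            episodes.append(UseEpisode(channel, open_t, end, "tilt_use"))
            open_t = None
    if open_t is not None:
        episodes.append(
            UseEpisode(channel, open_t, open_t + pd.Timedelta(seconds=timeout_s), "tilt_use")
        )
    return episodes


def plug_on_intervals(
    events: pd.DataFrame,
    on_threshold_watts: float = PLUG_ON_THRESHOLD_W,
    debounce_s: float = PLUG_DEBOUNCE_S,
    stream_end: pd.Timestamp | None = None,
) -> list[UseEpisode]:
    """Intervals with power draw >= threshold; gaps shorter than the
    debounce are merged.  Power is held between readings (step function);
    an interval still on at the last reading closes at ``stream_end``
    (default: the last reading)."""
    if on_threshold_watts < 0:
        raise ValueError("on_threshold_watts must be nonnegative")
    if events.empty:
        return []
    channel = events["channel_id"].iloc[0]
    series = events[events["field"] == "power_w"].set_index("timestamp")["value"]
    series = series[~series.index.duplicated(keep="last")].sort_index()
    if series.empty:
        return []
    on = series.to_numpy() >= on_threshold_watts
    times = series.index
    end_default = stream_end if stream_end is not None else times[-1]
    raw: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    open_t: pd.Timestamp | None = None
    for t, flag in zip(times, on):
        if flag and open_t is None:
            open_t = t
        elif not flag and open_t is not None:
            raw.append((open_t, t))
            open_t = None
    if open_t is not None and end_default > open_t:
        raw.append((open_t, end_default))
    merged: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    for t0, t1 in raw:
        if merged and (t0 - merged[-1][1]).total_seconds() < debounce_s:
            merged[-1] = (merged[-1][0], t1)
        else:
            merged.append((t0, t1))
    return [UseEpisode(channel, t0, t1, "plug_on") for t0, t1 in merged]


def temp_rise_episodes(
    events: pd.DataFrame,
    delta_c: float = TEMP_DELTA_C,
    window_s: float = TEMP_WINDOW_S,
) -> list[UseEpisode]:
    """Heating episodes of one temperature-humidity channel.

    Outside an episode the baseline is the median of out-of-episode
    readings in the trailing ``window_s``; an episode opens when the
    temperature exceeds baseline + ``delta_c`` (the baseline freezes for
    its duration) and closes when it returns within ``delta_c / 2`` of
    that frozen baseline.  A still-open episode closes at the last
    reading."""
    if events.empty:
        return []
    channel = events["channel_id"].iloc[0]
    series = events[events["field"] == "temp_c"].set_index("timestamp")["value"]
    series = series[~series.index.duplicated(keep="last")].sort_index()
    if len(series) < 2:
        return []
    times = series.index.to_numpy()
    temps = series.to_numpy(dtype=float)
    t_s = times.astype("datetime64[s]").astype(np.int64).astype(float)
    episodes: list[UseEpisode] = []
    base_vals: list[float] = []
    base_times: list[float] = []
    open_idx: int | None = None
    frozen_base = 0.0
    for i in range(len(temps)):
        if open_idx is None:
            while base_times and t_s[i] - base_times[0] > window_s:
                base_times.pop(0)
                base_vals.pop(0)
            baseline = float(np.median(base_vals)) if base_vals else temps[i]
            if base_vals and temps[i] - baseline >= delta_c:
                open_idx = i
                frozen_base = baseline
            else:
                base_times.append(t_s[i])
                base_vals.append(temps[i])
        else:
            if temps[i] <= frozen_base + delta_c / 2.0:
                episodes.append(
                    UseEpisode(channel, pd.Timestamp(times[open_idx]), pd.Timestamp(times[i]), "temp_rise")
                )
                open_idx = None
                base_times = [t_s[i]]
                base_vals = [temps[i]]
    if open_idx is not None:
        episodes.append(
            UseEpisode(channel, pd.Timestamp(times[open_idx]), pd.Timestamp(times[-1]), "temp_rise")
        )
    return episodes


def door_open_episodes(events: pd.DataFrame) -> list[UseEpisode]:
    """Open->close intervals of one door channel; counts are open transitions."""
    if events.empty:
        return []
    channel = events["channel_id"].iloc[0]
    series = events[events["field"] == "state"].set_index("timestamp")["value"].sort_index()
    episodes: list[UseEpisode] = []
    open_t: pd.Timestamp | None = None
    for t, state in series.items():
        if state >= 0.5 and open_t is None:
            open_t = t
        elif state < 0.5 and open_t is not None:
            episodes.append(UseEpisode(channel, open_t, t, "door_open"))
            open_t = None
    if open_t is not None:
        episodes.append(UseEpisode(channel, open_t, series.index[-1], "door_open"))
    return episodes


def motion_active_episodes(
    events: pd.DataFrame, merge_gap_s: float = MOTION_MERGE_GAP_S
) -> list[UseEpisode]:
    """Detections within ``merge_gap_s`` of each other merge into one
    activity episode (isolated hits get zero duration)."""
    hits = events[events["field"] == "detected"]
    if hits.empty:
        return []
    channel = events["channel_id"].iloc[0]
    times = hits["timestamp"].sort_values().to_numpy()
    gaps = np.diff(times).astype("timedelta64[s]").astype(float)
    breaks = np.flatnonzero(gaps > merge_gap_s) + 1
    episodes = []
    for seg in np.split(times, breaks):
        episodes.append(UseEpisode(channel, pd.Timestamp(seg[0]), pd.Timestamp(seg[-1]), "motion_active"))
    return episodes


def _bin_grid(start: pd.Timestamp, end: pd.Timestamp, width: pd.Timedelta) -> pd.DatetimeIndex:
    first = start.floor(width)
    return pd.date_range(first, end, freq=width, inclusive="left" if end == first else "both")


def bin_counts_durations(
    episodes_by_channel: dict[str, list[UseEpisode]],
    point_counts: dict[str, pd.Series] | None,
    bin_width: str | pd.Timedelta,
    grid: pd.DatetimeIndex,
    person_id: str = "",
    duration_only: set[str] | None = None,
) -> BinnedSeries:
    """Aggregate episodes and point events onto a fixed bin grid.

    ``point_counts`` maps channel -> Series of event timestamps (values
    ignored); point events contribute counts only.  Episode channels get
    count 1 in the start bin and overlap-proportional durations in every
    bin they span, capped at the grid end.  Channels in ``duration_only``
    take counts from ``point_counts`` alone (their episodes contribute
    durations only) — used for door/motion channels whose point stamps
    coincide with episode starts.
    """
    duration_only = duration_only or set()
    width = BIN_WIDTHS[bin_width] if isinstance(bin_width, str) else bin_width
    width_s = width.total_seconds()
    grid_end = grid[-1] + width
    channels = sorted(set(episodes_by_channel) | set(point_counts or {}))
    col = {ch: i for i, ch in enumerate(channels)}
    counts_arr = np.zeros((len(grid), len(channels)), dtype=np.int64)
    dur_arr = np.zeros((len(grid), len(channels)), dtype=float)
    g0_s = grid[0].value / 1e9
    end_s = grid_end.value / 1e9
    n_bins = len(grid)
    for ch, eps in episodes_by_channel.items():
        if not eps:
            continue
        j = col[ch]
        starts = np.array([ep.start.value for ep in eps], dtype=np.int64) / 1e9
        ends = np.array([ep.end.value for ep in eps], dtype=np.int64) / 1e9
        s = np.clip(starts, g0_s, end_s)
        e = np.clip(ends, g0_s, end_s)
        keep = e >= s
        s, e = s[keep], e[keep]
        b_start = np.minimum(((s - g0_s) // width_s).astype(np.int64), n_bins - 1)
        b_end = np.minimum(((np.maximum(e, s) - g0_s) // width_s).astype(np.int64), n_bins - 1)
        if ch not in duration_only:
            np.add.at(counts_arr[:, j], b_start, 1)
        # spread duration over the spanned bins (episodes are short: loop
        # over episodes whose span > 1 bin only)
        single = b_start == b_end
        np.add.at(dur_arr[:, j], b_start[single], (e - s)[single])
        for si, ei, bs, be in zip(s[~single], e[~single], b_start[~single], b_end[~single]):
            for b in range(bs, be + 1):
                lo = g0_s + b * width_s
                overlap = min(ei, lo + width_s) - max(si, lo)
                if overlap > 0:
                    dur_arr[b, j] += overlap
    for ch, stamps in (point_counts or {}).items():
        ts = stamps if isinstance(stamps, pd.DatetimeIndex) else pd.DatetimeIndex(stamps)
        ts = ts[(ts >= grid[0]) & (ts < grid_end)]
        idx = ((ts.asi8 / 1e9 - g0_s) // width_s).astype(np.int64)
        counts_arr[:, col[ch]] += np.bincount(idx, minlength=n_bins)
    counts = pd.DataFrame(counts_arr, index=grid, columns=channels)
    durations = pd.DataFrame(np.minimum(dur_arr, width_s), index=grid, columns=channels)
    return BinnedSeries(person_id=person_id, bin_width=width, counts=counts, durations=durations)


def lidar_kinematics(
    track: pd.DataFrame, min_speed_kmh: float = GAIT_MIN_SPEED_KMH
) -> tuple[pd.DataFrame, pd.Series]:
    """Gait samples and per-hour movement distance from a 2-D lidar track.

    ``track`` has columns timestamp, x, y (time-sorted).  Between
    consecutive fixes the speed is displacement / elapsed-time in km/h;
    fixes more than 30 s apart are treated as separate track segments.
    Samples below ``min_speed_kmh`` are excluded from gait statistics but
    their displacement still accrues to movement distance.
    """
    if track.empty or len(track) < 2:
        return (
            pd.DataFrame(columns=["timestamp", "speed_kmh", "displacement_m"]),
            pd.Series(dtype=float),
        )
    t = track["timestamp"].to_numpy()
    x = track["x"].to_numpy(dtype=float)
    y = track["y"].to_numpy(dtype=float)
    dt = np.diff(t).astype("timedelta64[s]").astype(float)
    disp = np.hypot(np.diff(x), np.diff(y))
    valid = dt > 0
    dup = ~valid
    if dup.any():
        logger.warning("lidar track: skipping %d duplicate-timestamp pairs", int(dup.sum()))
    seg_ok = valid & (dt <= 30.0)  # gap => new walk, not a displacement
    speed = np.zeros_like(disp)
    speed[seg_ok] = disp[seg_ok] / dt[seg_ok] * 3.6
    samples = pd.DataFrame(
        {
            "timestamp": track["timestamp"].iloc[1:].to_numpy()[seg_ok],
            "speed_kmh": speed[seg_ok],
            "displacement_m": disp[seg_ok],
        }
    )
    gait = samples[samples["speed_kmh"] >= min_speed_kmh].reset_index(drop=True)
    hours = pd.Series(samples["displacement_m"].to_numpy(), index=pd.DatetimeIndex(samples["timestamp"]).floor("1h"))
    distance_per_hour = hours.groupby(level=0).sum()
    return gait, distance_per_hour


def zone_visits(
    track: pd.DataFrame, zone_map: ZoneMap, min_dwell_s: float = ZONE_MIN_DWELL_S
) -> pd.DataFrame:
    """Maximal runs of track points in one zone -> visits.

    Runs shorter than ``min_dwell_s`` are discarded and their neighbours
    merged when they share a zone.  Points outside every zone snap to the
    nearest zone (logged).  Returns columns zone_id, start, end.
    """
    if track.empty:
        return pd.DataFrame(columns=["zone_id", "start", "end"])
    x = track["x"].to_numpy(dtype=float)
    y = track["y"].to_numpy(dtype=float)
    zones = zone_map.locate_array(x, y)
    times = pd.DatetimeIndex(track["timestamp"])
    runs: list[list] = []  # [zone, start, end]
    for z, t in zip(zones, times):
        if runs and runs[-1][0] == z:
            runs[-1][2] = t
        else:
            runs.append([int(z), t, t])
    kept = [r for r in runs if (r[2] - r[1]).total_seconds() >= min_dwell_s or len(runs) == 1]
    merged: list[list] = []
    for r in kept:
        if merged and merged[-1][0] == r[0]:
            merged[-1][2] = r[2]
        else:
            merged.append(list(r))
    return pd.DataFrame(
        {"zone_id": [r[0] for r in merged], "start": [r[1] for r in merged], "end": [r[2] for r in merged]}
    )


def extract_episodes(
    events: pd.DataFrame,
    household: HouseholdConfig,
    stream_end: pd.Timestamp | None = None,
    **rule_kwargs,
) -> tuple[dict[str, list[UseEpisode]], dict[str, pd.DatetimeIndex]]:
    """Per-channel episodes and point-event stamps for one person's log.

    Returns ``(episodes_by_channel, point_stamps_by_channel)``:
    vibration -> tilt uses, plug -> on-intervals, temp-humidity -> rises,
    door -> open episodes + open-transition stamps, motion -> activity
    episodes + detection stamps.
    """
    episodes: dict[str, list[UseEpisode]] = {}
    points: dict[str, pd.DatetimeIndex] = {}
    if events.empty:
        return episodes, points
    end = stream_end or events["timestamp"].max()
    for ch, ev in events.groupby("channel_id", sort=True):
        st = ev["sensor_type"].iloc[0]
        if st == "vibration":
            episodes[ch] = vibration_use_episodes(ev, **_sub(rule_kwargs, "tilt"))
        elif st == "plug":
            episodes[ch] = plug_on_intervals(ev, stream_end=end, **_sub(rule_kwargs, "plug"))
        elif st == "temp_humidity":
            episodes[ch] = temp_rise_episodes(ev, **_sub(rule_kwargs, "temp"))
        elif st == "door":
            eps = door_open_episodes(ev)
            episodes[ch] = eps
            points[ch] = pd.DatetimeIndex([e.start for e in eps])
        elif st == "motion":
            episodes[ch] = motion_active_episodes(ev)
            points[ch] = pd.DatetimeIndex(ev.loc[ev["field"] == "detected", "timestamp"])
    return episodes, points


def _sub(kwargs: dict, prefix: str) -> dict:
    return {k[len(prefix) + 1 :]: v for k, v in kwargs.items() if k.startswith(prefix + "_")}


def lidar_track(events: pd.DataFrame, household: HouseholdConfig) -> pd.DataFrame:
    """Extract the (timestamp, x, y) lidar track from a long event table."""
    lid = events[events["channel_id"] == household.lidar_channel]
    if lid.empty:
        return pd.DataFrame(columns=["timestamp", "x", "y"])
    wide = lid.pivot_table(index="timestamp", columns="field", values="value", aggfunc="last")
    wide = wide.dropna(subset=["x", "y"]).reset_index()
    return wide[["timestamp", "x", "y"]]
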