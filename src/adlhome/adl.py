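"""Rule-based fusion of per-channel use episodes into ADL episodes.

Seven activity families are inferred: cooking (with heating-food as the
microwave-only variant), taking medications, grooming, using household
appliances (TV / electric mat / fan / vacuum), outings (the
unlock-and-close-the-entrance-door proxy), household chores (washing
dishes, laundering) and indoor wandering (zone visits and late-night
activity, emitted as per-bin metrics rather than episodes).

Time-of-day tags follow the study's wall-clock windows: meals
breakfast 05-10, lunch 12-15, dinner 17-20; medications add bedtime
21-24; grooming nighttime 00-04; TV morning 04-12 / night 00-04; mat
daytime 12-16 / night 00-04.  Point-like activities tag by episode
start; appliance sessions tag by overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .household import HouseholdConfig
from .preprocess import UseEpisode

logger = logging.getLogger(__name__)

COOKING_WINDOW_S = 30 * 60.0
DISHES_MIN_S = 30.0
FAUCET_LONG_S = 60.0
OUTING_QUIET_GAP_S = 600.0
OUTING_RESUME_S = 300.0
TV_AFTER_RETURN_S = 1800.0

MEAL_TAGS = {"breakfast": (5, 10), "lunch": (12, 15), "dinner": (17, 20)}
MED_TAGS = {"morning": (5, 10), "lunch": (12, 15), "evening": (17, 20), "bedtime": (21, 24)}

#: appliance pairs whose simultaneous use during cooking is a feature
COOKING_PAIRS = {
    "fridge_sink": ("refrigerator", "kitchen_sink"),
    "sink_ricecooker": ("kitchen_sink", "rice_cooker"),
    "fridge_stove": ("refrigerator", "stove_temp"),
    "stove_microwave": ("stove_temp", "microwave_door"),
}

KITCHEN_APPLIANCE_ROLES = (
    "refrigerator",
    "rice_cooker",
    "kitchen_sink",
    "microwave_door",
    "cupboard_door",
)


@dataclass
class ADLEpisode:
    person_id: str
    adl_type: str
    start: pd.Timestamp
    end: pd.Timestamp
    contributing_channels: frozenset[str] = frozenset()
    tags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("ADL episode end precedes start")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class OutingRecord:
    person_id: str
    leave: pd.Timestamp
    return_: pd.Timestamp
    appliances_left_on: frozenset[str] = frozenset()
    lock_ok: bool = True
    tv_after_return: bool = False

    def __post_init__(self) -> None:
        if self.return_ <= self.leave:
            raise ValueError("outing return must follow leave")

    @property
    def duration_s(self) -> float:
        return (self.return_ - self.leave).total_seconds()


def _window_tag(t: pd.Timestamp, windows: dict[str, tuple[int, int]]) -> str | None:
    h = t.hour + t.minute / 60.0
    for name, (h0, h1) in windows.items():
        if h0 <= h < h1:
            return name
    return None


def _overlaps_window(start: pd.Timestamp, end: pd.Timestamp, h0: int, h1: int) -> bool:
    """Does [start, end] overlap the daily wall-clock window [h0, h1)?"""
    day = start.normalize()
    last = end.normalize()
    d = day
    while d <= last:
        w0 = d + pd.Timedelta(hours=h0)
        w1 = d + pd.Timedelta(hours=h1)
        if start < w1 and end > w0:
            return True
        d += pd.Timedelta(days=1)
    return False


def detect_cooking(
    kitchen_episodes: dict[str, list[UseEpisode]],
    stove_rises: list[UseEpisode],
    household: HouseholdConfig,
    person_id: str = "",
    window_s: float = COOKING_WINDOW_S,
) -> list[ADLEpisode]:
    """Cluster kitchen-appliance activity; classify cooking vs heating food.

    Events within a rolling ``window_s`` of each other form one candidate
    cluster.  A cluster is *cooking* iff it involves >= 2 distinct kitchen
    appliance channels and overlaps a gas-stove temperature rise; a
    cluster containing the microwave but no stove rise is *heating_food*.
    The episode spans the earliest to the latest contributing event
    (including the overlapping stove rise).
    """
    role_of = {household.role(r): r for r in KITCHEN_APPLIANCE_ROLES if r in household.roles}
    items: list[tuple[pd.Timestamp, pd.Timestamp, str]] = []
    for ch, eps in kitchen_episodes.items():
        if ch not in role_of:
            continue
        for ep in eps:
            items.append((ep.start, ep.end, ch))
    items.sort(key=lambda x: x[0])
    clusters: list[list[tuple[pd.Timestamp, pd.Timestamp, str]]] = []
    for it in items:
        if clusters and (it[0] - clusters[-1][-1][0]).total_seconds() <= window_s:
            clusters[-1].append(it)
        else:
            clusters.append([it])
    out: list[ADLEpisode] = []
    used_rises: set[int] = set()
    for cluster in clusters:
        c_start = min(s for s, _, _ in cluster)
        c_end = max(e for _, e, _ in cluster)
        channels = {ch for _, _, ch in cluster}
        rise = None
        for i, r in enumerate(stove_rises):
            if i in used_rises:
                continue
            if r.start <= c_end + pd.Timedelta(seconds=window_s) and r.end >= c_start - pd.Timedelta(
                seconds=window_s
            ):
                rise = (i, r)
                break
        if rise is not None and len(channels) >= 2:
            i, r = rise
            used_rises.add(i)
            start = min(c_start, r.start)
            end = max(c_end, r.end)
            tags = set()
            meal = _window_tag(start, MEAL_TAGS)
            if meal:
                tags.add(meal)
            if (end - start).total_seconds() > 30 * 60:
                tags.add("over_30min")
            contrib = channels | {r.channel_id}
            for pair, (ra, rb) in COOKING_PAIRS.items():
                ca = household.roles.get(ra)
                cb = household.roles.get(rb)
                if ca in contrib and cb in contrib:
                    tags.add(f"pair_{pair}")
            out.append(
                ADLEpisode(person_id, "cooking", start, end, frozenset(contrib), tags)
            )
        elif household.roles.get("microwave_door") in channels and rise is None:
            tags = set()
            meal = _window_tag(c_start, MEAL_TAGS)
            if meal:
                tags.add(meal)
            out.append(
                ADLEpisode(person_id, "heating_food", c_start, c_end, frozenset(channels), tags)
            )
    return sorted(out, key=lambda e: e.start)


def detect_medication(
    pill_episodes: list[UseEpisode], person_id: str = ""
) -> list[ADLEpisode]:
    """One taking-medications episode per pill-organizer use, window-tagged."""
    out = []
    for ep in pill_episodes:
        tags = set()
        tag = _window_tag(ep.start, MED_TAGS)
        if tag:
            tags.add(tag)
        out.append(
            ADLEpisode(person_id, "taking_medications", ep.start, ep.end, frozenset({ep.channel_id}), tags)
        )
    return out


def detect_appliance_use(
    plug_episodes: dict[str, list[UseEpisode]],
    vibration_episodes: dict[str, list[UseEpisode]],
    household: HouseholdConfig,
    person_id: str = "",
) -> list[ADLEpisode]:
    """TV/mat sessions from smart plugs, fan/vacuum uses from vibration.

    TV sessions tag ``tv_morning`` (04-12) and ``tv_night`` (00-04) by
    overlap; mat sessions tag ``mat_daytime`` (12-16) and ``mat_night``
    (00-04) by overlap."""
    out: list[ADLEpisode] = []
    specs = [
        ("tv_plug", "tv", (("tv_morning", 4, 12), ("tv_night", 0, 4))),
        ("mat_plug", "mat", (("mat_daytime", 12, 16), ("mat_night", 0, 4))),
    ]
    for role, label, windows in specs:
        ch = household.roles.get(role)
        for ep in plug_episodes.get(ch, []):
            tags = {label}
            for tag, h0, h1 in windows:
                if _overlaps_window(ep.start, ep.end, h0, h1):
                    tags.add(tag)
            out.append(
                ADLEpisode(person_id, "using_appliances", ep.start, ep.end, frozenset({ch}), tags)
            )
    for role in ("fan", "vacuum"):
        ch = household.roles.get(role)
        for ep in vibration_episodes.get(ch, []):
            out.append(
                ADLEpisode(person_id, "using_appliances", ep.start, ep.end, frozenset({ch}), {role})
            )
    return sorted(out, key=lambda e: e.start)


def detect_outings(
    entrance_door_stamps: pd.DatetimeIndex,
    motion_stamps: pd.DatetimeIndex,
    plug_episodes: dict[str, list[UseEpisode]],
    household: HouseholdConfig,
    person_id: str = "",
    quiet_gap_s: float = OUTING_QUIET_GAP_S,
    resume_s: float = OUTING_RESUME_S,
    lux_on_during: bool = False,
) -> list[OutingRecord]:
    """Outings from entrance-door toggles and interior-motion silence.

    A door toggle followed by at least ``quiet_gap_s`` with zero interior
    motion opens a candidate; it closes at the next door toggle with
    motion resuming within ``resume_s``.  Appliances (TV/mat plugs) whose
    on-interval covers the whole absence are flagged left-on;
    ``lock_ok`` is true iff nothing was left on and the lights were off
    (``lux_on_during`` reports lighting observed during the absence).
    Overlapping candidates keep the earliest.
    """
    stamps = pd.DatetimeIndex(entrance_door_stamps).sort_values()
    motion = pd.DatetimeIndex(motion_stamps).sort_values().asi8
    watched = [household.roles.get("tv_plug"), household.roles.get("mat_plug")]
    out: list[OutingRecord] = []
    last_return: pd.Timestamp | None = None
    for i, t_leave in enumerate(stamps[:-1]):
        if last_return is not None and t_leave < last_return:
            logger.info("outing candidate at %s overlaps previous; kept earliest", t_leave)
            continue
        t_next = stamps[i + 1]
        gap_lo = np.searchsorted(motion, (t_leave + pd.Timedelta(seconds=30)).value)
        gap_hi = np.searchsorted(motion, t_next.value)
        if gap_hi > gap_lo:  # interior motion during the absence
            continue
        if (t_next - t_leave).total_seconds() < quiet_gap_s:
            continue
        after = np.searchsorted(motion, t_next.value)
        if after >= len(motion):
            continue
        if (pd.Timestamp(motion[after]) - t_next).total_seconds() > resume_s:
            continue
        left_on = set()
        for ch in watched:
            for ep in plug_episodes.get(ch, []):
                if ep.start <= t_leave and ep.end >= t_next:
                    left_on.add(ch)
        tv = household.roles.get("tv_plug")
        tv_after = any(
            0.0 <= (ep.start - t_next).total_seconds() <= TV_AFTER_RETURN_S
            for ep in plug_episodes.get(tv, [])
        )
        out.append(
            OutingRecord(
                person_id=person_id,
                leave=t_leave,
                return_=t_next,
                appliances_left_on=frozenset(left_on),
                lock_ok=not left_on and not lux_on_during,
                tv_after_return=tv_after,
            )
        )
        last_return = t_next
    return out


def detect_chores(
    sink_episodes: list[UseEpisode],
    washer_episodes: list[UseEpisode],
    person_id: str = "",
    dishes_min_s: float = DISHES_MIN_S,
) -> list[ADLEpisode]:
    """Washing dishes (sink uses >= 30 s) and laundering (washer runs)."""
    out = [
        ADLEpisode(person_id, "household_chores", ep.start, ep.end, frozenset({ep.channel_id}), {"dishes"})
        for ep in sink_episodes
        if ep.duration_s >= dishes_min_s
    ]
    out += [
        ADLEpisode(person_id, "household_chores", ep.start, ep.end, frozenset({ep.channel_id}), {"laundering"})
        for ep in washer_episodes
    ]
    return sorted(out, key=lambda e: e.start)


def detect_grooming(
    faucet_episodes: list[UseEpisode],
    shower_episodes: list[UseEpisode],
    hairdryer_episodes: list[UseEpisode],
    person_id: str = "",
    long_faucet_s: float = FAUCET_LONG_S,
) -> list[ADLEpisode]:
    """Grooming uses with nighttime (start 00-04), shower and >=1 min tags."""
    out: list[ADLEpisode] = []
    for ep, kind in (
        [(e, "faucet") for e in faucet_episodes]
        + [(e, "shower") for e in shower_episodes]
        + [(e, "hairdryer") for e in hairdryer_episodes]
    ):
        tags = {kind}
        if 0 <= ep.start.hour < 4:
            tags.add("nighttime")
        if kind == "faucet" and ep.duration_s >= long_faucet_s:
            tags.add("over_1min")
        out.append(ADLEpisode(person_id, "grooming", ep.start, ep.end, frozenset({ep.channel_id}), tags))
    return sorted(out, key=lambda e: e.start)


def detect_wandering(
    visits: pd.DataFrame,
    events: pd.DataFrame,
    grid: pd.DatetimeIndex,
    bin_width: pd.Timedelta,
    household: HouseholdConfig,
) -> pd.DataFrame:
    """Per-bin indoor-wandering metrics.

    Columns: ``zone{z}_visits`` / ``zone{z}_stay_s`` for zones 1-6,
    ``room_transitions`` (zone changes involving the living room, counted
    at the boundary crossing) and ``night_events`` (all-channel event
    count inside 00:00-05:00).
    """
    cols: dict[str, np.ndarray] = {}
    n = len(grid)
    g0 = grid[0].value / 1e9
    width_s = bin_width.total_seconds()
    for z in range(1, 7):
        cols[f"zone{z}_visits"] = np.zeros(n)
        cols[f"zone{z}_stay_s"] = np.zeros(n)
    cols["room_transitions"] = np.zeros(n)
    cols["night_events"] = np.zeros(n)
    living = 2

    if not visits.empty:
        starts = pd.DatetimeIndex(visits["start"]).asi8 / 1e9
        ends = pd.DatetimeIndex(visits["end"]).asi8 / 1e9
        zones = visits["zone_id"].to_numpy()
        for s, e, z in zip(starts, ends, zones):
            b0 = int((s - g0) // width_s)
            if 0 <= b0 < n:
                cols[f"zone{z}_visits"][b0] += 1
            b_lo = max(int((s - g0) // width_s), 0)
            b_hi = min(int((e - g0) // width_s), n - 1)
            for b in range(b_lo, b_hi + 1):
                lo = g0 + b * width_s
                overlap = min(e, lo + width_s) - max(s, lo)
                if overlap > 0:
                    cols[f"zone{z}_stay_s"][b] += overlap
        trans = (zones[:-1] != zones[1:]) & ((zones[:-1] == living) | (zones[1:] == living))
        t_cross = ends[:-1][trans]
        idx = ((t_cross - g0) // width_s).astype(int)
        for b in idx[(idx >= 0) & (idx < n)]:
            cols["room_transitions"][b] += 1

    if not events.empty:
        samples = events.drop_duplicates(["timestamp", "channel_id"])
        ts = pd.DatetimeIndex(samples["timestamp"])
        night = (ts.hour < 5)
        t_night = ts[night].asi8 / 1e9
        idx = ((t_night - g0) // width_s).astype(int)
        ok = (idx >= 0) & (idx < n)
        cols["night_events"] += np.bincount(idx[ok], minlength=n)

    for z in range(1, 7):
        cols[f"zone{z}_stay_s"] = np.minimum(cols[f"zone{z}_stay_s"], width_s)
    return pd.DataFrame(cols, index=grid)


def infer_all(
    episodes: dict[str, list[UseEpisode]],
    points: dict[str, pd.DatetimeIndex],
    visits: pd.DataFrame,
    events: pd.DataFrame,
    grid: pd.DatetimeIndex,
    bin_width: pd.Timedelta,
    household: HouseholdConfig,
    person_id: str = "",
) -> tuple[list[ADLEpisode], list[OutingRecord], pd.DataFrame]:
    """Run every ADL rule for one person; returns (episodes, outings, wandering)."""
    role = household.roles.get
    kitchen = {household.role(r): episodes.get(household.role(r), []) for r in KITCHEN_APPLIANCE_ROLES}
    stove_rises = episodes.get(role("stove_temp"), [])
    adls: list[ADLEpisode] = []
    adls += detect_cooking(kitchen, stove_rises, household, person_id)
    adls += detect_medication(episodes.get(role("pill_organizer"), []), person_id)
    plug_eps = {ch: eps for ch, eps in episodes.items() if household.channels.get(ch) == "plug"}
    vib_eps = {ch: eps for ch, eps in episodes.items() if household.channels.get(ch) == "vibration"}
    adls += detect_appliance_use(plug_eps, vib_eps, household, person_id)
    adls += detect_chores(
        episodes.get(role("kitchen_sink"), []), episodes.get(role("washer_plug"), []), person_id
    )
    adls += detect_grooming(
        episodes.get(role("bathroom_faucet"), []),
        episodes.get(role("showerhead"), []),
        episodes.get(role("hairdryer"), []),
        person_id,
    )
    motion_channels = household.channels_of_type("motion")
    motion_stamps = pd.DatetimeIndex(
        np.sort(np.concatenate([points.get(ch, pd.DatetimeIndex([])).asi8 for ch in motion_channels]))
    )
    outings = detect_outings(
        points.get(role("entrance_door"), pd.DatetimeIndex([])),
        motion_stamps,
        plug_eps,
        household,
        person_id,
    )
    wandering = detect_wandering(visits, events, grid, bin_width, household)
    return sorted(adls, key=lambda e: e.start), outings, wandering


def episodes_frame(adls: list[ADLEpisode]) -> pd.DataFrame:
    """Tabular export: person_id, adl_type, start, end, channels, tags."""
    return pd.DataFrame(
        {
            "person_id": [e.person_id for e in adls],
            "adl_type": [e.adl_type for e in adls],
            "start": [e.start for e in adls],
            "end": [e.end for e in adls],
            "channels": ["|".join(sorted(e.contributing_channels)) for e in adls],
            "tags": ["|".join(sorted(e.tags)) for e in adls],
        }
    )
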