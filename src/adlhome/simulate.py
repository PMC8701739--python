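"""Persona-driven synthetic smart-home cohort generator.

Simulates raw sensor event streams for a small cohort of older adults
living alone, with the statistical structure the downstream analysis
assumes: scheduled meals with correlated kitchen-appliance use, medication
events with adherence and timing jitter, grooming, chores, TV/electric-mat
sessions, outings (with or without forgetting appliances on), night-time
activity, and 1 Hz lidar walks between zone centroids at a persona-specific
gait speed.

Group contrasts are encoded in :class:`PersonaParams`, not hard-coded by
label: the packaged defaults give the dementia group lower
appliance-use coherence, more night activity, worse medication adherence,
more forgotten-appliance outings, longer task durations and the two
groups' published mean gait speeds (normal 1.023 km/h, dementia
1.209 km/h).

The dwelling is deliberately silent between 00:00 and 05:00 except for
persona night-activity events, so a persona with ``night_activity_rate=0``
produces exactly zero events in that window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import empty_events, sort_events
from .household import HouseholdConfig, reference_household

HOUR = 3600.0
NIGHT_END_S = 5 * HOUR  # 00:00-05:00 late-night window
RESTING_TILT = (0.0, 0.0, 1.0)

#: mealtime cooking windows (start hour, end hour), shared with the ADL rules
MEAL_WINDOWS = {"breakfast": (5.0, 10.0), "lunch": (12.0, 15.0), "dinner": (17.0, 20.0)}


@dataclass
class PersonaParams:
    """Behavioural parameters of one simulated resident.

    Probabilities are per-opportunity; ``night_activity_rate`` is events
    per hour inside 00:00-05:00; gait speeds are km/h;
    ``task_duration_scale`` >= 1 stretches task durations.
    """

    meal_cook_prob: dict[str, float] = field(
        default_factory=lambda: {"breakfast": 0.8, "lunch": 0.6, "dinner": 0.9}
    )
    appliance_coherence: float = 0.85
    med_adherence_prob: float = 0.9
    med_time_jitter: float = 10.0  # minutes (std)
    night_activity_rate: float = 0.2
    forget_appliance_on_prob: float = 0.05
    gait_speed_mean: float = 1.023
    gait_speed_sd: float = 0.35
    task_duration_scale: float = 1.0
    outing_prob: float = 0.7

    def validate(self) -> None:
        probs = [
            *self.meal_cook_prob.values(),
            self.appliance_coherence,
            self.med_adherence_prob,
            self.forget_appliance_on_prob,
            self.outing_prob,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("persona probabilities must lie in [0, 1]")
        if self.gait_speed_mean <= 0:
            raise ValueError("gait_speed_mean must be positive")
        if self.task_duration_scale < 1.0:
            raise ValueError("task_duration_scale must be >= 1")
        if self.night_activity_rate < 0 or self.med_time_jitter < 0 or self.gait_speed_sd < 0:
            raise ValueError("rates/jitter must be nonnegative")


#: defaults for the early-stage dementia group (see docs/methods.md)
def dementia_persona() -> PersonaParams:
    return PersonaParams(
        meal_cook_prob={"breakfast": 0.55, "lunch": 0.45, "dinner": 0.65},
        appliance_coherence=0.25,
        med_adherence_prob=0.6,
        med_time_jitter=40.0,
        night_activity_rate=1.5,
        forget_appliance_on_prob=0.5,
        gait_speed_mean=1.209,
        gait_speed_sd=0.45,
        task_duration_scale=1.5,
        outing_prob=0.5,
    )


def normal_persona() -> PersonaParams:
    return PersonaParams()


@dataclass
class PersonProfile:
    person_id: str
    group: str  # "normal" | "dementia"
    mmse: int
    cdr: float
    household: HouseholdConfig
    behavior: PersonaParams

    def __post_init__(self) -> None:
        if self.group not in ("normal", "dementia"):
            raise ValueError(f"unknown group {self.group}")
        if not 0 <= self.mmse <= 30:
            raise ValueError("MMSE must be in 0..30")
        if self.group == "normal" and self.cdr != 0:
            raise ValueError("normal controls have CDR 0")
        if self.group == "dementia" and self.cdr not in (0.5, 1):
            raise ValueError("dementia group has CDR 0.5 or 1")
        self.behavior.validate()


@dataclass
class CohortConfig:
    n_normal: int = 7
    n_dementia: int = 6
    days: int = 14
    start_date: str = "2021-03-01"
    normal_behavior: PersonaParams = field(default_factory=normal_persona)
    dementia_behavior: PersonaParams = field(default_factory=dementia_persona)
    mmse_range_normal: tuple[int, int] = (25, 30)  # inclusive; mean 27.5
    mmse_range_dementia: tuple[int, int] = (12, 23)  # inclusive; mean 17.5
    persona_jitter: float = 0.05  # person-level sd on probabilities/coherence
    household: HouseholdConfig | None = None

    def validate(self) -> None:
        if self.n_normal <= 0 and self.n_dementia <= 0:
            raise ValueError("cohort must contain at least one person")
        if self.n_normal < 0 or self.n_dementia < 0:
            raise ValueError("group sizes must be nonnegative")
        if self.days <= 0:
            raise ValueError("days of observation must be positive")


class _EventBuffer:
    """Accumulates (seconds-of-day, channel, field, value) blocks cheaply."""

    def __init__(self, day: pd.Timestamp, person_id: str) -> None:
        self.day = day
        self.person_id = person_id
        self._secs: list[np.ndarray] = []
        self._meta: list[tuple[str, str, str, int]] = []
        self._vals: list[np.ndarray] = []

    def add(self, secs, channel: str, sensor_type: str, fld: str, values) -> None:
        s = np.atleast_1d(np.asarray(secs, dtype=float))
        if s.size == 0:
            return
        v = np.broadcast_to(np.atleast_1d(np.asarray(values, dtype=float)), s.shape)
        self._secs.append(s)
        self._vals.append(np.array(v, dtype=float))
        self._meta.append((channel, sensor_type, fld, s.size))

    def frame(self) -> pd.DataFrame:
        if not self._secs:
            return empty_events()
        secs = np.concatenate(self._secs)
        vals = np.concatenate(self._vals)
        n = secs.size
        ch = np.empty(n, dtype=object)
        st = np.empty(n, dtype=object)
        fl = np.empty(n, dtype=object)
        pos = 0
        for channel, stype, fld, size in self._meta:
            ch[pos : pos + size] = channel
            st[pos : pos + size] = stype
            fl[pos : pos + size] = fld
            pos += size
        ts = self.day + pd.to_timedelta(np.round(secs).astype(np.int64), unit="s")
        df = pd.DataFrame(
            {
                "timestamp": ts,
                "person_id": self.person_id,
                "channel_id": ch,
                "sensor_type": st,
                "field": fl,
                "value": vals,
            }
        )
        return sort_events(df)


def _tilt_use(buf: _EventBuffer, rng: np.random.Generator, channel: str, t0: float, t1: float) -> None:
    """One vibration-sensor use: deviated tilt at t0, restored at t1."""
    theta = np.deg2rad(rng.uniform(25.0, 60.0))
    phi = rng.uniform(0, 2 * np.pi)
    dev = (np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta))
    for fld, dv, rv in zip(("x", "y", "z"), dev, RESTING_TILT):
        buf.add([t0, t1], channel, "vibration", fld, [dv, rv])


def _door_toggle(buf: _EventBuffer, channel: str, t_open: float, t_close: float) -> None:
    buf.add([t_open, t_close], channel, "door", "state", [1.0, 0.0])


def _motion_hits(buf: _EventBuffer, channel: str, secs: np.ndarray) -> None:
    if len(secs) == 0:
        return
    lux = _daylight_lux(secs)
    buf.add(secs, channel, "motion", "detected", 1.0)
    buf.add(secs, channel, "motion", "lux", lux)


def _daylight_lux(secs: np.ndarray) -> np.ndarray:
    h = np.asarray(secs) / HOUR
    day = 300.0 * np.clip(np.sin((h - 6.0) / 12.0 * np.pi), 0.0, None)
    evening = np.where((h >= 18) & (h < 24), 120.0, 0.0)
    night = np.where(h < 5, 8.0, 0.0)
    return day + evening + night + 5.0


def _lognormal_speed(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Draws in km/h from a lognormal moment-matched to (mean, sd)."""
    if sd <= 0:
        return np.full(size, mean)
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _walk(
    buf: _EventBuffer,
    rng: np.random.Generator,
    household: HouseholdConfig,
    t0: float,
    zone_from: int,
    zone_to: int,
    persona: PersonaParams,
    sample_hz: float = 1.0,
) -> float:
    """Straight 1 Hz lidar walk between zone centroids; returns arrival time."""
    zm = household.zone_map
    x0, y0 = zm.zone_of(zone_from).centroid
    x1, y1 = zm.zone_of(zone_to).centroid
    dist = float(np.hypot(x1 - x0, y1 - y0))
    speed_kmh = float(_lognormal_speed(rng, persona.gait_speed_mean, persona.gait_speed_sd, 1)[0])
    speed_ms = max(speed_kmh / 3.6, 0.05)
    duration = dist / speed_ms
    n = max(int(duration * sample_hz) + 1, 2)
    tt = t0 + np.linspace(0.0, duration, n)
    frac = np.linspace(0.0, 1.0, n)
    xs = x0 + frac * (x1 - x0)
    ys = y0 + frac * (y1 - y0)
    buf.add(tt, household.lidar_channel, "lidar", "x", xs)
    buf.add(tt, household.lidar_channel, "lidar", "y", ys)
    return t0 + duration


def _temp_profile(
    buf: _EventBuffer,
    channel: str,
    t0: float,
    rise_s: float,
    hold_until: float,
    decay_s: float,
    baseline: float,
    amplitude: float,
    cadence: float = 60.0,
) -> None:
    """Dense ramp-hold-decay temperature trace for one heating episode."""
    t_end = hold_until + decay_s
    tt = np.arange(t0, t_end + cadence, cadence)
    temp = np.full(tt.shape, baseline)
    ramp = tt <= t0 + rise_s
    temp[ramp] = baseline + amplitude * (tt[ramp] - t0) / rise_s
    hold = (tt > t0 + rise_s) & (tt <= hold_until)
    temp[hold] = baseline + amplitude
    decay = tt > hold_until
    temp[decay] = baseline + amplitude * np.exp(-(tt[decay] - hold_until) / (decay_s / 3.0))
    buf.add(tt, channel, "temp_humidity", "temp_c", temp)
    buf.add(tt, channel, "temp_humidity", "rh", 45.0 + 0.5 * (temp - baseline))


def simulate_person_day(
    profile: PersonProfile, date, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate one calendar day of sensor events for one person.

    Returns a time-sorted long-format event table (see
    :mod:`adlhome.events`).  The generative script is: sleep until a
    wake-up after 05:00, scheduled meals / medication / grooming / chores
    / TV / mat sessions and at most one daytime outing, ambient motion in
    the occupied zone, lidar walks on zone changes, and Poisson night
    activity inside 00:00-05:00.
    """
    day = pd.Timestamp(date).normalize()
    p = profile.behavior
    hh = profile.household
    buf = _EventBuffer(day, profile.person_id)
    scale = p.task_duration_scale

    wake = float(np.clip(rng.normal(6.5 * HOUR, 1800.0), 5.1 * HOUR, 8.5 * HOUR))
    sleep = float(np.clip(rng.normal(22.5 * HOUR, 1800.0), 21 * HOUR, 23.9 * HOUR))

    # minute-resolution occupancy: 0 = asleep/absent, else zone id
    zone_min = np.zeros(1440, dtype=np.int64)
    zone_min[int(wake // 60) : int(sleep // 60)] = 2  # default: living room

    def occupy(t0: float, t1: float, zone: int) -> None:
        zone_min[max(int(t0 // 60), 0) : min(int(t1 // 60) + 1, 1440)] = zone

    outing: tuple[float, float] | None = None
    if rng.random() < p.outing_prob:
        leave = rng.uniform(10 * HOUR, 15 * HOUR)
        dur = rng.uniform(1.0 * HOUR, 3.0 * HOUR)
        outing = (leave, min(leave + dur, 19 * HOUR))

    plug_intervals: dict[str, list[tuple[float, float, float]]] = {}

    def plug_on(role: str, t0: float, t1: float, watts: float) -> None:
        if t1 > t0:
            plug_intervals.setdefault(hh.role(role), []).append((t0, t1, watts))

    # --- meals -----------------------------------------------------------
    kitchen_appliances = ("refrigerator", "rice_cooker", "kitchen_sink", "cupboard_door")
    stove = hh.role("stove_temp")
    for meal, (h0, h1) in MEAL_WINDOWS.items():
        if rng.random() >= p.meal_cook_prob.get(meal, 0.0):
            continue
        w0 = max(h0 * HOUR, wake + 600.0) if meal == "breakfast" else h0 * HOUR
        w1 = h1 * HOUR - 2400.0
        if w0 >= w1:
            continue
        t0 = rng.uniform(w0, w1)
        cook_dur = rng.uniform(12 * 60, 25 * 60) * scale
        occupy(t0, t0 + cook_dur, 4)
        _temp_profile(
            buf, stove, t0, rise_s=480.0, hold_until=t0 + cook_dur,
            decay_s=720.0, baseline=22.0, amplitude=5.0,
        )
        for role in kitchen_appliances:
            ch = hh.role(role)
            if role == "rice_cooker" and meal == "lunch" and rng.random() < 0.5:
                continue
            if rng.random() < p.appliance_coherence:
                u0 = rng.uniform(t0, t0 + max(cook_dur - 90.0, 60.0))
            elif rng.random() < 0.7:
                u0 = rng.uniform(wake + 300.0, sleep - 600.0)  # incoherent scatter
            else:
                continue
            u1 = u0 + rng.uniform(20.0, 80.0)
            if hh.channels[ch] == "door":
                _door_toggle(buf, ch, u0, u1)
            else:
                _tilt_use(buf, rng, ch, u0, u1)
        if rng.random() < 0.25:  # microwave also used while cooking
            m0 = rng.uniform(t0, t0 + cook_dur)
            _door_toggle(buf, hh.role("microwave_door"), m0, m0 + rng.uniform(30, 90))
        if rng.random() < 0.85:  # dishes afterwards
            d0 = t0 + cook_dur + rng.uniform(300.0, 1200.0)
            d1 = d0 + rng.uniform(60.0, 240.0) * scale
            occupy(d0, d1, 4)
            _tilt_use(buf, rng, hh.role("kitchen_sink"), d0, d1)

    if rng.random() < 0.3:  # heating food: microwave without the stove
        m0 = rng.uniform(max(wake + 1800.0, 10.2 * HOUR), 11.5 * HOUR)
        _door_toggle(buf, hh.role("microwave_door"), m0, m0 + rng.uniform(60, 180))
    if rng.random() < 0.5:  # stray short sink use (< 30 s, below dishes rule)
        s0 = rng.uniform(wake + 600.0, sleep - 600.0)
        _tilt_use(buf, rng, hh.role("kitchen_sink"), s0, s0 + rng.uniform(8.0, 25.0))

    # --- medication ------------------------------------------------------
    for dose_h in (8.0, 13.0, 19.0, 21.5):
        if rng.random() >= p.med_adherence_prob:
            continue
        t0 = dose_h * HOUR + rng.normal(0.0, p.med_time_jitter * 60.0)
        t0 = float(np.clip(t0, wake + 60.0, sleep - 120.0))
        if outing and outing[0] <= t0 <= outing[1]:
            continue
        _tilt_use(buf, rng, hh.role("pill_organizer"), t0, t0 + rng.uniform(20.0, 60.0))

    # --- grooming --------------------------------------------------------
    g0 = wake + rng.uniform(600.0, 1800.0)
    g1 = g0 + rng.uniform(70.0, 180.0) * scale
    occupy(g0, g1, 5)
    _tilt_use(buf, rng, hh.role("bathroom_faucet"), g0, g1)
    if rng.random() < 0.6:  # evening shower (+ hairdryer)
        s0 = sleep - rng.uniform(1.0 * HOUR, 2.0 * HOUR)
        s1 = s0 + rng.uniform(8 * 60, 12 * 60) * scale
        occupy(s0, s1 + 300.0, 5)
        _tilt_use(buf, rng, hh.role("showerhead"), s0, s1)
        _temp_profile(
            buf, hh.role("bathroom_temp"), s0, rise_s=300.0, hold_until=s1,
            decay_s=900.0, baseline=22.0, amplitude=3.0, cadence=120.0,
        )
        if rng.random() < 0.7:
            _tilt_use(buf, rng, hh.role("hairdryer"), s1 + 120.0, s1 + 120.0 + rng.uniform(150, 300))
    for _ in range(rng.poisson(2.0)):  # short basin uses during the day
        b0 = rng.uniform(wake + 1800.0, sleep - 1800.0)
        _tilt_use(buf, rng, hh.role("bathroom_faucet"), b0, b0 + rng.uniform(15.0, 45.0))

    # --- chores ----------------------------------------------------------
    if rng.random() < 1.0 / 3.0:
        w0 = rng.uniform(9 * HOUR, 16 * HOUR)
        plug_on("washer_plug", w0, w0 + 40 * 60 * scale, 500.0)
    if rng.random() < 0.2:
        v0 = rng.uniform(9 * HOUR, 17 * HOUR)
        _tilt_use(buf, rng, hh.role("vacuum"), v0, v0 + rng.uniform(400.0, 900.0))
    if rng.random() < 0.3:
        f0 = rng.uniform(12 * HOUR, 17 * HOUR)
        _tilt_use(buf, rng, hh.role("fan"), f0, f0 + rng.uniform(1200.0, 3600.0))
    if rng.random() < 0.4:
        b0 = rng.uniform(wake + 600.0, sleep - 600.0)
        _tilt_use(buf, rng, hh.role("bin"), b0, b0 + rng.uniform(5.0, 15.0))

    # --- TV and electric mat --------------------------------------------
    tv_on = sleep - rng.uniform(0.25 * HOUR, 0.5 * HOUR)
    plug_on("tv_plug", max(sleep - 3.2 * HOUR, 18 * HOUR), tv_on, 80.0)
    if rng.random() < 0.5:
        t0 = wake + rng.uniform(0.5 * HOUR, 1.0 * HOUR)
        plug_on("tv_plug", t0, min(t0 + rng.uniform(0.5 * HOUR, 1.5 * HOUR), 11.9 * HOUR), 80.0)
    if rng.random() < 0.15:
        m0 = rng.uniform(12.5 * HOUR, 14.5 * HOUR)
        plug_on("mat_plug", m0, m0 + rng.uniform(0.5 * HOUR, 1.5 * HOUR), 60.0)
    if rng.random() < 0.5:  # warms the bed before sleep
        plug_on("mat_plug", sleep - 0.5 * HOUR, min(sleep + 1.0 * HOUR, 24 * HOUR - 60.0), 60.0)

    # --- outing ----------------------------------------------------------
    if outing:
        leave, ret = outing
        occupy(leave, ret, 0)
        forgot = rng.random() < p.forget_appliance_on_prob
        if forgot:
            role = "tv_plug" if rng.random() < 0.7 else "mat_plug"
            plug_on(role, leave - 900.0, ret + 900.0, 80.0 if role == "tv_plug" else 60.0)
        # sessions on the other channels still cannot toggle while nobody
        # is home: clip them at the departure (diligent exit for those)
        for ch in (hh.role("tv_plug"), hh.role("mat_plug")):
            if forgot and ch == hh.role(role):
                continue
            plug_intervals[ch] = [
                (t0, t1, w)
                for t0, t1, w in _clip_intervals(plug_intervals.get(ch, []), leave, ret)
            ]
        _door_toggle(buf, hh.role("entrance_door"), leave, leave + 15.0)
        _door_toggle(buf, hh.role("entrance_door"), ret, ret + 15.0)
        _motion_hits(buf, hh.role("living_motion"), np.array([leave - 90.0, ret + rng.uniform(60.0, 240.0)]))
        if rng.random() < 0.5 and ret + 1500.0 < sleep:  # TV soon after returning
            plug_on("tv_plug", ret + rng.uniform(120.0, 1500.0), ret + rng.uniform(2400.0, 5400.0), 80.0)

    # --- night activity (00:00-05:00) ------------------------------------
    n_night = rng.poisson(p.night_activity_rate * 5.0)
    for _ in range(n_night):
        t0 = rng.uniform(0.0, NIGHT_END_S - 1800.0)
        kind = rng.choice(5, p=[0.4, 0.2, 0.1, 0.15, 0.15])
        if kind == 0:  # restless motion in a random zone
            zone = int(rng.integers(1, 7))
            ch = _primary_motion(hh, zone)
            _motion_hits(buf, ch, t0 + np.sort(rng.uniform(0, 600.0, rng.integers(2, 6))))
        elif kind == 1:  # bathroom visit
            _motion_hits(buf, _primary_motion(hh, 5), np.array([t0]))
            _tilt_use(buf, rng, hh.role("bathroom_faucet"), t0 + 60.0, t0 + 60.0 + rng.uniform(20.0, 60.0))
        elif kind == 2:  # fridge raid
            _motion_hits(buf, _primary_motion(hh, 4), np.array([t0]))
            _tilt_use(buf, rng, hh.role("refrigerator"), t0 + 30.0, t0 + 30.0 + rng.uniform(20.0, 60.0))
        elif kind == 3:  # TV or mat on at night
            if rng.random() < 0.6:
                plug_on("tv_plug", t0, t0 + rng.uniform(600.0, 1800.0), 80.0)
            else:
                plug_on("mat_plug", t0, t0 + rng.uniform(1200.0, 3600.0), 60.0)
            _motion_hits(buf, hh.role("living_motion"), np.array([t0 - 30.0]))
        else:  # wander across zones with the lidar watching
            zones = rng.permutation(np.arange(1, 7))[: rng.integers(2, 5)]
            t = t0
            for z0, z1 in zip(zones[:-1], zones[1:]):
                t = _walk(buf, rng, hh, t, int(z0), int(z1), p) + rng.uniform(30.0, 120.0)
                _motion_hits(buf, _primary_motion(hh, int(z1)), np.array([t - 15.0]))

    # --- ambient motion + walks from the occupancy timeline --------------
    runs = _runs(zone_min)
    prev_zone = 1  # starts the day in the bedroom
    for start_min, end_min, zone in runs:
        t0, t1 = start_min * 60.0, end_min * 60.0
        if zone == 0:
            continue
        if zone != prev_zone:
            _walk(buf, rng, hh, t0, prev_zone, zone, p)
        prev_zone = zone
        rate_s = 10.0 / HOUR  # ~10 detections/h on the occupied zone's sensor
        n_hits = rng.poisson(rate_s * (t1 - t0))
        if n_hits:
            _motion_hits(buf, _primary_motion(hh, zone), np.sort(rng.uniform(t0, t1, n_hits)))
    if prev_zone != 1:
        _walk(buf, rng, hh, sleep, prev_zone, 1, p)  # retire to the bedroom

    # --- flush plug intervals as power-transition events ------------------
    for ch, intervals in plug_intervals.items():
        for t0, t1, w in _merge_plug(intervals):
            buf.add([t0, t1], ch, "plug", "power_w", [w, 0.0])

    # --- background: padding channels and slow temperature baselines ------
    _background(buf, rng, hh, wake, sleep, outing)

    return buf.frame()


def _clip_intervals(
    intervals: list[tuple[float, float, float]], cut0: float, cut1: float
) -> list[tuple[float, float, float]]:
    out = []
    for t0, t1, w in intervals:
        if t1 <= cut0 or t0 >= cut1:
            out.append((t0, t1, w))
            continue
        if t0 < cut0:
            out.append((t0, cut0, w))
        if t1 > cut1:
            out.append((cut1, t1, w))
    return out


def _merge_plug(intervals: list[tuple[float, float, float]]) -> list[tuple[float, float, float]]:
    """Merge overlapping on-intervals so emitted transitions are well formed."""
    out: list[tuple[float, float, float]] = []
    for t0, t1, w in sorted(intervals):
        if out and t0 <= out[-1][1]:
            p0, p1, pw = out[-1]
            out[-1] = (p0, max(p1, t1), max(pw, w))
        else:
            out.append((t0, t1, w))
    return out


def _runs(zone_min: np.ndarray) -> list[tuple[int, int, int]]:
    change = np.flatnonzero(np.diff(zone_min)) + 1
    bounds = np.concatenate(([0], change, [len(zone_min)]))
    return [
        (int(bounds[i]), int(bounds[i + 1]), int(zone_min[bounds[i]]))
        for i in range(len(bounds) - 1)
    ]


def _primary_motion(hh: HouseholdConfig, zone: int) -> str:
    for ch in hh.channels_of_type("motion"):
        if hh.zone_map.sensor_placements.get(ch) == zone:
            return ch
    return hh.role("living_motion")


def _background(
    buf: _EventBuffer,
    rng: np.random.Generator,
    hh: HouseholdConfig,
    wake: float,
    sleep: float,
    outing: tuple[float, float] | None,
) -> None:
    """Sparse daytime noise on padding channels; slow temp baselines.

    Everything here is confined to 05:00-24:00 so the late-night window
    stays silent unless persona night activity produces events, and
    occupancy-driven noise (motion, doors, appliance touches) pauses
    while the resident is out.
    """
    core = {ch for ch in hh.roles.values()}
    day0 = max(NIGHT_END_S + 60.0, wake - 1800.0)

    def home_times(n: int) -> np.ndarray:
        t = rng.uniform(day0, sleep, n)
        if outing is not None:
            t = t[(t < outing[0] - 120.0) | (t > outing[1] + 120.0)]
        return np.sort(t)

    for ch, st in sorted(hh.channels.items()):
        if ch in core:
            continue
        if st == "door":
            for t0 in home_times(rng.poisson(1.0)):
                _door_toggle(buf, ch, t0, t0 + rng.uniform(10.0, 60.0))
        elif st == "vibration":
            for t0 in home_times(rng.poisson(1.0)):
                _tilt_use(buf, rng, ch, t0, t0 + rng.uniform(15.0, 60.0))
        elif st == "plug":
            if rng.random() < 0.1:
                tt = home_times(1)
                if len(tt):
                    buf.add(
                        [tt[0], tt[0] + rng.uniform(600.0, 1800.0)], ch, "plug", "power_w", [30.0, 0.0]
                    )
        elif st == "motion":
            _motion_hits(buf, ch, home_times(rng.poisson(3.0)))
        elif st == "temp_humidity":
            tt = np.arange(day0, 24 * HOUR, 1800.0)
            temp = 21.5 + 0.6 * np.sin((tt / HOUR - 8.0) / 24.0 * 2 * np.pi) + rng.normal(0, 0.1, tt.size)
            buf.add(tt, ch, "temp_humidity", "temp_c", temp)
            buf.add(tt, ch, "temp_humidity", "rh", 45.0 + rng.normal(0, 1.0, tt.size))
    # baseline cadence for the two episode-bearing temp channels
    for role in ("stove_temp", "bathroom_temp"):
        ch = hh.role(role)
        tt = np.arange(day0, 24 * HOUR, 600.0)
        buf.add(tt, ch, "temp_humidity", "temp_c", 22.0 + rng.normal(0, 0.08, tt.size))
        buf.add(tt, ch, "temp_humidity", "rh", 45.0 + rng.normal(0, 0.5, tt.size))


def _draw_profile(
    person_id: str,
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    household: HouseholdConfig,
) -> PersonProfile:
    if group == "normal":
        lo, hi = config.mmse_range_normal
        template = config.normal_behavior
        cdr = 0.0
    else:
        lo, hi = config.mmse_range_dementia
        template = config.dementia_behavior
        cdr = 0.5 if rng.random() < 1.0 / 6.0 else 1.0
    mmse = int(rng.integers(lo, hi + 1))
    j = config.persona_jitter

    def jp(x: float) -> float:
        return float(np.clip(x + rng.normal(0, j), 0.0, 1.0))

    behavior = replace(
        template,
        meal_cook_prob={k: jp(v) for k, v in template.meal_cook_prob.items()},
        appliance_coherence=jp(template.appliance_coherence),
        med_adherence_prob=jp(template.med_adherence_prob),
        outing_prob=jp(template.outing_prob),
        gait_speed_mean=float(max(template.gait_speed_mean * (1 + rng.normal(0, j / 2)), 0.2)),
        night_activity_rate=float(max(template.night_activity_rate * (1 + rng.normal(0, j)), 0.0)),
    )
    return PersonProfile(
        person_id=person_id, group=group, mmse=mmse, cdr=cdr,
        household=household, behavior=behavior,
    )


def generate_cohort(
    config: CohortConfig, seed: int
) -> tuple[list[PersonProfile], dict[str, pd.DataFrame]]:
    """Generate profiles and per-person event logs for a whole cohort.

    Deterministic given ``(config, seed)``: person- and day-level random
    streams are spawned from a single root ``SeedSequence``.
    """
    config.validate()
    household = config.household or reference_household()
    root = np.random.SeedSequence(seed)
    groups = ["normal"] * config.n_normal + ["dementia"] * config.n_dementia
    person_seeds = root.spawn(len(groups))
    start = pd.Timestamp(config.start_date)
    profiles: list[PersonProfile] = []
    logs: dict[str, pd.DataFrame] = {}
    for i, (group, pseed) in enumerate(zip(groups, person_seeds)):
        person_id = f"P{i + 1:02d}"
        prof_rng = np.random.default_rng(pseed)
        profile = _draw_profile(person_id, group, config, prof_rng, household)
        day_seeds = pseed.spawn(config.days)
        frames = [
            simulate_person_day(profile, start + pd.Timedelta(days=d), np.random.default_rng(ds))
            for d, ds in enumerate(day_seeds)
        ]
        logs[person_id] = sort_events(pd.concat(frames, ignore_index=True))
        profiles.append(profile)
    return profiles, logs


def profiles_frame(profiles: list[PersonProfile]) -> pd.DataFrame:
    """Cohort profile table (person_id, group, mmse, cdr)."""
    return pd.DataFrame(
        {
            "person_id": [p.person_id for p in profiles],
            "group": [p.group for p in profiles],
            "mmse": [p.mmse for p in profiles],
            "cdr": [p.cdr for p in profiles],
        }
    )
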