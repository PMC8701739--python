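"""Reference household: floor plan zones, sensor roster and channel roles.

A monitored dwelling is described by a :class:`ZoneMap` (six axis-aligned
rectangular zones in a floor-plan-local metric frame, origin at the
southwest corner) and a :class:`HouseholdConfig` listing every installed
sensor channel, its modality and the zone it sits in.  The packaged
:func:`reference_household` is the roster the feature schema is sized
against: 65 per-channel sensors (door, motion, smart plug,
temperature-humidity, vibration) plus one 2-D lidar tracker.

Channel ids follow the field's terse convention: ``d*`` door, ``m*``
motion, ``p*`` smart plug, ``t*`` temperature-humidity, ``v*`` vibration,
``lidar1`` for the tracker.  Functional roles (entrance door, TV plug,
pill organizer, ...) are resolved through :attr:`HouseholdConfig.roles`
so downstream ADL rules never hard-code channel ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SENSOR_TYPES = ("door", "motion", "vibration", "temp_humidity", "plug", "lidar")

#: payload field names expected per sensor modality (long event format)
PAYLOAD_FIELDS = {
    "door": ("state",),
    "motion": ("detected", "lux"),
    "vibration": ("x", "y", "z"),
    "temp_humidity": ("temp_c", "rh"),
    "plug": ("power_w",),
    "lidar": ("x", "y"),
}


@dataclass(frozen=True)
class Zone:
    zone_id: int
    name: str
    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    @property
    def centroid(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)


@dataclass(frozen=True)
class ZoneMap:
    """Six-zone partition of the dwelling with sensor placements."""

    zones: tuple[Zone, ...]
    sensor_placements: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.zones) != 6:
            raise ValueError(f"expected exactly 6 zones, got {len(self.zones)}")
        ids = [z.zone_id for z in self.zones]
        if sorted(ids) != list(range(1, 7)):
            raise ValueError("zone ids must be 1..6")
        for a in self.zones:
            for b in self.zones:
                if a.zone_id < b.zone_id and _overlap(a, b):
                    raise ValueError(f"zones {a.zone_id} and {b.zone_id} overlap")
        known = set(ids)
        for ch, z in self.sensor_placements.items():
            if z not in known:
                raise ValueError(f"channel {ch} placed in unknown zone {z}")

    def zone_of(self, zone_id: int) -> Zone:
        for z in self.zones:
            if z.zone_id == zone_id:
                return z
        raise KeyError(zone_id)

    def locate(self, x: float, y: float) -> int:
        """Zone id containing (x, y); nearest zone centroid if outside all."""
        for z in self.zones:
            if z.contains(x, y):
                return z.zone_id
        d = [(np.hypot(x - z.centroid[0], y - z.centroid[1]), z.zone_id) for z in self.zones]
        return min(d)[1]

    def locate_array(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`locate`; out-of-plan points snap to nearest centroid."""
        out = np.zeros(len(x), dtype=np.int64)
        for z in self.zones:
            inside = (x >= z.x0) & (x < z.x1) & (y >= z.y0) & (y < z.y1)
            out[inside] = z.zone_id
        missing = out == 0
        if missing.any():
            cx = np.array([z.centroid[0] for z in self.zones])
            cy = np.array([z.centroid[1] for z in self.zones])
            ids = np.array([z.zone_id for z in self.zones])
            d2 = (x[missing, None] - cx) ** 2 + (y[missing, None] - cy) ** 2
            out[missing] = ids[np.argmin(d2, axis=1)]
        return out


def _overlap(a: Zone, b: Zone) -> bool:
    return a.x0 < b.x1 and b.x0 < a.x1 and a.y0 < b.y1 and b.y0 < a.y1


@dataclass(frozen=True)
class HouseholdConfig:
    """Installed channel roster with modalities, placements and roles.

    ``channels`` maps channel_id -> sensor_type for every per-channel
    sensor (lidar excluded: it contributes trajectory features, not
    count/duration columns).  ``roles`` maps a functional role name used
    by the ADL rules to a channel id.
    """

    zone_map: ZoneMap
    channels: dict[str, str]
    roles: dict[str, str]
    lidar_channel: str = "lidar1"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ch, st in self.channels.items():
            if ch in seen:
                raise ValueError(f"duplicate channel id {ch}")
            seen.add(ch)
            if st not in SENSOR_TYPES:
                raise ValueError(f"unknown sensor type {st} for {ch}")
        for role, ch in self.roles.items():
            if ch not in self.channels:
                raise ValueError(f"role {role} points at unknown channel {ch}")

    def channels_of_type(self, sensor_type: str) -> list[str]:
        return sorted(ch for ch, st in self.channels.items() if st == sensor_type)

    def role(self, name: str) -> str:
        return self.roles[name]


def reference_zone_map() -> ZoneMap:
    """10 m x 8 m single-occupant flat partitioned into the six study zones."""
    zones = (
        Zone(1, "bedroom", 0.0, 0.0, 4.0, 4.0),
        Zone(2, "living_room", 4.0, 0.0, 10.0, 4.0),
        Zone(3, "entrance", 8.0, 4.0, 10.0, 8.0),
        Zone(4, "kitchen", 4.0, 4.0, 8.0, 8.0),
        Zone(5, "bathroom", 2.0, 4.0, 4.0, 8.0),
        Zone(6, "utility", 0.0, 4.0, 2.0, 8.0),
    )
    return ZoneMap(zones=zones, sensor_placements=_reference_placements())


# role -> (channel id, sensor type, zone). The first block carries the ADL
# rules; the rest pad the roster to the 65 per-channel sensors the feature
# schema is sized for (ambient motion, spare doors/plugs/vibration).
_CORE = [
    ("entrance_door", "d1", "door", 3),
    ("microwave_door", "d2", "door", 4),
    ("cupboard_door", "d3", "door", 4),
    ("tv_plug", "p1", "plug", 2),
    ("mat_plug", "p2", "plug", 1),
    ("washer_plug", "p3", "plug", 6),
    ("stove_temp", "t1", "temp_humidity", 4),
    ("bathroom_temp", "t2", "temp_humidity", 5),
    ("refrigerator", "v1", "vibration", 4),
    ("rice_cooker", "v2", "vibration", 4),
    ("kitchen_sink", "v3", "vibration", 4),
    ("pill_organizer", "v4", "vibration", 2),
    ("bathroom_faucet", "v5", "vibration", 5),
    ("showerhead", "v6", "vibration", 5),
    ("hairdryer", "v7", "vibration", 5),
    ("fan", "v8", "vibration", 2),
    ("vacuum", "v9", "vibration", 6),
    ("bin", "v10", "vibration", 4),
    ("living_motion", "m4", "motion", 2),
    ("kitchen_motion", "m10", "motion", 4),
]

_PAD_DOORS = [("d4", 1), ("d5", 6), ("d6", 5), ("d7", 1), ("d8", 2)]
_PAD_PLUGS = [("p4", 2), ("p5", 4), ("p6", 1), ("p7", 2), ("p8", 1), ("p9", 6), ("p10", 5)]
_PAD_TEMPS = [("t3", 2), ("t4", 1), ("t5", 4), ("t6", 3)]
# three motion sensors per zone (m4/m10 are the designated living/kitchen ones)
_MOTION = [(f"m{i}", ((i - 1) % 6) + 1) for i in range(1, 19)]
_PAD_VIBS = [(f"v{i}", ((i - 11) % 6) + 1) for i in range(11, 24)]


def _reference_placements() -> dict[str, int]:
    placements: dict[str, int] = {}
    for _, ch, _, zone in _CORE:
        placements[ch] = zone
    for ch, zone in _PAD_DOORS + _PAD_PLUGS + _PAD_TEMPS + _PAD_VIBS:
        placements[ch] = zone
    for ch, zone in _MOTION:
        placements.setdefault(ch, zone)
    placements["lidar1"] = 2
    return placements


def reference_household() -> HouseholdConfig:
    """The packaged 65-channel reference roster (plus lidar)."""
    channels: dict[str, str] = {}
    roles: dict[str, str] = {}
    for role, ch, st, _ in _CORE:
        channels[ch] = st
        roles[role] = ch
    for ch, _ in _PAD_DOORS:
        channels[ch] = "door"
    for ch, _ in _PAD_PLUGS:
        channels[ch] = "plug"
    for ch, _ in _PAD_TEMPS:
        channels[ch] = "temp_humidity"
    for ch, _ in _MOTION:
        channels.setdefault(ch, "motion")
    for ch, _ in _PAD_VIBS:
        channels[ch] = "vibration"
    return HouseholdConfig(zone_map=reference_zone_map(), channels=channels, roles=roles)
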