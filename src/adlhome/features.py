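"""Person-hour feature table assembly.

The reference schema has 195 columns: 132 IoT-side features (one count
and one active-duration column per roster channel, 65 each, plus lidar
movement distance and mean gait speed) and 63 ADL-side features (31
activity features, each as a count and a duration column, plus one
count-only medication total).  Counts are nonnegative integers per hour;
durations are seconds in [0, 3600].

Labels join from the cohort profile table only; nothing in the feature
values encodes the group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adl import ADLEpisode, OutingRecord, TV_AFTER_RETURN_S
from .household import HouseholdConfig
from .preprocess import BinnedSeries

LIDAR_FEATURES = ("lidar_distance_m", "lidar_gait_speed_kmh")

#: the 31 ADL activity features (each contributes a count and a duration
#: column); ``medication_total`` below is the one count-only extra.
ADL_BASE_FEATURES = (
    # indoor wandering
    "movement_in_room",
    "night_wandering",
    # unlocking and closing the entrance door
    "going_out",
    "no_lock",
    # household chores
    "laundering",
    "washing_dishes",
    # cooking
    "cooking",
    "breakfast_cooking",
    "lunch_cooking",
    "dinner_cooking",
    "cooking_over_30min",
    "cooking_stove_microwave",
    "cooking_fridge_sink",
    "cooking_fridge_stove",
    "cooking_sink_ricecooker",
    "heating_food",
    # taking medications
    "medication_morning",
    "medication_lunch",
    "medication_evening",
    "medication_bedtime",
    # grooming
    "grooming_night",
    "grooming_shower",
    "grooming_faucet_over_1min",
    "grooming_faucet_total",
    # using household appliances
    "tv_total",
    "tv_morning",
    "tv_night",
    "tv_after_return",
    "mat_total",
    "mat_daytime",
    "mat_night",
)

ADL_COUNT_ONLY = ("medication_total",)


@dataclass(frozen=True)
class FeatureSchema:
    iot_duration_names: tuple[str, ...]
    iot_count_names: tuple[str, ...]
    lidar_names: tuple[str, ...]
    adl_duration_names: tuple[str, ...]
    adl_count_names: tuple[str, ...]
    channels: tuple[str, ...]

    @property
    def iot_names(self) -> tuple[str, ...]:
        return self.iot_count_names + self.iot_duration_names + self.lidar_names

    @property
    def adl_names(self) -> tuple[str, ...]:
        return self.adl_count_names + self.adl_duration_names

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.iot_names + self.adl_names

    def counts(self) -> dict[str, int]:
        return {
            "iot_duration": len(self.iot_duration_names),
            "iot_count": len(self.iot_count_names),
            "lidar": len(self.lidar_names),
            "iot_total": len(self.iot_names),
            "adl_duration": len(self.adl_duration_names),
            "adl_count": len(self.adl_count_names),
            "adl_total": len(self.adl_names),
            "total": len(self.all_names),
        }


def feature_schema(
    household: HouseholdConfig,
    include_lidar: bool = True,
    include_adl: bool = True,
) -> FeatureSchema:
    """Instantiate the deterministic, sorted feature name set for a roster."""
    channels = tuple(sorted(household.channels))
    if len(set(channels)) != len(channels):
        raise ValueError("duplicate channel ids in roster")
    iot_count = tuple(f"iot_count_{ch}" for ch in channels)
    iot_dur = tuple(f"iot_dur_{ch}" for ch in channels)
    lidar = LIDAR_FEATURES if include_lidar else ()
    if include_adl:
        adl_dur = tuple(f"adl_dur_{name}" for name in ADL_BASE_FEATURES)
        adl_count = tuple(
            f"adl_count_{name}" for name in ADL_BASE_FEATURES + ADL_COUNT_ONLY
        )
    else:
        adl_dur = ()
        adl_count = ()
    return FeatureSchema(
        iot_duration_names=iot_dur,
        iot_count_names=iot_count,
        lidar_names=lidar,
        adl_duration_names=adl_dur,
        adl_count_names=adl_count,
        channels=channels,
    )


def _bin_spans(
    spans: list[tuple[pd.Timestamp, pd.Timestamp]],
    grid: pd.DatetimeIndex,
    width_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Count (start bin) and overlap duration per bin for [start, end] spans."""
    n = len(grid)
    counts = np.zeros(n)
    durs = np.zeros(n)
    if not spans:
        return counts, durs
    g0 = grid[0].value / 1e9
    for s_ts, e_ts in spans:
        s = s_ts.value / 1e9
        e = e_ts.value / 1e9
        b0 = int((s - g0) // width_s)
        if 0 <= b0 < n:
            counts[b0] += 1
        b_lo = max(b0, 0)
        b_hi = min(int((e - g0) // width_s), n - 1)
        for b in range(b_lo, b_hi + 1):
            lo = g0 + b * width_s
            overlap = min(e, lo + width_s) - max(s, lo)
            if overlap > 0:
                durs[b] += overlap
    return counts, np.minimum(durs, width_s)


def build_features(
    binned: BinnedSeries,
    adls: list[ADLEpisode],
    outings: list[OutingRecord],
    wandering: pd.DataFrame,
    lidar: tuple[pd.DataFrame, pd.Series] | None,
    schema: FeatureSchema,
    person_id: str,
) -> pd.DataFrame:
    """Assemble one person's hourly feature rows.

    Inputs must share the grid of ``binned`` (hourly).  Hours with no
    data are zero-filled.  The result has ``person_id`` and ``bin_start``
    columns plus every schema feature; labels are joined later from the
    cohort profile table.
    """
    grid = binned.counts.index
    width_s = binned.bin_width.total_seconds()
    n = len(grid)
    data: dict[str, np.ndarray] = {}

    for ch in schema.channels:
        data[f"iot_count_{ch}"] = (
            binned.counts[ch].to_numpy(dtype=float) if ch in binned.counts else np.zeros(n)
        )
        data[f"iot_dur_{ch}"] = (
            binned.durations[ch].to_numpy() if ch in binned.durations else np.zeros(n)
        )

    if schema.lidar_names:
        dist = np.zeros(n)
        speed = np.zeros(n)
        if lidar is not None:
            gait, dist_per_bin = lidar
            if len(dist_per_bin):
                aligned = dist_per_bin.reindex(grid, fill_value=0.0)
                dist = aligned.to_numpy()
            if len(gait):
                by_bin = gait.set_index(pd.DatetimeIndex(gait["timestamp"]).floor(binned.bin_width))[
                    "speed_kmh"
                ].groupby(level=0).mean()
                speed = by_bin.reindex(grid, fill_value=0.0).to_numpy()
        data["lidar_distance_m"] = dist
        data["lidar_gait_speed_kmh"] = speed

    if schema.adl_names:
        unknown = {
            ch
            for e in adls
            for ch in e.contributing_channels
            if ch not in schema.channels
        }
        if unknown:
            raise ValueError(f"ADL episodes reference channels outside the roster: {sorted(unknown)}")
        tv_after_starts = _tv_after_return_spans(adls, outings)
        selectors = _adl_selectors(adls, outings, tv_after_starts)
        for base in ADL_BASE_FEATURES + ADL_COUNT_ONLY:
            if base in ("movement_in_room", "night_wandering"):
                continue  # handled from wandering metrics below
            spans = selectors.get(base, [])
            counts, durs = _bin_spans(spans, grid, width_s)
            if f"adl_count_{base}" in schema.adl_count_names:
                data[f"adl_count_{base}"] = counts
            if f"adl_dur_{base}" in schema.adl_duration_names:
                data[f"adl_dur_{base}"] = durs

        night_mask = np.asarray(grid.hour < 5, dtype=float)
        if wandering is not None and len(wandering):
            w = wandering.reindex(grid, fill_value=0.0)
            stay_cols = [f"zone{z}_stay_s" for z in range(1, 7) if f"zone{z}_stay_s" in w]
            nonliving = [c for c in stay_cols if c != "zone2_stay_s"]
            data["adl_count_movement_in_room"] = w.get("room_transitions", pd.Series(0.0, index=grid)).to_numpy()
            data["adl_dur_movement_in_room"] = np.minimum(
                w[nonliving].sum(axis=1).to_numpy() if nonliving else np.zeros(n), width_s
            )
            data["adl_count_night_wandering"] = w.get("night_events", pd.Series(0.0, index=grid)).to_numpy()
            stay_total = w[stay_cols].sum(axis=1).to_numpy() if stay_cols else np.zeros(n)
            data["adl_dur_night_wandering"] = np.minimum(stay_total, width_s) * night_mask
        else:
            for name in (
                "adl_count_movement_in_room",
                "adl_dur_movement_in_room",
                "adl_count_night_wandering",
                "adl_dur_night_wandering",
            ):
                data[name] = np.zeros(n)

    out = pd.DataFrame(data, index=grid)
    for name in schema.all_names:  # zero-fill anything not produced
        if name not in out:
            out[name] = 0.0
    out = out[list(schema.all_names)]
    out.insert(0, "bin_start", grid)
    out.insert(0, "person_id", person_id)
    return out.reset_index(drop=True)


def _tv_after_return_spans(
    adls: list[ADLEpisode], outings: list[OutingRecord]
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    returns = [o.return_ for o in outings]
    spans = []
    for e in adls:
        if e.adl_type != "using_appliances" or "tv" not in e.tags:
            continue
        if any(0.0 <= (e.start - r).total_seconds() <= TV_AFTER_RETURN_S for r in returns):
            spans.append((e.start, e.end))
    return spans


def _adl_selectors(
    adls: list[ADLEpisode],
    outings: list[OutingRecord],
    tv_after: list[tuple[pd.Timestamp, pd.Timestamp]],
) -> dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]]:
    """Map each base feature to its [start, end] spans."""

    def pick(adl_type: str, tag: str | None = None):
        return [
            (e.start, e.end)
            for e in adls
            if e.adl_type == adl_type and (tag is None or tag in e.tags)
        ]

    sel = {
        "going_out": [(o.leave, o.return_) for o in outings],
        "no_lock": [(o.leave, o.return_) for o in outings if not o.lock_ok],
        "laundering": pick("household_chores", "laundering"),
        "washing_dishes": pick("household_chores", "dishes"),
        "cooking": pick("cooking"),
        "breakfast_cooking": pick("cooking", "breakfast"),
        "lunch_cooking": pick("cooking", "lunch"),
        "dinner_cooking": pick("cooking", "dinner"),
        "cooking_over_30min": pick("cooking", "over_30min"),
        "cooking_stove_microwave": pick("cooking", "pair_stove_microwave"),
        "cooking_fridge_sink": pick("cooking", "pair_fridge_sink"),
        "cooking_fridge_stove": pick("cooking", "pair_fridge_stove"),
        "cooking_sink_ricecooker": pick("cooking", "pair_sink_ricecooker"),
        "heating_food": pick("heating_food"),
        "medication_morning": pick("taking_medications", "morning"),
        "medication_lunch": pick("taking_medications", "lunch"),
        "medication_evening": pick("taking_medications", "evening"),
        "medication_bedtime": pick("taking_medications", "bedtime"),
        "medication_total": pick("taking_medications"),
        "grooming_night": pick("grooming", "nighttime"),
        "grooming_shower": pick("grooming", "shower"),
        "grooming_faucet_over_1min": pick("grooming", "over_1min"),
        "grooming_faucet_total": pick("grooming", "faucet"),
        "tv_total": pick("using_appliances", "tv"),
        "tv_morning": pick("using_appliances", "tv_morning"),
        "tv_night": pick("using_appliances", "tv_night"),
        "tv_after_return": tv_after,
        "mat_total": pick("using_appliances", "mat"),
        "mat_daytime": pick("using_appliances", "mat_daytime"),
        "mat_night": pick("using_appliances", "mat_night"),
    }
    return sel


def attach_labels(features: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Join group labels from the cohort profile table (the only label source)."""
    labeled = features.merge(profiles[["person_id", "group"]], on="person_id", how="left")
    if labeled["group"].isna().any():
        missing = labeled.loc[labeled["group"].isna(), "person_id"].unique()
        raise ValueError(f"no profile for persons {sorted(missing)}")
    return labeled.rename(columns={"group": "label"})
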