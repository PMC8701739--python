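"""End-to-end orchestration: simulate -> preprocess -> infer -> featurize
-> personalize -> stats -> evaluate, reproducibly from one config.

:func:`run_all` executes every stage and writes CSV artifacts plus a
manifest to a run directory; rerunning with the same config reproduces
every artifact byte-identically.  The in-memory stage functions
(:func:`featurize_person`, :func:`cohort_feature_tables`) are reusable on
their own and are what the examples and tests drive.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, stats
from .adl import infer_all
from .events import write_event_log
from .features import FeatureSchema, attach_labels, build_features, feature_schema
from .household import HouseholdConfig, reference_household
from .personalize import personalize_table
from .preprocess import (
    bin_counts_durations,
    extract_episodes,
    lidar_kinematics,
    lidar_track,
    zone_visits,
)
from .simulate import CohortConfig, generate_cohort, profiles_frame

STAGES = ("simulate", "preprocess", "featurize", "personalize", "stats", "evaluate")

#: appliance roles whose daily counts feed the correlation analysis
CORRELATION_ROLES = (
    "entrance_door",
    "microwave_door",
    "stove_temp",
    "tv_plug",
    "washer_plug",
    "pill_organizer",
    "refrigerator",
    "rice_cooker",
    "kitchen_sink",
    "bathroom_faucet",
)


@dataclass
class RunConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    bin_width: str = "1h"
    personalization_mode: str = "augment"
    min_history_bins: int = 24
    folds: int = 10
    n_estimators: int = classify.RF_N_ESTIMATORS
    out_dir: str = "runs/default"
    write_event_logs: bool = True

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        payload = asdict(self)
        payload["cohort"].pop("household", None)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def observation_grid(config: CohortConfig, bin_width: str = "1h") -> pd.DatetimeIndex:
    start = pd.Timestamp(config.start_date)
    per_day = {"10min": 144, "1h": 24, "1d": 1}[bin_width]
    return pd.date_range(start, periods=config.days * per_day, freq=bin_width)


def featurize_person(
    events: pd.DataFrame,
    household: HouseholdConfig,
    schema: FeatureSchema,
    grid: pd.DatetimeIndex,
    bin_width: pd.Timedelta,
    person_id: str,
) -> pd.DataFrame:
    """Events -> hourly feature rows for one person (preprocess + infer + build)."""
    stream_end = grid[-1] + bin_width
    episodes, points = extract_episodes(events, household, stream_end=stream_end)
    track = lidar_track(events, household)
    gait, dist = lidar_kinematics(track)
    visits = zone_visits(track, household.zone_map)
    adls, outings, wandering = infer_all(
        episodes, points, visits, events, grid, bin_width, household, person_id
    )
    binned = bin_counts_durations(
        episodes,
        points,
        bin_width,
        grid,
        person_id=person_id,
        duration_only=set(points),  # door/motion count from their point stamps
    )
    return build_features(binned, adls, outings, wandering, (gait, dist), schema, person_id)


def cohort_feature_tables(
    config: CohortConfig,
    seed: int,
    personalization_mode: str = "augment",
    min_history_bins: int = 24,
) -> tuple[pd.DataFrame, pd.DataFrame, FeatureSchema, pd.DataFrame]:
    """Simulate a cohort and build its labelled raw and personalized tables.

    Returns ``(raw, personalized, schema, profiles)`` where both tables
    carry person_id, bin_start, features and label columns.
    """
    household = config.household or reference_household()
    schema = feature_schema(household)
    profiles, logs = generate_cohort(config, seed)
    prof_df = profiles_frame(profiles)
    grid = observation_grid(config)
    width = pd.Timedelta("1h")
    parts = [
        featurize_person(logs[p.person_id], household, schema, grid, width, p.person_id)
        for p in profiles
    ]
    raw = attach_labels(pd.concat(parts, ignore_index=True), prof_df)
    personalized = personalize_table(
        raw.drop(columns=["label"]),
        prof_df,
        schema.all_names,
        min_history=min_history_bins,
        mode=personalization_mode,
    )
    personalized = attach_labels(personalized, prof_df)
    return raw, personalized, schema, prof_df


def _daily_appliance_counts(
    raw: pd.DataFrame, household: HouseholdConfig
) -> pd.DataFrame:
    """Per person-day appliance counts for the correlation analysis."""
    cols = {}
    for role in CORRELATION_ROLES:
        ch = household.roles.get(role)
        col = f"iot_count_{ch}"
        if col in raw.columns:
            cols[role] = col
    day = pd.DatetimeIndex(raw["bin_start"]).normalize()
    grouped = (
        raw.assign(date=day)
        .groupby(["person_id", "label", "date"], sort=True)[list(cols.values())]
        .sum()
        .reset_index()
    )
    return grouped.rename(columns={v: k for k, v in cols.items()})


def run_all(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Artifacts: ``profiles.csv``, per-person event logs, the raw and
    personalized feature tables, the group-comparison and correlation
    reports, the six-cell model summary and ``manifest.json`` recording
    the config hash and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    household = config.cohort.household or reference_household()

    raw, personalized, schema, prof_df = cohort_feature_tables(
        config.cohort,
        stage_seed(config.seed, "simulate"),
        personalization_mode=config.personalization_mode,
        min_history_bins=config.min_history_bins,
    )
    prof_df.to_csv(out / "profiles.csv", index=False)
    if config.write_event_logs:
        ev_dir = out / "events"
        ev_dir.mkdir(exist_ok=True)
        _, logs = generate_cohort(config.cohort, stage_seed(config.seed, "simulate"))
        for pid, ev in logs.items():
            write_event_log(ev, ev_dir / f"{pid}.csv")
    raw.to_csv(out / "features_raw.csv", index=False)
    personalized.to_csv(out / "features_personalized.csv", index=False)

    sig_vars = [f"iot_count_{household.roles[r]}" for r in CORRELATION_ROLES] + [
        "lidar_gait_speed_kmh",
        "lidar_distance_m",
    ]
    comparison = stats.compare_groups(raw, [v for v in sig_vars if v in raw.columns])
    comparison.to_csv(out / "group_comparison.csv", index=False)

    daily = _daily_appliance_counts(raw, household)
    matrices, diffs = stats.appliance_correlations(
        daily.drop(columns=["person_id", "date"]), label_col="label"
    )
    for grp, m in matrices.items():
        m.to_csv(out / f"correlation_{grp}.csv")
    diffs.to_csv(out / "correlation_differences.csv", index=False)

    reports = classify.run_matrix(
        raw,
        personalized,
        schema,
        folds=config.folds,
        seed=stage_seed(config.seed, "evaluate"),
        n_estimators=config.n_estimators,
    )
    classify.summary_table(reports).to_csv(out / "model_summary.csv", index=False)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(STAGES),
        "n_rows": int(len(raw)),
        "n_features": len(schema.all_names),
        "schema_counts": schema.counts(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
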