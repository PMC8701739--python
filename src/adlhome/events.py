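"""Sensor event log schema and I/O.

Events are rows of a long-format table with columns
``timestamp, person_id, channel_id, sensor_type, field, value``; one
physical sensor reading may span several rows (a vibration tilt sample is
three rows x/y/z, a lidar fix two rows x/y).  The on-disk format is plain
CSV with ISO-8601 timestamps, one file per person, and round-trips
losslessly through :func:`write_event_log` / :func:`read_event_log`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .household import PAYLOAD_FIELDS, SENSOR_TYPES

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["timestamp", "person_id", "channel_id", "sensor_type", "field", "value"]


def empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp": pd.Series([], dtype="datetime64[ns]"),
            "person_id": pd.Series([], dtype=object),
            "channel_id": pd.Series([], dtype=object),
            "sensor_type": pd.Series([], dtype=object),
            "field": pd.Series([], dtype=object),
            "value": pd.Series([], dtype=float),
        }
    )


def sort_events(events: pd.DataFrame) -> pd.DataFrame:
    """Stable time order with a deterministic tie-break on channel/field."""
    return events.sort_values(
        ["timestamp", "channel_id", "field"], kind="mergesort"
    ).reset_index(drop=True)


def validate_events(events: pd.DataFrame) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    bad = set(events["sensor_type"].unique()) - set(SENSOR_TYPES)
    if bad:
        raise ValueError(f"unknown sensor types {sorted(bad)}")


def write_event_log(events: pd.DataFrame, path: str | Path) -> None:
    """Write one person's events as CSV (header always present)."""
    validate_events(events)
    out = sort_events(events).copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, columns=EVENT_COLUMNS)


def read_event_log(path: str | Path) -> pd.DataFrame:
    """Parse an event-log CSV.

    Unparseable timestamps raise; rows with an unknown sensor type are
    skipped with a warning carrying their line numbers.  The result is
    time-sorted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"person_id": str, "channel_id": str})
    if df.empty:
        return empty_events()
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        lines = (df.index[ts.isna()] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: unparseable timestamps at lines {lines[:10]}")
    df["timestamp"] = ts
    val = pd.to_numeric(df["value"], errors="coerce")
    bad_val = val.isna() & df["value"].notna()
    known = df["sensor_type"].isin(SENSOR_TYPES)
    drop = bad_val | ~known
    if drop.any():
        for line in (df.index[drop] + 2).tolist():
            logger.warning("%s: skipping malformed line %d", path, line)
        df = df[~drop]
        val = val[~drop]
    df = df.assign(value=val.astype(float))
    return sort_events(df[EVENT_COLUMNS])


def summary_report(events: pd.DataFrame) -> pd.DataFrame:
    """Per-day detection counts, one column per channel.

    Mirrors the study's day-unit example table: door/motion/vibration/plug
    counts are state-change or detection tallies, temperature channels
    count sampled readings.  Counts here are raw row-group tallies per
    physical sample (a tilt sample's three axis rows count once).
    """
    if events.empty:
        return pd.DataFrame()
    ev = events.copy()
    ev["date"] = ev["timestamp"].dt.normalize()
    # collapse multi-row samples (same timestamp+channel) to one detection
    samples = ev.drop_duplicates(["timestamp", "channel_id"])
    table = (
        samples.groupby(["date", "channel_id"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    table.index.name = "date"
    return table


def events_from_records(records: list[tuple], person_id: str) -> pd.DataFrame:
    """Build an event table from (timestamp, channel, sensor_type, field, value) tuples."""
    if not records:
        return empty_events()
    ts, ch, st, fld, val = zip(*records)
    df = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(list(ts)),
            "person_id": person_id,
            "channel_id": list(ch),
            "sensor_type": list(st),
            "field": list(fld),
            "value": np.asarray(val, dtype=float),
        }
    )
    return sort_events(df)
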