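"""Shared fixtures: reference household, small synthetic cohorts and
hand-built event tables.  Everything is generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adlhome.events import events_from_records
from adlhome.household import reference_household
from adlhome.pipeline import cohort_feature_tables
from adlhome.simulate import CohortConfig


@pytest.fixture(scope="session")
def household():
    return reference_household()


@pytest.fixture(scope="session")
def small_cohort_tables():
    """Raw + personalized tables for a 4-person, 5-day cohort (seed 7)."""
    cfg = CohortConfig(n_normal=2, n_dementia=2, days=5)
    return cohort_feature_tables(cfg, seed=7)


def make_events(records, person_id="PX"):
    """(timestamp str, channel, sensor_type, field, value) tuples -> event table."""
    return events_from_records(records, person_id)


def tilt_pair(channel, t_dev, t_rest, dev=(0.8, 0.0, 0.6)):
    """Records for one vibration use: deviated tilt at t_dev, resting at t_rest."""
    recs = []
    for fld, dv, rv in zip(("x", "y", "z"), dev, (0.0, 0.0, 1.0)):
        recs.append((t_dev, channel, "vibration", fld, dv))
        recs.append((t_rest, channel, "vibration", fld, rv))
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def hourly_grid():
    return pd.date_range("2021-03-01", periods=24, freq="1h")
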