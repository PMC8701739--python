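"""Cognitive-ability-stratified IQR anomaly personalization.

Each person gets a per-feature normal range built from their own history:
lower = Q1 - k * IQR, upper = Q3 + k * IQR, where the multiplier k
shrinks with cognitive level (MMSE 30 -> 1.5, 27-29 -> 1.2, 24-26 -> 1.0,
<= 23 -> 0.5), so stricter anomaly criteria apply at lower cognitive
ability.  Baselines are causal: the range scored against a bin uses only
strictly earlier bins, with a minimum history before any flag is raised.
The personalized dataset augments the raw features with per-bin
``anomaly_<feature>`` indicators (optionally replacing them); rolling
per-day anomaly counts are available separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: (group label, k) by MMSE band — highest band first
MMSE_BANDS = (
    (30, "no_decline", 1.5),
    (27, "very_mild", 1.2),
    (24, "mild", 1.0),
    (0, "moderate", 0.5),
)

K_VALUES = (1.5, 1.2, 1.0, 0.5)
MIN_HISTORY_BINS = 24


@dataclass(frozen=True)
class CognitiveProfile:
    person_id: str
    mmse: int
    group_label: str
    k: float


@dataclass
class AnomalyBaseline:
    """Per-feature quartile summary of one person's history."""

    person_id: str
    q1: pd.Series
    q3: pd.Series
    k: float
    n_history: int
    min_history: int = MIN_HISTORY_BINS

    @property
    def iqr(self) -> pd.Series:
        return self.q3 - self.q1

    @property
    def lower(self) -> pd.Series:
        return self.q1 - self.k * self.iqr

    @property
    def upper(self) -> pd.Series:
        return self.q3 + self.k * self.iqr

    @property
    def available(self) -> bool:
        return self.n_history >= self.min_history


def assign_cognitive_group(mmse: int, person_id: str = "") -> CognitiveProfile:
    """Map an MMSE score to its cognitive band and IQR multiplier k."""
    if not 0 <= mmse <= 30:
        raise ValueError(f"MMSE {mmse} outside 0..30")
    for lo, label, k in MMSE_BANDS:
        if mmse >= lo:
            return CognitiveProfile(person_id=person_id, mmse=mmse, group_label=label, k=k)
    raise AssertionError("unreachable")


def fit_baseline(
    history: pd.DataFrame | pd.Series | np.ndarray,
    k: float,
    person_id: str = "",
    min_history: int = MIN_HISTORY_BINS,
) -> AnomalyBaseline:
    """Quartile baseline (linear-interpolation quantiles) from history rows."""
    if k not in K_VALUES:
        raise ValueError(f"k must be one of {K_VALUES}")
    if isinstance(history, (pd.Series, np.ndarray, list)):
        history = pd.DataFrame({"value": np.asarray(history, dtype=float)})
    n = len(history)
    q1 = history.quantile(0.25)
    q3 = history.quantile(0.75)
    return AnomalyBaseline(
        person_id=person_id, q1=q1, q3=q3, k=k, n_history=n, min_history=min_history
    )


def is_anomalous(
    values: pd.Series | float, baseline: AnomalyBaseline, feature: str | None = None
) -> pd.Series | bool:
    """Flag observations of one feature outside its [lower, upper] range.

    ``feature`` defaults to the Series name (or the baseline's only
    feature); an unavailable baseline flags nothing.
    """
    if feature is None:
        if isinstance(values, pd.Series) and values.name in baseline.q1.index:
            feature = values.name
        else:
            feature = baseline.q1.index[0]
    if not baseline.available:
        return False if np.isscalar(values) else pd.Series(False, index=values.index)
    lo = float(baseline.lower[feature])
    hi = float(baseline.upper[feature])
    return (values < lo) | (values > hi)


def _causal_bounds(
    values: pd.DataFrame, k: float, min_history: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expanding causal Q1/Q3 bounds per column (history strictly before each row)."""
    q1 = values.expanding(min_periods=min_history).quantile(0.25).shift(1)
    q3 = values.expanding(min_periods=min_history).quantile(0.75).shift(1)
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def anomaly_transform(
    features: pd.DataFrame,
    profile: CognitiveProfile,
    feature_names: list[str] | tuple[str, ...],
    min_history: int = MIN_HISTORY_BINS,
    mode: str = "augment",
) -> pd.DataFrame:
    """Score one person's time-ordered feature rows against causal baselines.

    Adds an ``anomaly_<feature>`` 0/1 column per feature (1 where the raw
    value falls outside the person's personalized range; 0 where the
    baseline history is still shorter than ``min_history`` bins).
    ``mode="augment"`` keeps the raw columns, ``mode="replace"`` drops
    them.
    """
    if "person_id" in features.columns:
        pids = features["person_id"].unique()
        if len(pids) != 1 or (profile.person_id and pids[0] != profile.person_id):
            raise ValueError("feature rows do not match the cognitive profile's person")
    vals = features[list(feature_names)].astype(float)
    lower, upper = _causal_bounds(vals, profile.k, min_history)
    flags = ((vals < lower) | (vals > upper)).fillna(False).astype(np.int8)
    flags.columns = [f"anomaly_{c}" for c in feature_names]
    if mode == "replace":
        keep = features.drop(columns=list(feature_names))
        return pd.concat([keep, flags], axis=1)
    if mode != "augment":
        raise ValueError("mode must be 'augment' or 'replace'")
    return pd.concat([features, flags], axis=1)


def anomaly_day_counts(personalized: pd.DataFrame, bins_per_day: int = 24) -> pd.DataFrame:
    """Rolling per-day anomaly counts per feature (trailing ``bins_per_day`` bins)."""
    anom_cols = [c for c in personalized.columns if c.startswith("anomaly_")]
    rolled = (
        personalized[anom_cols]
        .rolling(bins_per_day, min_periods=1)
        .sum()
        .astype(int)
    )
    rolled.columns = [c.replace("anomaly_", "anomaly_day_") for c in anom_cols]
    return rolled


def personalize_table(
    features: pd.DataFrame,
    profiles: pd.DataFrame,
    feature_names: list[str] | tuple[str, ...],
    min_history: int = MIN_HISTORY_BINS,
    mode: str = "augment",
) -> pd.DataFrame:
    """Apply :func:`anomaly_transform` person-by-person to a cohort table.

    ``profiles`` must carry person_id and mmse; rows must be time-ordered
    within person (they are sorted by bin_start defensively).
    """
    mmse_by_person = profiles.set_index("person_id")["mmse"].to_dict()
    parts = []
    for pid, rows in features.groupby("person_id", sort=True):
        if pid not in mmse_by_person:
            raise ValueError(f"no MMSE for person {pid}")
        prof = assign_cognitive_group(int(mmse_by_person[pid]), person_id=str(pid))
        rows = rows.sort_values("bin_start")
        parts.append(anomaly_transform(rows, prof, feature_names, min_history, mode))
    return pd.concat(parts, ignore_index=True)
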