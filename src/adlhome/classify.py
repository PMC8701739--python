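"""Random-forest classification of normal vs early-stage dementia with
10-fold cross-validation, confusion-matrix metrics and the
personalized/raw x IoT/ADL/IoT+ADL evaluation matrix.

The positive class is *dementia*.  Pooled metrics are recomputed from the
summed confusion counts across folds (never averaged percentages), which
is unbiased under unequal fold sizes.  Fold construction is record-level
stratified (person-hours from both groups are pooled); an optional
leave-one-person-out grouping is provided as a leakage diagnostic and is
an explicit deviation from the pooled design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .features import FeatureSchema
from .shapley import shapley_importance

POSITIVE_LABEL = "dementia"
RF_N_ESTIMATORS = 500


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    pos = y_true == 1
    return ConfusionMatrix(
        tp=int(np.sum(pos & (y_pred == 1))),
        fp=int(np.sum(~pos & (y_pred == 1))),
        fn=int(np.sum(pos & (y_pred == 0))),
        tn=int(np.sum(~pos & (y_pred == 0))),
    )


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Precision, recall, F1 (harmonic mean) and accuracy from counts.

    Undefined ratios (zero denominator) are reported as NaN; an all-zero
    matrix raises.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else float("nan")
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else float("nan")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = 0.0 if (precision == 0 or recall == 0) else float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    accuracy = (cm.tp + cm.tn) / cm.total
    return {"precision": precision, "recall": recall, "f1": f1, "accuracy": accuracy}


@dataclass
class ModelReport:
    feature_set: str  # e.g. "IoT+ADL/personalized"
    fold_matrices: list[ConfusionMatrix]
    pooled: ConfusionMatrix = field(init=False)
    pooled_metrics: dict[str, float] = field(init=False)
    importance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        pooled = ConfusionMatrix(0, 0, 0, 0)
        for cm in self.fold_matrices:
            pooled = pooled + cm
        self.pooled = pooled
        self.pooled_metrics = metrics(pooled)


def _encode_labels(labels: pd.Series | np.ndarray) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OU":
        return (arr == POSITIVE_LABEL).astype(int)
    return arr.astype(int)


def make_forest(seed: int, n_estimators: int = RF_N_ESTIMATORS) -> RandomForestClassifier:
    """The study's classifier with the package's documented defaults:
    ``n_estimators`` trees, sqrt(p) features per split, unlimited depth."""
    return RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )


def crossval(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    folds: int = 10,
    seed: int = 0,
    n_estimators: int = RF_N_ESTIMATORS,
    feature_set: str = "all",
    groups: np.ndarray | None = None,
) -> ModelReport:
    """Stratified k-fold random-forest evaluation, deterministic given seed.

    ``groups`` switches to grouped (leave-persons-out) folds — the
    leakage diagnostic, not the default design.
    """
    y = _encode_labels(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes for cross-validation")
    if groups is None and counts.min() < folds:
        raise ValueError(f"need >= {folds} rows per class for {folds}-fold stratification")
    X = features.to_numpy(dtype=float)
    if groups is not None:
        splitter = GroupKFold(n_splits=folds)
        split = splitter.split(X, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
        split = splitter.split(X, y)
    fold_matrices = []
    for i, (train, test) in enumerate(split):
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {i} has one class only")
        clf = make_forest(seed + i, n_estimators)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        fold_matrices.append(confusion_from_predictions(y[test], pred))
    return ModelReport(feature_set=feature_set, fold_matrices=fold_matrices)


def fit_full(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    seed: int = 0,
    n_estimators: int = RF_N_ESTIMATORS,
) -> RandomForestClassifier:
    clf = make_forest(seed, n_estimators)
    clf.fit(features, _encode_labels(labels))
    return clf


def select_columns(
    table: pd.DataFrame,
    schema: FeatureSchema,
    feature_set: str,
    personalized: bool,
) -> list[str]:
    """Feature columns for one evaluation-matrix cell.

    ``feature_set`` in {"iot", "adl", "both"}; the personalized variant
    adds the ``anomaly_`` indicator of every selected raw feature.
    """
    if feature_set == "iot":
        base = list(schema.iot_names)
    elif feature_set == "adl":
        base = list(schema.adl_names)
    elif feature_set == "both":
        base = list(schema.all_names)
    else:
        raise ValueError("feature_set must be iot, adl or both")
    cols = [c for c in base if c in table.columns]
    if personalized:
        cols += [f"anomaly_{c}" for c in base if f"anomaly_{c}" in table.columns]
    return cols


def run_matrix(
    raw_table: pd.DataFrame,
    personalized_table: pd.DataFrame,
    schema: FeatureSchema,
    label_col: str = "label",
    folds: int = 10,
    seed: int = 0,
    n_estimators: int = RF_N_ESTIMATORS,
    with_importance: bool = False,
) -> dict[str, ModelReport]:
    """The six-cell evaluation: {IoT, ADL, IoT+ADL} x {raw, personalized}."""
    reports: dict[str, ModelReport] = {}
    for fs, fs_label in (("iot", "IoT"), ("adl", "ADL"), ("both", "IoT+ADL")):
        for personalized, table in ((False, raw_table), (True, personalized_table)):
            cols = select_columns(table, schema, fs, personalized)
            name = f"{fs_label}/{'personalized' if personalized else 'raw'}"
            report = crossval(
                table[cols], table[label_col], folds=folds, seed=seed,
                n_estimators=n_estimators, feature_set=name,
            )
            if with_importance:
                clf = fit_full(table[cols], table[label_col], seed=seed, n_estimators=n_estimators)
                report.importance = shapley_importance(clf, table[cols], seed=seed)
            reports[name] = report
    return reports


def summary_table(reports: dict[str, ModelReport]) -> pd.DataFrame:
    """Precision/recall/F1/accuracy per cell as percentages (2 d.p.)."""
    rows = []
    for name, rep in reports.items():
        m = rep.pooled_metrics
        rows.append(
            {
                "feature_set": name,
                "precision_pct": round(100 * m["precision"], 2),
                "recall_pct": round(100 * m["recall"], 2),
                "f1_pct": round(100 * m["f1"], 2),
                "accuracy_pct": round(100 * m["accuracy"], 2),
            }
        )
    return pd.DataFrame(rows)
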