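"""Seeded permutation-sampling Shapley attribution for tabular classifiers.

Estimates each feature's Shapley value for the positive-class predicted
probability by Monte-Carlo over feature orderings: for a random
permutation, features are switched one at a time from a background row's
value to the explained row's value, and the change in model output is
that feature's marginal contribution.  Averaging over permutations and
background pairings converges to the exact Shapley value; a fixed seed
makes runs reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def shapley_values(
    predict,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Per-row, per-feature Shapley estimates for ``predict`` (rows x features).

    ``predict`` maps an (n, p) array to an (n,) score (e.g. positive-class
    probability).  Each permutation pairs every explained row with one
    background row drawn with replacement.
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    phi = np.zeros((n, p))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        z = background[rng.integers(0, len(background), n)].copy()
        prev = predict(z)
        for j in order:
            z[:, j] = X[:, j]
            cur = predict(z)
            phi[:, j] += cur - prev
            prev = cur
    return phi / n_permutations


def shapley_importance(
    model,
    X: pd.DataFrame,
    background: pd.DataFrame | None = None,
    n_permutations: int = 20,
    max_rows: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean |Shapley value| feature ranking for a fitted classifier.

    Explains at most ``max_rows`` rows (deterministic subsample) against a
    background of the same table.  Returns a frame (feature,
    mean_abs_shap) sorted by decreasing importance.
    """
    names = list(X.columns)
    if hasattr(model, "feature_names_in_"):
        missing = set(model.feature_names_in_) ^ set(names)
        if missing:
            raise ValueError(f"model/feature mismatch: {sorted(missing)}")
        X = X[list(model.feature_names_in_)]
        names = list(X.columns)
    rng = np.random.default_rng(seed)
    arr = X.to_numpy(dtype=float)
    rows = arr
    if len(arr) > max_rows:
        rows = arr[rng.choice(len(arr), max_rows, replace=False)]
    bg = background.to_numpy(dtype=float) if background is not None else arr
    if len(bg) > max_rows:
        bg = bg[rng.choice(len(bg), max_rows, replace=False)]

    def predict(z: np.ndarray) -> np.ndarray:
        proba = model.predict_proba(pd.DataFrame(z, columns=names))
        return proba[:, -1]

    phi = shapley_values(predict, rows, bg, n_permutations=n_permutations, seed=seed)
    importance = np.abs(phi).mean(axis=0)
    return (
        pd.DataFrame({"feature": names, "mean_abs_shap": importance})
        .sort_values("mean_abs_shap", ascending=False, ignore_index=True)
    )
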