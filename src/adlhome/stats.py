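"""Two-group statistical battery: normality, rank-sum comparison and
Spearman correlation structure of appliance use.

The comparison workflow mirrors the field's standard recipe: Shapiro-Wilk
normality per group first; when either group departs from normality the
non-parametric Wilcoxon rank-sum (Mann-Whitney) test compares the groups,
otherwise Welch's t (a branch rarely taken on count data).  The Spearman
coefficient is computed from the classical rank-difference formula
r = 1 - 6 * sum(d_i^2) / (n (n^2 - 1)) when ranks are tie-free, and as
the product-moment correlation of average ranks otherwise (the formula
assumes distinct ranks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
EXACT_RANKSUM_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int = 0

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def spearman_r(x, y) -> float:
    """Spearman rank correlation.

    Tie-free inputs use the exact rank-difference formula; ties fall back
    to Pearson correlation of average ranks.  Constant input has no
    defined rank correlation and returns NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined", RuntimeWarning)
        return float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    if tie_free:
        d = rx - ry
        return float(1.0 - 6.0 * np.sum(d * d) / (n * (n * n - 1.0)))
    return float(np.corrcoef(rx, ry)[0, 1])


def shapiro_wilk(sample) -> TestResult:
    """Shapiro-Wilk normality test (valid for n in 3..5000)."""
    a = np.asarray(sample, dtype=float)
    if not 3 <= len(a) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns near n=5000
        stat, p = sps.shapiro(a)
    return TestResult("shapiro_wilk", float(stat), float(p), len(a))


def wilcoxon_rank_sum(a, b, method: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``method='auto'`` uses the exact null distribution when both samples
    have n <= 20 and no ties, and the normal approximation with
    continuity correction otherwise.  The reported statistic is the
    rank-sum W of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        small = max(len(a), len(b)) <= EXACT_RANKSUM_MAX_N
        no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        method = "exact" if small and no_ties else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic) + len(a) * (len(a) + 1) / 2.0  # U -> rank-sum W
    return TestResult("wilcoxon_rank_sum", w, float(res.pvalue), len(a), len(b))


def compare_groups(
    table: pd.DataFrame,
    variables: list[str],
    label_col: str = "label",
    group_a: str = "normal",
    group_b: str = "dementia",
    alpha: float = ALPHA,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-variable two-group comparison with the normality-gated branch.

    Returns a tidy frame (variable, branch, statistic, p_value,
    sw_p_a, sw_p_b, n_a, n_b, significant).  ``fdr=True`` adds a
    Benjamini-Hochberg adjusted p column (off by default, matching
    per-variable alpha reporting).
    """
    rows = []
    for var in variables:
        x = table.loc[table[label_col] == group_a, var].dropna().to_numpy(dtype=float)
        y = table.loc[table[label_col] == group_b, var].dropna().to_numpy(dtype=float)
        if len(x) < 3 or len(y) < 3:
            rows.append((var, "insufficient", np.nan, np.nan, np.nan, np.nan, len(x), len(y)))
            continue
        sw_a = _safe_shapiro(x)
        sw_b = _safe_shapiro(y)
        non_normal = (sw_a < alpha) or (sw_b < alpha)
        if non_normal:
            res = wilcoxon_rank_sum(x, y)
            branch = "wilcoxon"
        else:
            t = sps.ttest_ind(x, y, equal_var=False)
            res = TestResult("welch_t", float(t.statistic), float(t.pvalue), len(x), len(y))
            branch = "t_test"
        rows.append((var, branch, res.statistic, res.p_value, sw_a, sw_b, len(x), len(y)))
    out = pd.DataFrame(
        rows,
        columns=["variable", "branch", "statistic", "p_value", "sw_p_a", "sw_p_b", "n_a", "n_b"],
    )
    out["significant"] = out["p_value"] < alpha
    if fdr:
        out["p_adjusted"] = _benjamini_hochberg(out["p_value"].to_numpy())
        out["significant"] = out["p_adjusted"] < alpha
    return out


def _safe_shapiro(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # constant data: certainly not normal
    if len(x) > 5000:
        x = x[:: len(x) // 5000 + 1]
    return shapiro_wilk(x).p_value


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    return adj


def appliance_correlations(
    daily_counts: pd.DataFrame,
    label_col: str = "label",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Spearman correlation matrix of appliance-use counts per group.

    ``daily_counts`` has one row per person-day, appliance columns and a
    group label.  Returns (matrix per group, pairwise difference listing
    ordered by |r_a - r_b|).
    """
    variables = [c for c in daily_counts.columns if c not in (label_col, "person_id", "date")]
    matrices: dict[str, pd.DataFrame] = {}
    for grp, rows in daily_counts.groupby(label_col):
        m = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
        for va, vb in combinations(variables, 2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                r = spearman_r(rows[va].to_numpy(), rows[vb].to_numpy())
            m.loc[va, vb] = m.loc[vb, va] = r
        matrices[str(grp)] = m
    groups = sorted(matrices)
    diffs = []
    if len(groups) == 2:
        ma, mb = matrices[groups[0]], matrices[groups[1]]
        for va, vb in combinations(variables, 2):
            ra, rb = ma.loc[va, vb], mb.loc[va, vb]
            diffs.append((va, vb, ra, rb, abs(ra - rb)))
    diff = pd.DataFrame(
        diffs, columns=["var_a", "var_b", f"r_{groups[0] if groups else 'a'}", f"r_{groups[-1] if groups else 'b'}", "abs_diff"]
    ).sort_values("abs_diff", ascending=False, ignore_index=True)
    return matrices, diff
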