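"""Spearman correlation, normality/rank-sum battery and the appliance
correlation comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from adlhome.stats import (
    appliance_correlations,
    compare_groups,
    shapiro_wilk,
    spearman_r,
    wilcoxon_rank_sum,
)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_r([1, 2, 3], [3, 6, 9]) == 1.0

    def test_perfect_inverse(self):
        assert spearman_r([1, 2, 3], [9, 6, 3]) == -1.0

    def test_worked_example_point_eight(self):
        # sum d^2 = 4 -> 1 - 24/120
        assert spearman_r([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_matches_rank_pearson_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(4, 60)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert spearman_r(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_ties_match_scipy(self, rng):
        x = rng.integers(0, 4, 30).astype(float)
        y = rng.integers(0, 4, 30).astype(float)
        expected = sps.spearmanr(x, y).statistic
        assert spearman_r(x, y) == pytest.approx(expected, abs=1e-12)

    @given(
        st.lists(st.integers(-(10**6), 10**6), min_size=4, max_size=40, unique=True),
        st.floats(0.1, 5.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_monotone_transform(self, xs, a):
        rng = np.random.default_rng(len(xs))
        y = rng.permutation(len(xs)).astype(float)
        x = np.asarray(xs, dtype=float)
        r0 = spearman_r(x, y)
        r1 = spearman_r(a * x + 2.0, y)  # strictly increasing transforms
        order = np.argsort(np.argsort(x)).astype(float)  # rank map itself
        r2 = spearman_r(order, y)
        assert r0 == pytest.approx(r1, abs=1e-9)
        assert r0 == pytest.approx(r2, abs=1e-9)

    def test_constant_input_undefined(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(spearman_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman_r([1, 2, 3], [1, 2])


class TestRankSum:
    def test_identical_samples_p_near_one(self):
        a = np.arange(10.0)
        res = wilcoxon_rank_sum(a, a.copy())  # full ties: no shift at all
        assert res.p_value > 0.9

    def test_separated_samples_tiny_p(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        assert wilcoxon_rank_sum(a, b).p_value < 1e-3

    def test_exact_matches_permutation_oracle(self, rng):
        """For n <= 8 the exact p agrees with full enumeration over
        label permutations of the rank-sum statistic."""
        from itertools import combinations

        for trial in range(5):
            a = rng.normal(size=5)
            b = rng.normal(size=5)
            res = wilcoxon_rank_sum(a, b)
            pooled = np.concatenate([a, b])
            ranks = sps.rankdata(pooled)
            w_obs = ranks[:5].sum()
            n = len(pooled)
            ws = [ranks[list(idx)].sum() for idx in combinations(range(n), 5)]
            ws = np.array(ws)
            mu = ws.mean()
            p_exact = np.mean(np.abs(ws - mu) >= np.abs(w_obs - mu) - 1e-12)
            assert res.p_value == pytest.approx(p_exact, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0, 2.0])


class TestShapiroWilk:
    def test_rejects_uniform_large_sample(self, rng):
        rejections = sum(
            shapiro_wilk(rng.uniform(size=4000)).p_value < 0.05 for _ in range(5)
        )
        assert rejections == 5

    def test_accepts_normal_sample_mostly(self, rng):
        ps = [shapiro_wilk(rng.normal(size=200)).p_value for _ in range(20)]
        assert np.mean(np.asarray(ps) < 0.05) < 0.3

    def test_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestCompareGroups:
    def _table(self, rng, effect=0.0, dist="lognormal"):
        n = 120
        if dist == "lognormal":
            a = rng.lognormal(0, 0.6, n)
            b = rng.lognormal(effect, 0.6, n)
        else:
            a = rng.normal(0, 1, n)
            b = rng.normal(effect, 1, n)
        return pd.DataFrame(
            {"v": np.concatenate([a, b]), "label": ["normal"] * n + ["dementia"] * n}
        )

    def test_non_normal_data_takes_wilcoxon_branch(self, rng):
        res = compare_groups(self._table(rng, effect=1.0), ["v"])
        assert res.loc[0, "branch"] == "wilcoxon"
        assert res.loc[0, "significant"]

    def test_normal_data_takes_t_branch(self, rng):
        res = compare_groups(self._table(rng, dist="normal"), ["v"])
        assert res.loc[0, "branch"] == "t_test"

    def test_generator_gait_contrast_flagged(self, small_cohort_tables):
        raw, _, _, _ = small_cohort_tables
        moving = raw[raw["lidar_gait_speed_kmh"] > 0]
        res = compare_groups(moving, ["lidar_gait_speed_kmh"])
        assert res.loc[0, "significant"]

    def test_type_one_error_near_alpha(self, rng):
        """Label-permuted comparisons reject at roughly the 5% level."""
        n_sim, hits = 400, 0
        for _ in range(n_sim):
            a = rng.lognormal(0, 1, 30)
            b = rng.lognormal(0, 1, 30)
            hits += wilcoxon_rank_sum(a, b).p_value < 0.05
        assert abs(hits / n_sim - 0.05) < 0.03


class TestApplianceCorrelations:
    def test_identical_groups_have_zero_differences(self, rng):
        base = pd.DataFrame(rng.poisson(5, (30, 3)), columns=["fridge", "sink", "tv"])
        table = pd.concat(
            [base.assign(label="normal"), base.assign(label="dementia")], ignore_index=True
        )
        _, diffs = appliance_correlations(table)
        assert np.allclose(diffs["abs_diff"], 0.0)

    def test_duplicated_variable_gives_unit_correlation(self, rng):
        x = rng.poisson(5, 40).astype(float)
        table = pd.DataFrame({"a": x, "b": x, "label": "normal"})
        mats, _ = appliance_correlations(table)
        assert mats["normal"].loc["a", "b"] == pytest.approx(1.0)

    def test_matrix_is_symmetric_with_unit_diagonal(self, rng):
        table = pd.DataFrame(
            rng.poisson(4, (50, 4)).astype(float), columns=list("abcd")
        ).assign(label="normal")
        mats, _ = appliance_correlations(table)
        m = mats["normal"].to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert (np.abs(m) <= 1.0 + 1e-12).all()

    def test_coherence_contrast_orders_fridge_sink(self):
        """Generator coherence 0.9 vs 0.1 -> higher fridge-sink daily-count
        correlation in the coherent group."""
        from dataclasses import replace

        from adlhome.pipeline import _daily_appliance_counts, cohort_feature_tables
        from adlhome.simulate import CohortConfig, dementia_persona, normal_persona

        cfg = CohortConfig(
            n_normal=3,
            n_dementia=3,
            days=6,
            normal_behavior=replace(normal_persona(), appliance_coherence=0.9),
            dementia_behavior=replace(dementia_persona(), appliance_coherence=0.1),
            persona_jitter=0.01,
        )
        raw, _, _, _ = cohort_feature_tables(cfg, seed=5)
        from adlhome.household import reference_household

        daily = _daily_appliance_counts(raw, reference_household())
        mats, _ = appliance_correlations(daily.drop(columns=["person_id", "date"]))
        r_coherent = mats["normal"].loc["refrigerator", "kitchen_sink"]
        r_incoherent = mats["dementia"].loc["refrigerator", "kitchen_sink"]
        assert r_coherent > r_incoherent
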