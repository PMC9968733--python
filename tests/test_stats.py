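"""Statistical battery: brute-force oracles and dispatch rules."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import chondroprint as cp
from chondroprint.stats import (DunnResult, dunn_all_pairs,
                                percent_change_matrix)


class TestCompareTwoGroups:
    def test_identical_samples_rank_test_p_is_one(self):
        x = np.array([1.0, 1.0, 1.0, 1.0])
        res = cp.compare_two_groups(x, x.copy())
        assert res.test == "mann-whitney"
        assert res.p_value == pytest.approx(1.0)
        assert res.group_means[0] == res.group_means[1]

    def test_mann_whitney_statistic_matches_exhaustive_enumeration(self):
        """U on a 4+4 toy (with a tie) equals the brute-force count of
        (x, y) pairs with x > y plus half the tied pairs."""
        from chondroprint.stats import _mann_whitney

        x = np.array([1.2, 3.4, 2.2, 5.0])
        y = np.array([0.5, 2.2, 4.1, 0.9])
        u_brute = sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0
                      for xi in x for yi in y)
        u, _ = _mann_whitney(x, y)
        assert u == pytest.approx(u_brute)

    def test_rank_p_tracks_exact_permutation_null(self):
        """The tie-corrected normal approximation tracks the exact
        permutation p-value at a moderate separation."""
        from chondroprint.stats import _mann_whitney

        x = np.array([2.0, 5.0, 7.0, 9.0])
        y = np.array([1.0, 3.0, 4.0, 6.0])
        _, p_approx = _mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        u_obs = sum(1.0 for a in x for b in y if a > b)
        stats = []
        for idx in combinations(range(8), 4):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            stats.append(sum(1.0 for a in xs for b in ys if a > b))
        p_exact = np.mean([abs(s - 8) >= abs(u_obs - 8) for s in stats])
        assert p_approx == pytest.approx(p_exact, abs=0.06)

    def test_normal_gate_routes_gaussian_data_to_t_test(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.2, 1, 30)
        res = cp.compare_two_groups(x, y)
        assert res.test == "t-test"
        assert res.normality == (True, True)

    def test_power_for_3sd_shift_at_n8(self):
        """Two Gaussian groups shifted by 3 SD at n=8 are detected in at
        least 99% of replicates."""
        hits = 0
        n_rep = 1000
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            x = rng.normal(0.0, 1.0, 8)
            y = rng.normal(3.0, 1.0, 8)
            hits += cp.compare_two_groups(x, y).significant
        assert hits / n_rep >= 0.99

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            cp.compare_two_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestMultiGroupRanks:
    def test_identical_groups_nothing_significant(self):
        g = [np.full(5, 2.0), np.full(5, 2.0), np.full(4, 2.0)]
        omnibus, pairs = cp.multi_group_ranks(g)
        assert not omnibus.significant
        assert all(not p.significant for p in pairs)

    def test_kruskal_wallis_matches_hand_computed_formula(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        omnibus, _ = cp.multi_group_ranks(groups)
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, no ties
        n = 9
        rbar = [2.0, 5.0, 8.0]
        h = 12.0 / (n * (n + 1)) * sum(
            3 * (r - (n + 1) / 2) ** 2 for r in rbar)
        assert omnibus.statistic == pytest.approx(h)

    def test_dunn_z_matches_independent_mean_rank_formula(self):
        groups = [np.array([1.0, 2.0, 3.0, 4.0]),
                  np.array([2.0, 5.0, 6.0]),
                  np.array([7.0, 8.0, 9.0, 10.0, 11.0])]
        pairs = dunn_all_pairs(groups, gate=True)
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        mean_ranks = [ranks[:4].mean(), ranks[4:7].mean(), ranks[7:].mean()]
        n = len(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        ties = np.sum(counts**3 - counts)
        var = n * (n + 1) / 12 - ties / (12 * (n - 1))
        for p in pairs:
            i, j = p.group_a, p.group_b
            se = np.sqrt(var * (1 / len(groups[i]) + 1 / len(groups[j])))
            assert p.z == pytest.approx((mean_ranks[i] - mean_ranks[j]) / se)

    def test_unequal_group_sizes_supported(self):
        groups = [np.arange(3.0), np.arange(5.0) + 10, np.arange(8.0) + 20]
        omnibus, pairs = cp.multi_group_ranks(groups)
        assert omnibus.significant
        assert len(pairs) == 3

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            cp.multi_group_ranks([[1, 2], [3, 4]])


class TestFoldChange:
    def _table(self, ctrl, trt):
        rows = []
        for d, (c, t) in enumerate(zip(ctrl, trt), start=1):
            rows.append({"donor_id": f"D{d}", "condition": 0, "g": c})
            rows.append({"donor_id": f"D{d}", "condition": 1, "g": t})
        return pd.DataFrame(rows)

    def test_control_vs_itself_is_exactly_one(self):
        t = self._table([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        res = cp.fold_change(t, "g")
        assert res.mode == "fold"
        assert res.mean == pytest.approx(1.0)
        assert np.allclose(res.per_donor["fold"], 1.0)

    def test_direct_ratio(self):
        t = self._table([2.0, 2.0, 2.0], [164.0, 164.0, 164.0])
        res = cp.fold_change(t, "g")
        assert res.mean == pytest.approx(82.0)
        assert res.sem == pytest.approx(0.0)

    def test_low_expressed_controls_switch_to_copies_mode(self):
        t = self._table([0.1, 0.2, 0.3, 0.4], [10.0, 12.0, 14.0, 16.0])
        res = cp.fold_change(t, "g")
        assert res.mode == "copies"
        assert res.low_control_flagged
        assert res.mean == pytest.approx(13.0)

    def test_scale_invariance(self):
        t1 = self._table([2.0, 4.0, 8.0], [6.0, 2.0, 24.0])
        t2 = t1.copy()
        t2["g"] = t2["g"] * 37.0
        assert cp.fold_change(t1, "g").mean == pytest.approx(
            cp.fold_change(t2, "g").mean)


class TestPercentChange:
    def test_simple_increase_and_null(self):
        a = pd.DataFrame({"v": np.linspace(90, 110, 30)})   # mean 100
        b = pd.DataFrame({"v": np.linspace(100, 120, 30)})  # mean 110
        res = percent_change_matrix({"a": a, "b": b},
                                    [("a", "b"), ("a", "a")])
        assert res.percent.loc["v", "a -> b"] == pytest.approx(10.0)
        assert res.percent.loc["v", "a -> a"] == pytest.approx(0.0)
        assert not res.significant.loc["v", "a -> a"]

    def test_scale_invariance_of_percent_change(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"v": rng.lognormal(0, 0.3, 50)})
        b = pd.DataFrame({"v": rng.lognormal(0.2, 0.3, 50)})
        r1 = percent_change_matrix({"a": a, "b": b}, [("a", "b")])
        r2 = percent_change_matrix({"a": a * 5.0, "b": b * 5.0},
                                   [("a", "b")])
        assert r1.percent.loc["v"].values == pytest.approx(
            r2.percent.loc["v"].values)

    def test_unknown_or_empty_condition_rejected(self):
        a = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            percent_change_matrix({"a": a}, [("a", "b")])
        with pytest.raises(ValueError):
            percent_change_matrix({"a": a, "b": a.iloc[:0]}, [("a", "b")])


class TestCorrelogram:
    def _table(self, n=20, seed=3):
        rng = np.random.default_rng(seed)
        cond = np.repeat([0, 1], n // 2)
        area = 100 - 10 * cond + rng.normal(0, 3, n)
        il6 = 2 + 80 * cond + rng.lognormal(0, 0.2, n)
        return pd.DataFrame({"condition": cond, "area": area, "IL-6": il6})

    def test_diagonal_is_one_and_matrix_symmetric(self):
        res = cp.correlogram(self._table())
        assert np.allclose(np.diag(res.r), 1.0)
        assert np.allclose(res.r.values, res.r.values.T, equal_nan=True)

    def test_method_dispatch_categorical_forces_spearman(self):
        res = cp.correlogram(self._table())
        assert res.method.loc["condition", "area"] == "spearman"
        assert res.method.loc["area", "IL-6"] == "pearson"

    def test_spearman_matches_rank_then_pearson_bruteforce(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        y = np.array([2.0, 0.5, 2.5, 1.0, 9.0])
        t = pd.DataFrame({"condition": [0, 0, 1, 1, 0], "a": x, "b": y})
        res = cp.correlogram(t.assign(c=y), variables=["condition", "a"],
                             categorical=("condition",))
        rx = sps.rankdata(t["condition"])
        ry = sps.rankdata(x)
        manual = np.corrcoef(rx, ry)[0, 1]
        assert res.r.loc["condition", "a"] == pytest.approx(manual)

    def test_treatment_shift_yields_significant_positive_spearman(self):
        res = cp.correlogram(self._table())
        assert res.r.loc["condition", "IL-6"] > 0
        assert res.significant.loc["condition", "IL-6"]

    def test_constant_variable_reported_missing(self):
        t = self._table()
        t["flat"] = 5.0
        res = cp.correlogram(t, variables=["condition", "area", "flat"])
        assert np.isnan(res.r.loc["flat", "area"])
        assert res.method.loc["flat", "area"] == "undefined"

    def test_row_permutation_invariance(self):
        t = self._table()
        res1 = cp.correlogram(t)
        res2 = cp.correlogram(t.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(res1.r, res2.r)

    def test_condition_broadcasts_to_cells(self):
        cells = pd.DataFrame({"sample_id": ["s1", "s1", "s2"],
                              "area": [1.0, 2.0, 3.0]})
        samples = pd.DataFrame({"sample_id": ["s1", "s2"],
                                "condition": [0, 1]})
        out = cp.broadcast_condition_to_cells(cells, samples)
        assert list(out["condition"]) == [0, 0, 1]
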