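"""Group-statistics tests: closed-form t, exhaustive permutation oracle,
cluster/BFS oracle, sign consistency, activity contrast, power."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from envconn import (
    ConnMatrix,
    activity_contrast,
    cross_experiment_comparison,
    edgewise_ttest,
    maxstat_correct,
    nbs_cluster_test,
    subsample_sign_consistency,
    ttest_power,
)
from envconn.connectome import EdgeMask, matrix_from_upper
from envconn.envelope import ActivityProfile
from envconn.bands import ALPHA
from envconn.stats import _largest_component, round_half_up

from conftest import full_mask, make_conn


def conns_from_rows(rows: np.ndarray, n_nodes: int, prefix="s"):
    """One ConnMatrix per row of edge values."""
    return [
        ConnMatrix(f"{prefix}{k}", "Alpha", matrix_from_upper(row, n_nodes))
        for k, row in enumerate(rows)
    ]


def bfs_largest_component_edges(edges: list[tuple[int, int]]) -> int:
    """Independent breadth-first-search oracle: edge count of the largest
    connected component of an undirected edge list."""
    if not edges:
        return 0
    adj: dict[int, set[int]] = {}
    for i, j in edges:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    seen: set[int] = set()
    best = 0
    for start in adj:
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        best = max(best, sum(1 for i, j in edges if i in comp))
    return best


class TestEdgewiseTtest:
    def test_identical_groups_zero_t(self, rng):
        rows = rng.standard_normal((4, 6))
        ga = conns_from_rows(rows, 4, "a")
        gb = conns_from_rows(rows, 4, "b")
        t, _ = edgewise_ttest(ga, gb, full_mask(4))
        assert np.allclose(t, 0.0)

    def test_closed_form_pooled_t(self):
        # edge values A={1,2,3}, B={4,5,6}: t = -3.6742, p = 0.0213 (df=4)
        ga = conns_from_rows(np.array([[1.0], [2.0], [3.0]]), 2, "a")
        gb = conns_from_rows(np.array([[4.0], [5.0], [6.0]]), 2, "b")
        t, p = edgewise_ttest(ga, gb, full_mask(2))
        assert t[0, 1] == pytest.approx(-3.6742346141747673, abs=1e-10)
        assert p[0, 1] == pytest.approx(0.021311641128756713, abs=1e-10)

    def test_group_swap_antisymmetry(self, rng):
        ga = [make_conn(rng, 6, f"a{k}") for k in range(5)]
        gb = [make_conn(rng, 6, f"b{k}") for k in range(7)]
        m = full_mask(6)
        t_ab, _ = edgewise_ttest(ga, gb, m)
        t_ba, _ = edgewise_ttest(gb, ga, m)
        assert np.allclose(t_ab, -t_ba)

    def test_zero_variance_edge_flagged_nan(self):
        rows_a = np.array([[1.0, 0.3, 0.2], [1.0, 0.1, -0.1], [1.0, -0.2, 0.4]])
        rows_b = np.array([[1.0, 0.5, 0.3], [1.0, 0.4, -0.2]])
        t, p = edgewise_ttest(conns_from_rows(rows_a, 3, "a"), conns_from_rows(rows_b, 3, "b"),
                              full_mask(3))
        assert np.isnan(t[0, 1]) and np.isnan(p[0, 1])
        assert np.isfinite(t[0, 2])

    def test_planted_shift_power(self):
        # delta = 1.5 pooled sd at n=30/30 detects at p<0.05 nearly always
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            a = r.standard_normal((30, 3))
            b = r.standard_normal((30, 3))
            a[:, 1] += 1.5
            _, p = edgewise_ttest(
                conns_from_rows(a, 3, "a"), conns_from_rows(b, 3, "b"), full_mask(3)
            )
            hits += p[0, 2] < 0.05  # edge index 1 of upper triangle = (0,2)
        assert hits >= 95

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            edgewise_ttest([make_conn(rng, 4)], [make_conn(rng, 4)], full_mask(4))


class TestMaxstatCorrect:
    def test_corrected_dominates_uncorrected(self, rng):
        ga = [make_conn(rng, 8, f"a{k}") for k in range(8)]
        gb = [make_conn(rng, 8, f"b{k}") for k in range(8)]
        m = full_mask(8)
        _, p_unc = edgewise_ttest(ga, gb, m)
        p_corr = maxstat_correct(ga, gb, m, n_perm=300, seed=0)
        iu = np.triu_indices(8, 1)
        assert np.all(p_corr[iu] >= p_unc[iu] - 1e-12)

    def test_matches_exhaustive_enumeration_3v3(self, rng):
        """With 3 vs 3 subjects all 20 label splits are enumerable; corrected
        p must equal the brute-force fraction of splits whose max |t| reaches
        each observed |t|."""
        rows = rng.standard_normal((6, 10))
        ga = conns_from_rows(rows[:3], 5, "a")
        gb = conns_from_rows(rows[3:], 5, "b")
        m = full_mask(5)
        p_corr = maxstat_correct(ga, gb, m, n_perm=5000, seed=1)

        # independent oracle via scipy t-tests over explicit splits
        def tvec(a_idx):
            a = rows[list(a_idx)]
            b = rows[[k for k in range(6) if k not in a_idx]]
            return sps.ttest_ind(a, b, axis=0, equal_var=True).statistic

        obs = np.abs(tvec((0, 1, 2)))
        maxes = [np.max(np.abs(tvec(c))) for c in combinations(range(6), 3)]
        expected = np.array([np.mean([mx >= o - 1e-12 for mx in maxes]) for o in obs])
        iu = np.triu_indices(5, 1)
        assert np.allclose(p_corr[iu], expected, atol=1e-12)

    def test_small_nperm_warns(self, rng):
        ga = [make_conn(rng, 4, f"a{k}") for k in range(6)]
        gb = [make_conn(rng, 4, f"b{k}") for k in range(6)]
        with pytest.warns(RuntimeWarning, match="very small"):
            maxstat_correct(ga, gb, full_mask(4), n_perm=50, seed=0)


class TestClusterTest:
    def test_hand_counted_components(self):
        edges = [(1, 2), (2, 3), (3, 4), (5, 6)]
        edge_nodes = np.array(edges).T
        size_e, size_n, members = _largest_component(
            edge_nodes, np.ones(4, dtype=bool), 8
        )
        assert size_e == 3 and size_n == 4
        assert set(members) == {(1, 2), (2, 3), (3, 4)}

    def test_matches_bfs_oracle_on_random_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 13))
            i, j = np.triu_indices(n, 1)
            present = rng.random(i.shape[0]) < rng.uniform(0.05, 0.5)
            edge_nodes = np.vstack([i, j])
            size, _, _ = _largest_component(edge_nodes, present, n)
            edges = list(zip(i[present].tolist(), j[present].tolist()))
            assert size == bfs_largest_component_edges(edges)

    def test_no_suprathreshold_edges(self, rng):
        rows = rng.standard_normal((8, 6)) * 1e-3
        ga = conns_from_rows(rows[:4], 4, "a")
        gb = conns_from_rows(rows[4:], 4, "b")
        res = nbs_cluster_test(ga, gb, full_mask(4), edge_alpha=1e-9, n_perm=100, seed=0)
        assert res[1].size_edges == 0 and res[1].p == 1.0
        assert res[-1].size_edges == 0 and res[-1].p == 1.0

    def test_planted_cluster_detected(self, rng):
        # strong connected 3-edge positive cluster on nodes 0-1-2-3
        n = 10
        n_edges = n * (n - 1) // 2
        a = rng.standard_normal((20, n_edges))
        b = rng.standard_normal((20, n_edges))
        iu = list(zip(*np.triu_indices(n, 1)))
        for e in [(0, 1), (1, 2), (2, 3)]:
            a[:, iu.index(e)] += 2.0
        res = nbs_cluster_test(
            conns_from_rows(a, n, "a"), conns_from_rows(b, n, "b"),
            full_mask(n), n_perm=300, seed=2,
        )
        assert res[1].size_edges >= 3
        assert res[1].p < 0.05
        assert set(res[1].edges) >= {(0, 1), (1, 2), (2, 3)}


class TestSignConsistency:
    def test_separated_groups_fully_flagged(self, rng):
        a = np.ones((10, 6)) + 0.01 * rng.standard_normal((10, 6))
        b = -np.ones((10, 6)) + 0.01 * rng.standard_normal((10, 6))
        flags = subsample_sign_consistency(
            conns_from_rows(a, 4, "a"), conns_from_rows(b, 4, "b"),
            full_mask(4), n_iter=200, seed=0,
        )
        iu = np.triu_indices(4, 1)
        assert np.all(flags[iu] == 1)

    def test_half_cohort_rounding(self):
        # 51 -> 26 and 108 -> 54 under round-half-up
        assert round_half_up(0.5 * 51) == 26
        assert round_half_up(0.5 * 108) == 54

    def test_null_flag_rate_matches_subsampling_theory(self):
        """Under the null the half-subsample difference shares the sign of
        the full-sample difference, whose noise is comparable to the
        subsampling noise, so the flag probability is approximately
        P(|Z| > 1.645) ~ 10% — the filter is a robustness descriptor, not a
        calibrated 5% test."""
        flagged = 0
        n_edges = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            a = r.standard_normal((15, 10))
            b = r.standard_normal((15, 10))
            flags = subsample_sign_consistency(
                conns_from_rows(a, 5, "a"), conns_from_rows(b, 5, "b"),
                full_mask(5), n_iter=400, seed=seed,
            )
            iu = np.triu_indices(5, 1)
            flagged += np.sum(flags[iu] != 0)
            n_edges += 10
        assert 0.03 < flagged / n_edges < 0.20

    def test_tiny_subsample_rejected(self, rng):
        ga = [make_conn(rng, 4, f"a{k}") for k in range(3)]
        gb = [make_conn(rng, 4, f"b{k}") for k in range(3)]
        with pytest.raises(ValueError, match="too small"):
            subsample_sign_consistency(ga, gb, full_mask(4), frac=0.34)


class TestActivityContrast:
    def profiles(self, arr, prefix="s"):
        return [ActivityProfile(f"{prefix}{k}", ALPHA, row) for k, row in enumerate(arr)]

    def test_identical_groups_nothing_significant(self, rng):
        cov = np.abs(rng.standard_normal((6, 10))) + 0.5
        res = activity_contrast(self.profiles(cov, "a"), self.profiles(cov, "b"),
                                n_perm=200, seed=0)
        assert not res["sig_pos"].any() and not res["sig_neg"].any()

    def test_planted_increase_detected(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            a = 0.5 + 0.05 * r.standard_normal((25, 10))
            b = 0.5 + 0.05 * r.standard_normal((25, 10))
            a[:, :3] += 0.1  # CoV increase at 3 nodes
            res = activity_contrast(self.profiles(a, "a"), self.profiles(b, "b"),
                                    n_perm=500, seed=seed)
            hits += bool(res["sig_pos"][:3].all())
            assert not res["sig_neg"][:3].any()  # increases never in negative contrast
        assert hits >= 9

    def test_sign_bookkeeping(self, rng):
        a = 1.0 + 0.01 * rng.standard_normal((10, 4))
        b = 0.5 + 0.01 * rng.standard_normal((10, 4))
        res = activity_contrast(self.profiles(a, "a"), self.profiles(b, "b"),
                                n_perm=200, seed=1)
        assert res["t"].min() > 0
        assert not res["sig_neg"].any()


class TestCrossExperiment:
    def test_perfect_anticorrelation(self, rng):
        n = 8
        t1 = matrix_from_upper(rng.standard_normal(28), n)
        m = full_mask(n)
        res = cross_experiment_comparison(t1, -t1, m, m)
        assert res.r == pytest.approx(-1.0)
        assert np.all(res.product_map <= 1e-12)

    def test_independent_tmaps_weakly_correlated(self):
        rng = np.random.default_rng(8)
        n = 21  # 210 edges
        t1 = matrix_from_upper(rng.standard_normal(210), n)
        t2 = matrix_from_upper(rng.standard_normal(210), n)
        m = full_mask(n)
        res = cross_experiment_comparison(t1, t2, m, m)
        assert abs(res.r) < 0.2
        assert res.n_common == 210

    def test_conjunction_lists_opposite_signs(self):
        n = 5
        t1 = np.zeros((n, n))
        t2 = np.zeros((n, n))
        t1[1, 3] = t1[3, 1] = 2.5
        t2[1, 3] = t2[3, 1] = -2.2
        sig = np.zeros((n, n), dtype=bool)
        sig[1, 3] = sig[3, 1] = True
        m = full_mask(n)
        res = cross_experiment_comparison(t1, t2, m, m, sig1=sig, sig2=sig)
        assert res.conjunction == [(1, 3, 2.5, -2.2)]

    def test_empty_intersection_rejected(self, rng):
        n = 6
        t = matrix_from_upper(rng.standard_normal(15), n)
        empty = EdgeMask(band="x", mask=np.zeros((n, n), dtype=bool))
        with pytest.raises(ValueError, match="common masked edges"):
            cross_experiment_comparison(t, t, empty, empty)


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert ttest_power(0.0, 20, 20, 0.05) == pytest.approx(0.05, abs=1e-9)

    def test_benchmark_d05_n64(self):
        assert ttest_power(0.5, 64, 64, 0.05) == pytest.approx(0.801, abs=0.001)

    def test_monotone_in_effect_and_n(self):
        powers_d = [ttest_power(d, 30, 30) for d in (0.2, 0.5, 0.8, 1.2)]
        assert all(x < y for x, y in zip(powers_d, powers_d[1:]))
        powers_n = [ttest_power(0.5, n, n) for n in (10, 30, 90)]
        assert all(x < y for x, y in zip(powers_n, powers_n[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ttest_power(-0.1, 10, 10)
        with pytest.raises(ValueError):
            ttest_power(0.5, 1, 10)
        with pytest.raises(ValueError):
            ttest_power(0.5, 10, 10, alpha=1.5)
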