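"""Cluster-permutation statistics: oracles, calibration, invariances."""

import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import brute_force_components, grid_from_t
from eegmci.cluster import (Cluster, NullDistribution, assess_significance,
                            cluster_analysis, extract_cba, first_level,
                            form_clusters, permutation_null)
from eegmci.montage import neighbor_matrix


class TestFirstLevel:
    def test_null_p_values_uniform(self):
        """Under equal group means, the 800 per-cell p values are uniform
        (Kolmogorov-Smirnov does not reject at alpha=0.01)."""
        rng = np.random.default_rng(0)
        grids = rng.standard_normal((40, 20, 40))
        labels = np.array(["HC"] * 20 + ["MCI"] * 20)
        grid = first_level(grids, labels, "independent")
        ks = stats.kstest(grid.p.ravel(), "uniform")
        assert ks.pvalue > 0.01

    def test_matches_scipy_ttest(self):
        rng = np.random.default_rng(1)
        grids = rng.standard_normal((16, 4, 6))
        labels = np.array(["HC"] * 9 + ["MCI"] * 7)
        grid = first_level(grids, labels, "independent")
        ref = stats.ttest_ind(grids[labels == "MCI"], grids[labels == "HC"],
                              axis=0, equal_var=True)
        np.testing.assert_allclose(grid.t, ref.statistic, atol=1e-10)
        np.testing.assert_allclose(grid.p, ref.pvalue, atol=1e-10)

    def test_shifted_cell_detected(self):
        rng = np.random.default_rng(2)
        grids = rng.standard_normal((40, 20, 40))
        labels = np.array(["HC"] * 20 + ["MCI"] * 20)
        grids[20:, 5, 10] += 3.0           # 3 pooled SDs in one cell
        grid = first_level(grids, labels, "independent")
        assert grid.p[5, 10] < 0.01

    def test_paired_identical_visits_all_zero(self):
        diffs = np.zeros((10, 4, 5))
        with pytest.warns(UserWarning):
            grid = first_level(diffs, None, "paired")
        np.testing.assert_array_equal(grid.t, 0.0)
        np.testing.assert_array_equal(grid.p, 1.0)

    def test_paired_matches_scipy(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((12, 4, 5))
        b = a + 0.3 + 0.5 * rng.standard_normal((12, 4, 5))
        grid = first_level(b - a, None, "paired")
        ref = stats.ttest_rel(b, a, axis=0)
        np.testing.assert_allclose(grid.t, ref.statistic, atol=1e-10)

    def test_label_swap_flips_t_sign(self):
        rng = np.random.default_rng(4)
        grids = rng.standard_normal((20, 5, 5))
        labels = np.array(["HC"] * 10 + ["MCI"] * 10)
        g1 = first_level(grids, labels, "independent", groups=("HC", "MCI"))
        g2 = first_level(grids, labels, "independent", groups=("MCI", "HC"))
        np.testing.assert_allclose(g1.t, -g2.t, atol=1e-12)


def _grid_with_cells(shape, cells, t_value=4.0):
    t = np.zeros(shape)
    for (r, c) in cells:
        t[r, c] = t_value
    return grid_from_t(t)


class TestFormClusters:
    def test_no_suprathreshold_cells(self):
        clusters = form_clusters(grid_from_t(np.zeros((4, 4))), min_size=2)
        assert clusters == []

    def test_toy_example_discards_isolated_cell(self):
        grid = _grid_with_cells((4, 4), [(0, 0), (0, 1), (1, 1), (3, 3)])
        clusters = form_clusters(grid, min_size=2)
        assert len(clusters) == 1
        assert clusters[0].size == 3
        assert set(map(tuple, clusters[0].cells)) == {(0, 0), (0, 1), (1, 1)}
        assert clusters[0].tsize == pytest.approx(12.0)

    def test_opposite_signs_split(self):
        t = np.zeros((3, 3))
        t[1, 1], t[1, 2] = 4.0, -4.0       # adjacent, opposite signs
        t[0, 1] = 4.0
        clusters = form_clusters(grid_from_t(t), min_size=1)
        signs = sorted(c.sign for c in clusters)
        assert signs == [-1, 1]
        assert {c.size for c in clusters} == {1, 2}

    def test_matches_brute_force_on_all_3x3_patterns(self):
        """Cluster formation equals an independent BFS connected-components
        oracle on every one of the 512 patterns of a 3x3 grid."""
        for bits in range(512):
            mask = np.array([(bits >> k) & 1 for k in range(9)],
                            dtype=bool).reshape(3, 3)
            grid = grid_from_t(np.where(mask, 4.0, 0.0))
            got = {frozenset(map(tuple, c.cells))
                   for c in form_clusters(grid, min_size=1)}
            assert got == set(brute_force_components(mask)), bits

    def test_custom_channel_adjacency_chain_equivalence(self):
        rng = np.random.default_rng(5)
        t = 4.0 * (rng.random((10, 12)) < 0.3)
        grid = grid_from_t(t)
        chain = np.zeros((10, 10), dtype=bool)
        for i in range(9):
            chain[i, i + 1] = chain[i + 1, i] = True
        a = {frozenset(map(tuple, c.cells))
             for c in form_clusters(grid, min_size=1)}
        b = {frozenset(map(tuple, c.cells))
             for c in form_clusters(grid, min_size=1, channel_adjacency=chain)}
        assert a == b

    def test_scalp_adjacency_merges_nonconsecutive_rows(self):
        """With a scalp neighbour matrix, channels that are physically
        adjacent but non-consecutive in the montage ordering join clusters."""
        adj = neighbor_matrix()
        pair = np.argwhere(adj)
        far = pair[np.abs(pair[:, 0] - pair[:, 1]) > 1][0]
        t = np.zeros((20, 10))
        t[far[0], 3] = t[far[1], 3] = 4.0
        grid = grid_from_t(t)
        assert len(form_clusters(grid, min_size=2)) == 0
        assert len(form_clusters(grid, min_size=2, channel_adjacency=adj)) == 1


class TestPermutationNull:
    def test_exact_enumeration_2v2(self):
        """At n=2v2 the null is the exhaustive set of 6 label assignments,
        verified against a direct itertools enumeration."""
        rng = np.random.default_rng(6)
        grids = rng.standard_normal((4, 3, 3))
        labels = np.array(["HC", "HC", "MCI", "MCI"])
        with pytest.warns(UserWarning):
            null = permutation_null(grids, labels, "independent",
                                    min_size=1, seed=0)
        assert null.exact and null.n_permutations == 6
        # oracle: recompute max |tsize| per assignment by brute force
        expected = []
        tcrit = stats.t.ppf(1 - 0.01 / 2, 2)
        for combo in itertools.combinations(range(4), 2):
            lab = np.array(["HC"] * 4, dtype=object)
            lab[list(combo)] = "MCI"
            grid = first_level(grids, lab, "independent")
            cl = form_clusters(grid, min_size=1)
            expected.append(max((abs(c.tsize) for c in cl), default=0.0))
        assert sorted(np.round(null.max_tsizes, 9)) == \
            sorted(np.round(expected, 9))
        assert tcrit > 0

    def test_seed_determinism(self):
        rng = np.random.default_rng(7)
        grids = rng.standard_normal((30, 8, 8))
        labels = np.array(["HC"] * 15 + ["MCI"] * 15)
        n1 = permutation_null(grids, labels, "independent", n_perm=50, seed=3)
        n2 = permutation_null(grids, labels, "independent", n_perm=50, seed=3)
        np.testing.assert_array_equal(n1.max_tsizes, n2.max_tsizes)

    def test_paired_sign_flip_null(self):
        rng = np.random.default_rng(8)
        diffs = rng.standard_normal((16, 6, 6))
        null = permutation_null(diffs, None, "paired", n_perm=40, seed=1)
        assert null.max_tsizes.shape == (40,)
        assert np.all(null.max_tsizes >= 0)

    def test_no_cluster_iterations_contribute_zero(self):
        grids = np.random.default_rng(9).standard_normal((20, 4, 4)) * 0.01
        labels = np.array(["HC"] * 10 + ["MCI"] * 10)
        null = permutation_null(grids, labels, "independent", n_perm=30,
                                min_size=4, seed=2)
        assert (null.max_tsizes == 0).any()


class TestAssessSignificance:
    def _cluster(self, tsize):
        return Cluster(cells=np.array([[0, 0], [0, 1]]), size=2,
                       tsize=tsize, sign=1, space="channel_frequency")

    def test_extremes_and_89th_percentile(self):
        null = NullDistribution(np.arange(1.0, 1001.0), 1000, seed=0)
        top = assess_significance([self._cluster(2000.0)], null)[0]
        assert top.percentile == 100.0 and top.significant
        bottom = assess_significance([self._cluster(0.5)], null)[0]
        assert bottom.percentile == 0.0 and not bottom.significant
        mid = assess_significance([self._cluster(890.5)], null)[0]
        assert mid.percentile == pytest.approx(89.0)
        assert not mid.significant

    def test_threshold_is_95th_percentile(self):
        null = NullDistribution(np.arange(1.0, 101.0), 100, seed=0)
        at = assess_significance([self._cluster(95.0)], null)[0]
        assert at.percentile == 95.0 and at.significant


class TestExtractCba:
    def test_constant_and_mean(self):
        c = Cluster(cells=np.array([[0, 0], [1, 2]]), size=2, tsize=8.0,
                    sign=1, space="channel_frequency")
        grid = np.full((3, 4), 2.5)
        assert extract_cba(grid, c) == pytest.approx(2.5)
        grid[0, 0], grid[1, 2] = 1.0, 3.0
        assert extract_cba(grid, c) == pytest.approx(2.0)

    def test_aggregation_gain_on_correlated_effect(self):
        """Averaging over a cluster of cells sharing a common group effect
        beats the best single cell when per-cell noise is independent."""
        from eegmci.reliability import hedges_g

        rng = np.random.default_rng(10)
        n, cells = 2000, 25
        half = n // 2
        labels = np.array(["HC"] * half + ["MCI"] * half)
        shared = rng.standard_normal(n)[:, None]
        shared[half:] += 0.8
        grids = (shared + rng.standard_normal((n, cells))).reshape(n, 5, 5)
        cluster = Cluster(cells=np.argwhere(np.ones((5, 5), bool)), size=25,
                          tsize=1.0, sign=1, space="channel_frequency")
        cba = np.array([extract_cba(g, cluster) for g in grids])
        g_cba = hedges_g(cba[half:], cba[:half])
        per_cell = [hedges_g(grids[half:, r, c], grids[:half, r, c])
                    for r in range(5) for c in range(5)]
        assert g_cba >= max(per_cell)
        assert labels.size == n


class TestProcedureCalibration:
    def test_type_one_error_on_gaussian_grids(self):
        """form -> null -> assess at the 95th percentile keeps the dataset
        false-positive rate near 5% on iid-noise grids (n=20/20)."""
        rng = np.random.default_rng(11)
        labels = np.array(["HC"] * 20 + ["MCI"] * 20)
        hits = 0
        reps = 150
        for _ in range(reps):
            grids = rng.standard_normal((40, 20, 40))
            res = cluster_analysis(grids, labels, "independent",
                                   "channel_frequency", n_perm=100,
                                   seed=int(rng.integers(2**31)))
            hits += any(c.significant for c in res.clusters)
        assert 0.01 <= hits / reps <= 0.10
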