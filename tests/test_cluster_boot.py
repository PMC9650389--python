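"""Correlation distance, complete linkage, multiscale bootstrap, AU."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

from mepclust import (
    BootstrapTable,
    au_from_bp,
    cluster_with_support,
    complete_linkage,
    correlation_distance,
    multiscale_bootstrap,
)
from mepclust.errors import DataError, ZeroVarianceError


class TestCorrelationDistance:
    def test_duplicated_columns_give_zero_distance(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=8)
        data = np.column_stack([col, col, rng.normal(size=8)])
        dist, _ = correlation_distance(data)
        assert dist[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_columns_give_two(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=8)
        data = np.column_stack([col, -col, rng.normal(size=8)])
        dist, _ = correlation_distance(data)
        assert dist[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_hand_computed_pearson(self):
        data = np.array(
            [[1.0, 2.0, 5.0], [2.0, 1.0, 4.0], [3.0, 5.0, 1.0], [4.0, 3.0, 2.0]]
        )
        dist, labels = correlation_distance(data)
        for i in range(3):
            for j in range(3):
                xi = data[:, i] - data[:, i].mean()
                xj = data[:, j] - data[:, j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert dist[i, j] == pytest.approx(1.0 - r, abs=1e-12)

    def test_zero_variance_column_names_the_complex(self):
        data = pd.DataFrame(
            {"good": [1.0, 2, 3, 4], "flat": [5.0, 5, 5, 5], "ok": [2.0, 1, 4, 3]}
        )
        with pytest.raises(ZeroVarianceError, match="flat"):
            correlation_distance(data)


class TestCompleteLinkage:
    def test_three_leaf_example(self):
        dist = np.array([[0.0, 1, 4], [1, 0, 5], [4, 5, 0]])
        tree = complete_linkage(dist, ["A", "B", "C"])
        sets = tree.leafsets()
        assert sets[0] == {"A", "B"} and tree.merges[0][2] == pytest.approx(1.0)
        assert sets[1] == {"A", "B", "C"} and tree.merges[1][2] == pytest.approx(5.0)

    def test_identical_leaves_merge_at_zero(self):
        dist = np.array([[0.0, 0, 3], [0, 0, 3], [3, 3, 0]])
        tree = complete_linkage(dist, ["A", "B", "C"])
        assert tree.merges[0][2] == 0.0

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = rng.integers(3, 8)
            raw = rng.random((n, n))
            dist = (raw + raw.T) / 2
            np.fill_diagonal(dist, 0)
            tree = complete_linkage(dist)
            heights = tree.heights()
            assert np.all(np.diff(heights) >= -1e-12)

    def test_matches_scipy_on_distinct_distances(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            condensed = rng.permutation(np.linspace(0.1, 2.0, n * (n - 1) // 2))
            dist = squareform(condensed)
            tree = complete_linkage(dist)
            z = linkage(condensed, method="complete")
            np.testing.assert_allclose(sorted(tree.heights()), sorted(z[:, 2]), atol=1e-12)

    def test_tie_break_picks_lexicographically_smallest(self):
        # d(A,B) = d(C,D) = 1: the (A,B) merge must come first
        dist = np.full((4, 4), 5.0)
        np.fill_diagonal(dist, 0.0)
        dist[0, 1] = dist[1, 0] = 1.0
        dist[2, 3] = dist[3, 2] = 1.0
        tree = complete_linkage(dist, ["A", "B", "C", "D"])
        assert tree.leafsets()[0] == {"A", "B"}
        assert tree.leafsets()[1] == {"C", "D"}

    def test_asymmetric_matrix_rejected(self):
        dist = np.array([[0.0, 1, 2], [1.1, 0, 3], [2, 3, 0]])
        with pytest.raises(DataError, match="symmetric"):
            complete_linkage(dist)


class TestMultiscaleBootstrap:
    def block_data(self, seed=0, n_rows=30):
        """Two duplicated column blocks + informative rows."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n_rows)
        b = rng.normal(size=n_rows)
        return pd.DataFrame(
            {
                "a1": a + 0.01 * rng.normal(size=n_rows),
                "a2": a + 0.01 * rng.normal(size=n_rows),
                "b1": b + 0.01 * rng.normal(size=n_rows),
                "b2": b + 0.01 * rng.normal(size=n_rows),
            }
        )

    def test_same_seed_reproduces_table_exactly(self):
        data = self.block_data()
        t1, _ = multiscale_bootstrap(data, nboot=50, seed=9)
        t2, _ = multiscale_bootstrap(data, nboot=50, seed=9)
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_growing_nboot_preserves_early_replicates(self):
        data = self.block_data()
        t_small, _ = multiscale_bootstrap(data, scales=[1.0], nboot=20, seed=9)
        t_big, _ = multiscale_bootstrap(data, scales=[1.0], nboot=40, seed=9)
        # counts at nboot=20 are a prefix of the nboot=40 stream
        assert np.all(t_small.counts <= t_big.counts)

    def test_duplicated_blocks_get_high_bp(self):
        data = self.block_data()
        table, tree = multiscale_bootstrap(data, scales=[1.0], nboot=200, seed=3)
        bp = {s: table.bp[k, 0] for k, s in enumerate(table.leafsets)}
        assert bp[frozenset({"a1", "a2"})] >= 0.95
        assert bp[frozenset({"b1", "b2"})] >= 0.95

    def test_single_scale_gives_one_bp_column(self):
        table, _ = multiscale_bootstrap(self.block_data(), scales=[1.0], nboot=5, seed=0)
        assert table.bp.shape[1] == 1

    def test_resample_below_two_rows_is_an_error(self):
        data = self.block_data(n_rows=3)
        with pytest.raises(DataError, match="< 2 rows"):
            multiscale_bootstrap(data, scales=[0.3], nboot=5, seed=0)


def make_table(bp_rows, scales, nboot=1000):
    counts = np.rint(np.asarray(bp_rows, dtype=float) * nboot).astype(int)
    return BootstrapTable(
        leafsets=tuple(frozenset([str(i)]) for i in range(len(bp_rows))),
        scales=tuple(scales),
        nboot=nboot,
        counts=counts,
        seed=0,
    )


class TestAuFromBp:
    scales = tuple(np.round(np.arange(0.5, 1.45, 0.1), 10))

    def test_flat_half_bp_gives_au_half(self):
        table = make_table([[0.5] * 10], self.scales)
        au, bp = au_from_bp(table)
        assert au[0] == pytest.approx(0.5, abs=1e-12)
        assert bp[0] == pytest.approx(0.5)

    def test_constructed_curve_recovers_au(self):
        # BP_r = 1 - Phi(v sqrt(r) + c / sqrt(r)) with v = 1, c = 0.5
        v, c = 1.0, 0.5
        r = np.asarray(self.scales)
        bp_curve = 1.0 - norm.cdf(v * np.sqrt(r) + c / np.sqrt(r))
        table = BootstrapTable(
            leafsets=(frozenset(["x"]),),
            scales=self.scales,
            nboot=10**9,  # effectively exact BP so rounding does not bite
            counts=np.rint(bp_curve * 10**9).astype(int)[None, :],
            seed=0,
        )
        au, _ = au_from_bp(table)
        assert au[0] == pytest.approx(1.0 - norm.cdf(0.5), abs=1e-4)
        assert au[0] == pytest.approx(0.3085, abs=5e-4)

    def test_degenerate_all_ones_and_all_zeros(self):
        table = make_table([[1.0] * 10, [0.0] * 10], self.scales)
        au, _ = au_from_bp(table)
        assert au[0] == 1.0
        assert au[1] == 0.0

    def test_fewer_than_two_usable_scales_warns_and_gives_nan(self):
        table = make_table([[1.0, 1.0, 0.5]], [0.8, 1.0, 1.2])
        with pytest.warns(UserWarning, match="AU not computed"):
            au, _ = au_from_bp(table)
        assert np.isnan(au[0])


class TestTreeReporting:
    def small_tree(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            {
                "a1": rng.normal(size=20),
                "a2": rng.normal(size=20),
                "b1": rng.normal(size=20),
            }
        )
        return cluster_with_support(data, scales=[0.8, 1.0, 1.2], nboot=50, seed=4)

    def test_au_and_bp_are_probabilities(self):
        tree = self.small_tree()
        ok = np.isfinite(tree.au)
        assert np.all((tree.au[ok] >= 0) & (tree.au[ok] <= 1))
        assert np.all((tree.bp >= 0) & (tree.bp <= 1))

    def test_flagging_is_strict_and_excludes_root(self):
        tree = self.small_tree()
        tree.au = np.array([0.96, 0.99])  # root is the last node
        assert tree.significant_nodes(0.95) == [tree.leafsets()[0]]
        tree.au = np.array([0.95, 0.99])  # exactly at threshold: not flagged
        assert tree.significant_nodes(0.95) == []

    def test_all_zero_au_flags_nothing(self):
        tree = self.small_tree()
        tree.au = np.zeros(2)
        assert tree.significant_nodes() == []
        part = tree.flagged_partition()
        assert len(set(part.values())) == 3  # all singletons

    def test_newick_round_trips_through_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        tree = self.small_tree()
        tree.au = np.array([0.875, 0.5])
        nwk = tree.to_newick()
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        taxa = sorted(leaf.taxon.label for leaf in parsed.leaf_node_iter())
        assert taxa == ["a1", "a2", "b1"]
        supports = sorted(
            float(n.label) for n in parsed.internal_nodes() if n.label is not None
        )
        assert supports[0] == pytest.approx(50.0)
        assert supports[-1] == pytest.approx(87.5)

    def test_leaf_permutation_gives_isomorphic_reference_tree(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.normal(size=(25, 5)), columns=list("abcde"))
        dist, labels = correlation_distance(data)
        tree = complete_linkage(dist, labels)
        order = [3, 1, 4, 0, 2]
        dist_p = dist[np.ix_(order, order)]
        tree_p = complete_linkage(dist_p, [labels[i] for i in order])
        assert set(map(frozenset, tree.leafsets())) == set(map(frozenset, tree_p.leafsets()))
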