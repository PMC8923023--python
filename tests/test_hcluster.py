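"""Pearson distances, agglomeration, relative cuts and Newick round trips."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from oracles import clade_heights, naive_agglomerate
from orthoclust.hcluster import (
    D_MAX,
    Dendrogram,
    agglomerate,
    cut_relative,
    from_newick,
    pairwise_distances,
    pearson_distance,
    to_newick,
)


class TestPearsonDistance:
    def test_identical_vectors_distance_zero(self):
        assert pearson_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_anticorrelated_vectors_distance_two(self):
        assert pearson_distance([1, 2, 3], [3, 2, 1]) == pytest.approx(2.0)

    def test_hand_computed_half_correlation(self):
        # r([1,2,3],[1,3,2]) = 0.5 by direct evaluation of the formula
        assert pearson_distance([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_small_support_is_undefined(self):
        d = pearson_distance([1, 2, 3], [1, 3, 2], [True, True, False])
        assert np.isnan(d)

    def test_zero_variance_is_undefined(self):
        assert np.isnan(pearson_distance([1, 1, 1], [1, 2, 3]))

    def test_pairwise_matches_scalar_on_masked_rows(self, rng):
        X = rng.random((8, 12))
        M = rng.random((8, 12)) > 0.2
        D = pairwise_distances(X, M).square()
        for i in range(8):
            for j in range(i + 1, 8):
                expected = pearson_distance(X[i], X[j], M[i], M[j])
                if np.isnan(expected):
                    expected = D_MAX
                assert D[i, j] == pytest.approx(expected, abs=1e-9)

    def test_undefined_pairs_fall_back_to_dmax(self):
        X = np.ones((2, 6))
        X[1] = np.arange(6)
        mask = np.array(
            [[True] * 3 + [False] * 3, [False] * 3 + [True] * 3]
        )
        D = pairwise_distances(X, mask)
        assert D.condensed[0] == D_MAX
        assert D.n_undefined == 1


class TestAgglomerate:
    def test_single_leaf_gives_empty_merge_list(self):
        tree = agglomerate(np.zeros((1, 1)), "average")
        assert tree.n_leaves == 1 and len(tree.merges) == 0

    def test_three_leaf_average_linkage_by_hand(self):
        # d(A,B)=1, d(A,C)=4, d(B,C)=5 -> merge (A,B) at 1, then C at (4+5)/2
        sq = squareform([1.0, 4.0, 5.0])
        tree = agglomerate(sq, "average")
        assert tree.merges[0][:3].tolist() == [0.0, 1.0, 1.0]
        assert tree.merges[1][2] == pytest.approx(4.5)

    def test_three_leaf_complete_linkage_by_hand(self):
        sq = squareform([1.0, 4.0, 5.0])
        tree = agglomerate(sq, "complete")
        assert tree.merges[1][2] == pytest.approx(5.0)  # max(4, 5)

    def test_non_finite_distance_rejected(self):
        sq = squareform([1.0, np.inf, 5.0])
        with pytest.raises(ValueError, match="non-finite"):
            agglomerate(sq, "average")

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_matches_naive_oracle_on_random_matrices(self, linkage, rng):
        for _ in range(25):
            n = int(rng.integers(2, 13))
            condensed = rng.random(n * (n - 1) // 2) * 2
            sq = squareform(condensed)
            tree = agglomerate(sq, linkage)
            expected = naive_agglomerate(sq, linkage)
            assert clade_heights(n, tree.merges) == clade_heights(n, expected)

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_matches_scipy_cophenetic_distances(self, linkage, rng):
        n = 20
        condensed = rng.random(n * (n - 1) // 2)
        ours = agglomerate(squareform(condensed), linkage)
        Z = scipy_linkage(condensed, method=linkage)
        ours_coph = _cophenetic_from_merges(ours)
        scipy_coph = cophenet(Z)
        np.testing.assert_allclose(ours_coph, scipy_coph, atol=1e-12)

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_partition_invariant_to_row_permutation(self, linkage, rng):
        n = 15
        condensed = rng.random(n * (n - 1) // 2)
        sq = squareform(condensed)
        perm = rng.permutation(n)
        sq_p = sq[np.ix_(perm, perm)]
        cut = cut_relative(agglomerate(sq, linkage), 0.6)
        cut_p = cut_relative(agglomerate(sq_p, linkage), 0.6)
        parts = {
            frozenset(np.flatnonzero(cut.cluster_of_row == c))
            for c in range(1, cut.k + 1)
        }
        parts_p = {
            frozenset(perm[np.flatnonzero(cut_p.cluster_of_row == c)])
            for c in range(1, cut_p.k + 1)
        }
        assert parts == parts_p


def _cophenetic_from_merges(tree):
    n = tree.n_leaves
    members = {i: [i] for i in range(n)}
    D = np.zeros((n, n))
    for t, (left, right, h, _s) in enumerate(tree.merges):
        a, b = members[int(left)], members[int(right)]
        for i in a:
            for j in b:
                D[i, j] = D[j, i] = h
        members[n + t] = a + b
    return D[np.triu_indices(n, k=1)]


class TestCutRelative:
    def _three_leaf_tree(self):
        return agglomerate(squareform([1.0, 4.0, 5.0]), "average")

    def test_hand_example_cuts_into_two_clusters(self):
        # heights 1.0 and 4.5; 0.75 * 4.5 = 3.375 -> only the first merge applies
        cut = cut_relative(self._three_leaf_tree(), 0.75)
        assert cut.k == 2
        assert cut.cluster_of_row[0] == cut.cluster_of_row[1]
        assert cut.cluster_of_row[2] != cut.cluster_of_row[0]

    def test_fraction_one_gives_single_cluster(self):
        assert cut_relative(self._three_leaf_tree(), 1.0).k == 1

    def test_tiny_fraction_gives_all_singletons(self):
        assert cut_relative(self._three_leaf_tree(), 0.01).k == 3

    def test_fraction_out_of_range_rejected(self):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                cut_relative(self._three_leaf_tree(), bad)

    def test_cluster_count_non_increasing_in_fraction(self, rng):
        n = 30
        tree = agglomerate(squareform(rng.random(n * (n - 1) // 2)), "average")
        ks = [cut_relative(tree, f).k for f in np.linspace(0.01, 1.0, 25)]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_merges_exactly_at_cut_height_are_applied(self):
        # root at 4.5; fraction 1.0 puts the cut exactly at the root merge
        assert cut_relative(self._three_leaf_tree(), 1.0).k == 1


class TestNewick:
    def test_single_leaf(self):
        tree = Dendrogram(1, np.empty((0, 4)))
        assert to_newick(tree, ["A"]) == "A;"

    def test_three_leaf_example_branch_lengths(self):
        tree = agglomerate(squareform([1.0, 4.0, 5.0]), "average")
        text = to_newick(tree, ["A", "B", "C"])
        # ((A:1,B:1):3.5,C:4.5); up to sibling order
        assert "A:1" in text and "B:1" in text
        assert ":3.5" in text and "C:4.5" in text

    def test_duplicate_labels_rejected(self):
        tree = agglomerate(squareform([1.0, 4.0, 5.0]), "average")
        with pytest.raises(ValueError, match="duplicate"):
            to_newick(tree, ["A", "A", "C"])

    def test_round_trip_preserves_topology_and_heights(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 15))
            condensed = rng.random(n * (n - 1) // 2)
            tree = agglomerate(squareform(condensed), "average")
            labels = [f"L{i}" for i in range(n)]
            back, back_labels = from_newick(to_newick(tree, labels))
            orig = {
                frozenset(labels[i] for i in clade): h
                for clade, h in clade_heights(n, tree.merges)
            }
            got = {
                frozenset(back_labels[i] for i in clade): h
                for clade, h in clade_heights(n, back.merges)
            }
            assert got.keys() == orig.keys()
            for clade, h in orig.items():
                assert got[clade] == pytest.approx(h, abs=1e-9)

    def test_round_trip_agrees_with_dendropy_parse(self, rng):
        dendropy = pytest.importorskip("dendropy")
        n = 8
        tree = agglomerate(squareform(rng.random(n * (n - 1) // 2)), "average")
        labels = [f"L{i}" for i in range(n)]
        text = to_newick(tree, labels)
        dtree = dendropy.Tree.get(data=text, schema="newick")
        # bipartitions (clades) seen by dendropy match our merge clades
        dendropy_clades = set()
        for node in dtree.preorder_node_iter():
            leaves = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            if 1 < len(leaves) < n:
                dendropy_clades.add(leaves)
        ours = {
            frozenset(labels[i] for i in clade)
            for clade, _h in clade_heights(n, tree.merges)
            if len(clade) < n
        }
        assert dendropy_clades == ours

    def test_monotone_heights_for_average_and_complete(self, rng):
        for linkage in ("average", "complete"):
            n = 25
            tree = agglomerate(
                squareform(rng.random(n * (n - 1) // 2)), linkage
            )
            heights = tree.merges[:, 2]
            assert np.all(np.diff(heights) >= -1e-12)
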