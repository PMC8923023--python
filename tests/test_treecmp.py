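"""Shared clades, Fowlkes-Mallows cuts and cophenetic correlation."""

import numpy as np
import pytest
from scipy.spatial.distance import squareform

from orthoclust.hcluster import agglomerate
from orthoclust.treecmp import (
    clade_sets,
    compare_trees,
    cophenetic_correlation,
    cut_tree_k,
    fowlkes_mallows,
    restrict_to_common_leaves,
    tree_from_dendrogram,
    tree_from_newick,
)


def random_tree(rng, labels):
    n = len(labels)
    dendro = agglomerate(squareform(rng.random(n * (n - 1) // 2)), "average")
    return tree_from_dendrogram(dendro, labels)


@pytest.fixture()
def balanced_pair():
    a = tree_from_newick("((A:1,B:1):2,(C:1,D:1):2);")
    b = tree_from_newick("((A:1,C:1):2,(B:1,D:1):2);")
    return a, b


class TestRestrict:
    def test_identical_leaf_sets_unchanged(self, rng):
        labels = [f"L{i}" for i in range(8)]
        a, b = random_tree(rng, labels), random_tree(rng, labels)
        ra, rb = restrict_to_common_leaves(a, b)
        assert clade_sets(ra) == clade_sets(a)
        assert clade_sets(rb) == clade_sets(b)

    def test_extra_leaf_pruned_from_both(self, rng):
        a = random_tree(rng, ["A", "B", "C", "D", "X"])
        b = random_tree(rng, ["A", "B", "C", "D"])
        ra, rb = restrict_to_common_leaves(a, b)
        assert ra.leaves() == rb.leaves() == {"A", "B", "C", "D"}

    def test_pruning_is_idempotent_for_comparisons(self, rng):
        a = random_tree(rng, ["A", "B", "C", "D", "E", "X", "Y"])
        b = random_tree(rng, ["A", "B", "C", "D", "E", "Z"])
        first = compare_trees(a, b)
        ra, rb = restrict_to_common_leaves(a, b)
        second = compare_trees(ra, rb)
        assert first.shared_clades == second.shared_clades
        assert first.cophenetic_r == pytest.approx(second.cophenetic_r)

    def test_too_few_common_leaves_rejected(self, rng):
        a = random_tree(rng, ["A", "B", "C", "D"])
        b = random_tree(rng, ["A", "B", "X", "Y"])
        with pytest.raises(ValueError, match="common leaves"):
            restrict_to_common_leaves(a, b)


class TestCommonNodes:
    def test_identical_trees_share_everything(self, rng):
        labels = [f"L{i}" for i in range(10)]
        a = random_tree(rng, labels)
        cmp = compare_trees(a, a)
        assert cmp.fraction_shared_a == cmp.fraction_shared_b == 1.0

    def test_disjoint_four_leaf_pair_shares_nothing(self, balanced_pair):
        a, b = balanced_pair
        cmp = compare_trees(a, b)
        # clades {AB},{CD} vs {AC},{BD}: no overlap
        assert cmp.shared_clades == 0

    def test_root_and_singletons_excluded(self, balanced_pair):
        a, _ = balanced_pair
        clades = clade_sets(a)
        assert clades == {frozenset("AB"), frozenset("CD")}

    def test_tip_swap_loses_exactly_one_clade(self, rng):
        # caterpillar ((((A,B),C),D),E) vs the same with deepest pair swapped
        a = tree_from_newick("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")
        b = tree_from_newick("((((A:1,C:1):1,B:2):1,D:3):1,E:4);")
        ca, cb = clade_sets(a), clade_sets(b)
        assert len(ca & cb) == len(ca) - 1

    def test_shared_clades_invariant_to_sibling_rotation(self):
        a = tree_from_newick("((A:1,B:1):2,(C:1,D:1):2);")
        rot = tree_from_newick("((D:1,C:1):2,(B:1,A:1):2);")
        assert clade_sets(a) == clade_sets(rot)


class TestFowlkesMallows:
    def test_identical_trees_score_one(self, rng):
        labels = [f"L{i}" for i in range(12)]
        a = random_tree(rng, labels)
        for k in (2, 5, 11):
            assert fowlkes_mallows(a, a, k) == pytest.approx(1.0)

    def test_disjoint_pair_at_k2(self, balanced_pair):
        a, b = balanced_pair
        # each cut is two pairs; cross agreements T = 0
        assert fowlkes_mallows(a, b, 2) == pytest.approx(0.0)

    def test_matches_hand_pair_count_formula(self, rng):
        labels = [f"L{i}" for i in range(10)]
        a, b = random_tree(rng, labels), random_tree(rng, labels)
        k = 4
        ca, cb = cut_tree_k(a, k), cut_tree_k(b, k)
        same = lambda c, i, j: c[labels[i]] == c[labels[j]]  # noqa: E731
        T = P = Q = 0
        for i in range(10):
            for j in range(i + 1, 10):
                P += same(ca, i, j)
                Q += same(cb, i, j)
                T += same(ca, i, j) and same(cb, i, j)
        expected = T / np.sqrt(P * Q) if P and Q else 0.0
        assert fowlkes_mallows(a, b, k) == pytest.approx(expected)

    def test_mean_over_permutations_matches_null_expectation(self, rng):
        # under random relabelling, E[T] = P*Q / C(n,2); so E[Bk] ~ sqrt(PQ)/C
        labels = [f"L{i}" for i in range(60)]
        a = random_tree(rng, labels)
        b = random_tree(rng, labels)
        k = 6
        ca, cb = cut_tree_k(a, k), cut_tree_k(b, k)
        la = np.array([ca[x] for x in labels])
        lb = np.array([cb[x] for x in labels])
        from sklearn.metrics import fowlkes_mallows_score

        n_pairs = 60 * 59 / 2
        P = sum(
            np.sum(la == c) * (np.sum(la == c) - 1) / 2 for c in set(la)
        )
        Q = sum(
            np.sum(lb == c) * (np.sum(lb == c) - 1) / 2 for c in set(lb)
        )
        null_mean = np.sqrt(P * Q) / n_pairs
        perm_scores = []
        for _ in range(100):
            perm = rng.permutation(60)
            perm_scores.append(fowlkes_mallows_score(la, lb[perm]))
        se = np.std(perm_scores) / 10
        assert np.mean(perm_scores) == pytest.approx(null_mean, abs=3 * se + 1e-3)

    def test_out_of_range_k_rejected(self, balanced_pair):
        a, b = balanced_pair
        for k in (1, 4):
            with pytest.raises(ValueError):
                fowlkes_mallows(a, b, k)


class TestCophenetic:
    def test_self_correlation_is_one(self, rng):
        a = random_tree(rng, [f"L{i}" for i in range(8)])
        assert cophenetic_correlation(a, a) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        labels = [f"L{i}" for i in range(8)]
        dendro = agglomerate(
            squareform(rng.random(8 * 7 // 2)), "average"
        )
        a = tree_from_dendrogram(dendro, labels)
        doubled = dendro.merges.copy()
        doubled[:, 2] *= 2
        b = tree_from_dendrogram(type(dendro)(8, doubled), labels)
        assert cophenetic_correlation(a, b) == pytest.approx(1.0)

    def test_hand_built_four_leaf_pair(self):
        a = tree_from_newick("((A:1,B:1):2,(C:1,D:1):2);")
        b = tree_from_newick("((A:1,C:1):2,(B:1,D:1):2);")
        # vectors over pairs (AB,AC,AD,BC,BD,CD):
        # a: [1,3,3,3,3,1]; b: [3,1,3,3,1,3] -> r by direct formula
        va = np.array([1, 3, 3, 3, 3, 1])
        vb = np.array([3, 1, 3, 3, 1, 3])
        expected = np.corrcoef(va, vb)[0, 1]
        assert cophenetic_correlation(a, b) == pytest.approx(expected)

    def test_zero_variance_flagged(self):
        star_like = tree_from_newick("((A:1,B:1):0,(C:1,D:1):0);")
        with pytest.raises(ValueError, match="variance"):
            cophenetic_correlation(star_like, star_like)


class TestSymmetry:
    def test_statistics_symmetric_under_swap(self, rng):
        a = random_tree(rng, [f"L{i}" for i in range(9)])
        b = random_tree(rng, [f"L{i}" for i in range(9)])
        ab = compare_trees(a, b, "a", "b")
        ba = compare_trees(b, a, "b", "a")
        assert ab.shared_clades == ba.shared_clades
        assert ab.cophenetic_r == pytest.approx(ba.cophenetic_r)
        assert ab.fraction_shared_a == ba.fraction_shared_b
        assert ab.fraction_shared_b == ba.fraction_shared_a
        assert ab.fm_at_k == pytest.approx(ba.fm_at_k)

    def test_half_split_trees_more_similar_than_random(self, small_matrix):
        # trees from two halves of the feature columns share more clades
        # than trees from independent random data of the same shape
        from orthoclust.hcluster import pairwise_distances

        values, mask = small_matrix.values, small_matrix.mask
        labels = small_matrix.family_ids
        half = values.shape[1] // 2
        t1 = tree_from_dendrogram(
            agglomerate(
                pairwise_distances(values[:, :half], mask[:, :half]), "average"
            ),
            labels,
        )
        t2 = tree_from_dendrogram(
            agglomerate(
                pairwise_distances(values[:, half:], mask[:, half:]), "average"
            ),
            labels,
        )
        split_frac = compare_trees(t1, t2).fraction_shared_a

        rng = np.random.default_rng(0)
        rand_fracs = []
        for _ in range(20):
            r1 = random_tree(rng, labels)
            r2 = random_tree(rng, labels)
            rand_fracs.append(compare_trees(r1, r2).fraction_shared_a)
        assert split_frac > np.mean(rand_fracs)
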