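"""Comparison of dendrograms built from different data subsets.

Trees inferred from different species subsets share their ortholog-family
leaves but not necessarily their topology.  After restricting both trees to
the common leaf set (pruning and contracting pass-through nodes, heights
preserved), we report:

* *common nodes* -- internal clades (leaf sets, root and singletons
  excluded) present in both trees, and the fraction each tree shares;
* the Fowlkes-Mallows index ``B_k`` of the two k-cluster cuts;
* the cophenetic correlation between the merge-height distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hcluster import Dendrogram, from_newick


@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree (leaf iff no children)."""

    height: float
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> set[str]:
        if not self.children:
            return {self.label}
        out: set[str] = set()
        for c in self.children:
            out |= c.leaves()
        return out


def tree_from_dendrogram(tree: Dendrogram, labels: list[str]) -> TreeNode:
    n = tree.n_leaves
    nodes: dict[int, TreeNode] = {
        i: TreeNode(0.0, labels[i]) for i in range(n)
    }
    for t, (left, right, h, _s) in enumerate(tree.merges):
        nodes[n + t] = TreeNode(
            float(h), children=[nodes[int(left)], nodes[int(right)]]
        )
    return nodes[n + len(tree.merges) - 1] if len(tree.merges) else nodes[0]


def tree_from_newick(text: str) -> TreeNode:
    dendro, labels = from_newick(text)
    return tree_from_dendrogram(dendro, labels)


def restrict_to_common_leaves(
    a: TreeNode, b: TreeNode
) -> tuple[TreeNode, TreeNode]:
    """Prune both trees to their shared leaves; contract pass-through nodes."""
    common = a.leaves() & b.leaves()
    if len(common) < 4:
        raise ValueError(
            f"only {len(common)} common leaves; need at least 4 to compare"
        )
    return _prune(a, common), _prune(b, common)


def _prune(node: TreeNode, keep: set[str]) -> TreeNode | None:
    if not node.children:
        return node if node.label in keep else None
    kept = [c for c in (_prune(c, keep) for c in node.children) if c]
    if not kept:
        return None
    if len(kept) == 1:  # contract the pass-through node, keep child height
        return kept[0]
    return TreeNode(node.height, children=kept)


def clade_sets(root: TreeNode) -> set[frozenset[str]]:
    """Leaf sets of internal nodes, excluding the root and singletons."""
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode, is_root: bool) -> frozenset[str]:
        if not node.children:
            return frozenset([node.label])
        members = frozenset().union(*(walk(c, False) for c in node.children))
        if not is_root and len(members) > 1:
            out.add(members)
        return members

    walk(root, True)
    return out


def cut_tree_k(root: TreeNode, k: int) -> dict[str, int]:
    """Cut into exactly ``k`` clusters by descending merge height."""
    leaves = sorted(root.leaves())
    n = len(leaves)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}")
    # remove the k-1 highest internal nodes (ties by leaf count, then leaf
    # order, for determinism); clusters = maximal remaining subtrees
    internal: list[tuple[float, int, TreeNode]] = []

    def collect(node: TreeNode) -> None:
        if node.children:
            internal.append((node.height, len(node.leaves()), node))
            for c in node.children:
                collect(c)

    collect(root)
    internal.sort(key=lambda item: (-item[0], -item[1]))
    removed = {id(item[2]) for item in internal[: k - 1]}

    assignment: dict[str, int] = {}
    next_id = 0

    def assign(node: TreeNode) -> None:
        nonlocal next_id
        if node.children and id(node) in removed:
            for c in node.children:
                assign(c)
        else:
            next_id += 1
            for leaf in sorted(node.leaves()):
                assignment[leaf] = next_id

    assign(root)
    return assignment


def fowlkes_mallows(a: TreeNode, b: TreeNode, k: int) -> float:
    """``B_k`` between the k-cluster cuts of two trees over shared leaves.

    ``B_k = T / sqrt(P * Q)`` with T the number of leaf pairs co-clustered
    in both trees and P, Q the within-tree co-clustered pair counts;
    0 (flagged degenerate upstream) when either cut is all singletons.
    """
    from sklearn.metrics import fowlkes_mallows_score

    leaves = sorted(a.leaves() & b.leaves())
    n = len(leaves)
    if not (2 <= k <= n - 1):
        raise ValueError(f"k must be in 2..{n - 1}")
    ca = cut_tree_k(a, k)
    cb = cut_tree_k(b, k)
    la = [ca[leaf] for leaf in leaves]
    lb = [cb[leaf] for leaf in leaves]
    if len(set(la)) == n or len(set(lb)) == n:
        return 0.0  # all singletons: no co-clustered pairs to agree on
    return float(fowlkes_mallows_score(la, lb))


def cophenetic_vector(root: TreeNode) -> tuple[list[str], np.ndarray]:
    """Condensed matrix of pairwise merge heights (lowest common ancestor)."""
    leaves = sorted(root.leaves())
    index = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))

    def walk(node: TreeNode) -> list[int]:
        if not node.children:
            return [index[node.label]]
        groups = [walk(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for i in groups[gi]:
                    for j in groups[gj]:
                        D[i, j] = D[j, i] = node.height
        return [i for g in groups for i in g]

    walk(root)
    return leaves, D[np.triu_indices(n, k=1)]


def cophenetic_correlation(a: TreeNode, b: TreeNode) -> float:
    """Pearson r between the cophenetic distance vectors of two trees."""
    la, da = cophenetic_vector(a)
    lb, db = cophenetic_vector(b)
    if la != lb:
        raise ValueError("trees must be restricted to the same leaves first")
    if np.std(da) == 0 or np.std(db) == 0:
        raise ValueError("zero cophenetic variance; correlation undefined")
    return float(np.corrcoef(da, db)[0, 1])


@dataclass
class TreeComparison:
    tree_a: str
    tree_b: str
    common_leaves: int
    shared_clades: int
    clades_a: int
    clades_b: int
    fraction_shared_a: float
    fraction_shared_b: float
    fm_at_k: dict[int, float]
    cophenetic_r: float

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["fm_at_k"] = {str(k): v for k, v in self.fm_at_k.items()}
        return d


def compare_trees(
    a: TreeNode,
    b: TreeNode,
    name_a: str = "tree_a",
    name_b: str = "tree_b",
    fm_ks: tuple[int, ...] | None = None,
) -> TreeComparison:
    """Full comparison of two trees over their common leaves."""
    ra, rb = restrict_to_common_leaves(a, b)
    clades_a = clade_sets(ra)
    clades_b = clade_sets(rb)
    shared = clades_a & clades_b
    n = len(ra.leaves())
    if fm_ks is None:
        fm_ks = tuple(sorted({2, max(2, n // 10), max(2, n // 4)}))
    fm = {k: fowlkes_mallows(ra, rb, k) for k in fm_ks if 2 <= k <= n - 1}
    return TreeComparison(
        tree_a=name_a,
        tree_b=name_b,
        common_leaves=n,
        shared_clades=len(shared),
        clades_a=len(clades_a),
        clades_b=len(clades_b),
        fraction_shared_a=len(shared) / len(clades_a) if clades_a else 0.0,
        fraction_shared_b=len(shared) / len(clades_b) if clades_b else 0.0,
        fm_at_k=fm,
        cophenetic_r=cophenetic_correlation(ra, rb),
    )
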