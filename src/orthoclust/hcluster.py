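"""Agglomerative hierarchical clustering on Pearson-correlation distances.

The clustering primitive is implemented from first principles: distances are
``d = 1 - r`` (range [0, 2]) computed over pairwise-complete (jointly
unmasked) features, and trees are built by repeated merging of the closest
cluster pair with Lance-Williams distance updates (average, complete or
single linkage).  Trees are cut at a *relative branch height* -- a fixed
fraction of the root merge height -- and exported as Newick.

Conventions that matter for reproducibility:

* Undefined distances (joint support < ``min_support`` features, or zero
  variance over the joint support) are set to ``D_MAX = 2.0`` ("maximally
  dissimilar") and counted.
* Merge ties are broken by the lowest (row, row) index pair, rows being the
  original matrix row indices (a merged cluster inherits the smallest row
  index of its members), so results are order-stable.
* Merges whose height equals the cut height exactly are applied (<=).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

D_MAX = 2.0

LINKAGES = ("average", "complete", "single")


@dataclass(frozen=True)
class DistanceMatrix:
    """Condensed Pearson distance matrix with per-pair feature support."""

    n: int
    condensed: np.ndarray  # shape (n*(n-1)//2,), values in [0, 2]
    pair_support: np.ndarray  # same shape, number of jointly unmasked features
    n_undefined: int = 0  # pairs that fell back to D_MAX

    def square(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.condensed, checks=False)


@dataclass(frozen=True)
class Dendrogram:
    """Merge list over matrix rows.

    Leaves are numbered ``0..n_leaves-1``; the t-th merge creates internal
    node ``n_leaves + t`` (the scipy convention).  ``merges`` has one row
    ``(left, right, height, size)`` per merge.
    """

    n_leaves: int
    merges: np.ndarray  # shape (n_leaves - 1, 4)

    def __post_init__(self) -> None:
        if self.merges.shape != (max(self.n_leaves - 1, 0), 4):
            raise ValueError("merge list must have exactly n-1 rows of 4")

    @property
    def root_height(self) -> float:
        return float(self.merges[-1, 2]) if len(self.merges) else 0.0

    def leaf_order(self) -> list[int]:
        """Leaves left-to-right as they appear in the dendrogram layout."""
        if self.n_leaves == 1:
            return [0]
        order: list[int] = []
        stack = [self.n_leaves + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                left, right = self.merges[node - self.n_leaves, :2]
                stack.append(int(right))  # right popped after left
                stack.append(int(left))
        return order

    def clades(self, include_root: bool = False) -> list[frozenset[int]]:
        """Leaf sets of internal nodes (singletons excluded)."""
        sets: dict[int, frozenset[int]] = {}
        out: list[frozenset[int]] = []
        for t, (left, right, _h, _s) in enumerate(self.merges):
            members = frozenset()
            for child in (int(left), int(right)):
                members |= (
                    frozenset([child]) if child < self.n_leaves else sets[child]
                )
            sets[self.n_leaves + t] = members
            out.append(members)
        if not include_root and out:
            out = out[:-1]
        return out


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat clustering obtained by cutting a dendrogram."""

    cut_height: float
    relative_fraction: float
    cluster_of_row: np.ndarray  # row -> cluster id in 1..k
    k: int

    def as_dict(self, labels: list[str]) -> dict[str, int]:
        return {lab: int(c) for lab, c in zip(labels, self.cluster_of_row)}


def pearson_distance(
    x: np.ndarray,
    y: np.ndarray,
    x_mask: np.ndarray | None = None,
    y_mask: np.ndarray | None = None,
    min_support: int = 3,
) -> float:
    """Pearson distance ``1 - r`` over jointly unmasked positions.

    Returns ``nan`` when the joint support is below ``min_support`` or either
    vector has zero variance over that support; callers substitute
    :data:`D_MAX`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    joint = np.ones(len(x), dtype=bool)
    if x_mask is not None:
        joint &= np.asarray(x_mask, dtype=bool)
    if y_mask is not None:
        joint &= np.asarray(y_mask, dtype=bool)
    xs, ys = x[joint], y[joint]
    if len(xs) < min_support:
        return float("nan")
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    vx, vy = (xs**2).sum(), (ys**2).sum()
    if vx <= 0 or vy <= 0:
        return float("nan")
    r = float((xs * ys).sum() / np.sqrt(vx * vy))
    return 1.0 - min(1.0, max(-1.0, r))


def pairwise_distances(
    values: np.ndarray, mask: np.ndarray | None = None, min_support: int = 3
) -> DistanceMatrix:
    """All-pairs pairwise-complete Pearson distances for a row matrix.

    Vectorised with matrix products over the 0/1 mask; identical (to fp
    rounding) to calling :func:`pearson_distance` per pair.
    """
    X = np.asarray(values, dtype=float)
    n, m = X.shape
    W = (
        np.ones_like(X)
        if mask is None
        else np.asarray(mask, dtype=float).reshape(n, m)
    )
    Xw = np.nan_to_num(X) * W

    cnt = W @ W.T
    sx = Xw @ W.T  # sx[i, j] = sum of x_i over joint support with j
    sxx = (Xw * Xw) @ W.T
    sxy = Xw @ Xw.T

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = cnt * sxy - sx * sx.T
        varx = cnt * sxx - sx**2
        vary = varx.T
        r = cov / np.sqrt(varx * vary)
    r = np.clip(r, -1.0, 1.0)
    d = 1.0 - r

    iu = np.triu_indices(n, k=1)
    condensed = d[iu]
    support = cnt[iu].astype(int)
    bad = (support < min_support) | ~np.isfinite(condensed)
    n_undefined = int(bad.sum())
    if n_undefined:
        logger.warning(
            "%d distance pairs undefined (support < %d or zero variance); "
            "set to d_max = %.1f",
            n_undefined,
            min_support,
            D_MAX,
        )
        condensed = condensed.copy()
        condensed[bad] = D_MAX
    condensed = np.clip(condensed, 0.0, D_MAX)
    return DistanceMatrix(n, condensed, support, n_undefined)


def agglomerate(D: DistanceMatrix | np.ndarray, linkage: str = "average") -> Dendrogram:
    """Build a dendrogram by repeated nearest-pair merging.

    Inter-cluster distances are updated by the Lance-Williams recurrences:
    size-weighted mean (average), max (complete) or min (single).  Ties are
    broken by the lowest (i, j) position pair; a merged cluster is stored at
    the smaller of its parents' positions, so positions track the minimum
    original row index of each cluster.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if isinstance(D, DistanceMatrix):
        n, sq = D.n, D.square()
    else:
        sq = np.asarray(D, dtype=float)
        n = sq.shape[0]
    if not np.isfinite(sq).all():
        raise ValueError("distance matrix contains non-finite values")
    if n == 1:
        return Dendrogram(1, np.empty((0, 4)))

    W = sq.astype(float).copy()
    np.fill_diagonal(W, np.inf)
    sizes = np.ones(n)
    node_id = np.arange(n)
    active = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 4))
    prev_height = -np.inf

    for t in range(n - 1):
        flat = int(np.argmin(W))  # row-major first min = lowest (i, j) pair
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        h = W[i, j]
        merges[t] = (node_id[i], node_id[j], h, sizes[i] + sizes[j])
        if linkage in ("average", "complete"):
            # both linkages are monotone; tolerate fp jitter only
            assert h >= prev_height - 1e-9, "non-monotone merge heights"
        prev_height = max(prev_height, h)

        di, dj = W[i], W[j]
        if linkage == "average":
            new = (sizes[i] * di + sizes[j] * dj) / (sizes[i] + sizes[j])
        elif linkage == "complete":
            new = np.maximum(di, dj)
        else:
            new = np.minimum(di, dj)
        new[~active] = np.inf
        new[i] = np.inf
        new[j] = np.inf
        W[i, :] = new
        W[:, i] = new
        W[j, :] = np.inf
        W[:, j] = np.inf
        sizes[i] += sizes[j]
        node_id[i] = n + t
        active[j] = False

    return Dendrogram(n, merges)


def cut_relative(tree: Dendrogram, fraction: float = 0.75) -> ClusterAssignment:
    """Cut at ``fraction`` of the root merge height.

    All merges with height <= the cut height are applied; the clusters are
    the resulting components, numbered 1..k by leftmost-leaf order in the
    dendrogram layout.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n = tree.n_leaves
    cut_height = fraction * tree.root_height
    parent = np.arange(n + max(n - 1, 0))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for t, (left, right, h, _s) in enumerate(tree.merges):
        if h <= cut_height:
            node = n + t
            parent[find(int(left))] = node
            parent[find(int(right))] = node

    roots = np.array([find(i) for i in range(n)])
    # number clusters by first appearance in the dendrogram leaf order
    order = tree.leaf_order()
    labels = np.zeros(n, dtype=int)
    next_id = 0
    seen: dict[int, int] = {}
    for leaf in order:
        r = int(roots[leaf])
        if r not in seen:
            next_id += 1
            seen[r] = next_id
    for i in range(n):
        labels[i] = seen[int(roots[i])]
    return ClusterAssignment(float(cut_height), float(fraction), labels, next_id)


def to_newick(tree: Dendrogram, labels: list[str] | None = None) -> str:
    """Serialise as Newick with ultrametric branch lengths.

    A leaf's branch length is its parent's merge height; an internal node's
    is the height difference to its parent.  The root carries no length.
    """
    n = tree.n_leaves
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels must cover all leaves")
    if len(set(labels)) != n:
        raise ValueError("duplicate leaf labels")
    if n == 1:
        return f"{labels[0]};"

    heights = {i: 0.0 for i in range(n)}
    for t, (_l, _r, h, _s) in enumerate(tree.merges):
        heights[n + t] = float(h)

    def render(node: int, parent_height: float) -> str:
        length = parent_height - heights[node]
        if node < n:
            return f"{labels[node]}:{length:.12g}"
        left, right, h, _ = tree.merges[node - n]
        inner = f"({render(int(left), h)},{render(int(right), h)})"
        return f"{inner}:{length:.12g}"

    root = n + len(tree.merges) - 1
    left, right, h, _ = tree.merges[root - n]
    return f"({render(int(left), float(h))},{render(int(right), float(h))});"


def from_newick(text: str) -> tuple[Dendrogram, list[str]]:
    """Parse an ultrametric Newick string back into a merge list.

    Inverse of :func:`to_newick` up to sibling order: node heights are
    recovered from cumulative branch lengths (leaves are assumed to sit at
    height 0) and merges are re-emitted in non-decreasing height order.
    Returns the dendrogram and the leaf labels in row order.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    body = text[:-1]
    pos = 0

    def parse() -> dict:
        nonlocal pos
        node: dict = {"children": [], "label": "", "length": 0.0}
        if body[pos] == "(":
            pos += 1
            while True:
                node["children"].append(parse())
                if body[pos] == ",":
                    pos += 1
                    continue
                if body[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(body) and body[pos] not in ",():;":
            pos += 1
        node["label"] = body[start:pos]
        if pos < len(body) and body[pos] == ":":
            pos += 1
            start = pos
            while pos < len(body) and body[pos] not in ",()":
                pos += 1
            node["length"] = float(body[start:pos])
        return node

    root = parse()
    if not root["children"]:
        return Dendrogram(1, np.empty((0, 4))), [root["label"]]

    labels: list[str] = []
    internal: list[tuple[float, list]] = []  # (height, child leaf-id lists)

    def depth_below(node: dict) -> float:
        if not node["children"]:
            return 0.0
        return max(c["length"] + depth_below(c) for c in node["children"])

    def walk(node: dict) -> list[int]:
        if not node["children"]:
            labels.append(node["label"])
            return [len(labels) - 1]
        groups = [walk(c) for c in node["children"]]
        if len(groups) != 2:
            raise ValueError("dendrogram Newick must be strictly binary")
        internal.append((depth_below(node), groups))
        return [i for g in groups for i in g]

    walk(root)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels")

    n = len(labels)
    internal.sort(key=lambda item: item[0])
    node_of: dict[frozenset[int], int] = {frozenset([i]): i for i in range(n)}
    merges = np.empty((n - 1, 4))
    for t, (h, (ga, gb)) in enumerate(internal):
        a, b = frozenset(ga), frozenset(gb)
        left, right = sorted((node_of[a], node_of[b]))
        merges[t] = (left, right, h, len(a) + len(b))
        node_of[a | b] = n + t
    return Dendrogram(n, merges), labels
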