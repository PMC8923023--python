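"""Independent brute-force oracles shared across test modules."""

import numpy as np


def naive_agglomerate(square, linkage):
    """O(n^3) oracle: recompute every inter-cluster distance from scratch.

    Distances come straight from the original matrix (mean over all cross
    pairs for average linkage, max for complete, min for single); the pair
    with minimal distance merges, ties broken by lowest minimum-leaf-index
    pair.  Deliberately shares no code with the implementation under test.
    """
    n = square.shape[0]
    clusters = [(i, [i]) for i in range(n)]  # (node_id, members)
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ds = [
                    square[i, j]
                    for i in clusters[a][1]
                    for j in clusters[b][1]
                ]
                d = {
                    "average": sum(ds) / len(ds),
                    "complete": max(ds),
                    "single": min(ds),
                }[linkage]
                ma, mb = min(clusters[a][1]), min(clusters[b][1])
                key = (d, min(ma, mb), max(ma, mb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        ida, members_a = clusters[a]
        idb, members_b = clusters[b]
        merges.append((ida, idb, d, len(members_a) + len(members_b)))
        merged = (next_id, members_a + members_b)
        next_id += 1
        clusters = [
            c for k, c in enumerate(clusters) if k not in (a, b)
        ] + [merged]
    return merges


def clade_heights(n, merges):
    """Set of (frozen leaf set, height) pairs for topology comparison."""
    members = {i: frozenset([i]) for i in range(n)}
    out = set()
    for t, (left, right, h, _s) in enumerate(merges):
        clade = members[int(left)] | members[int(right)]
        members[n + t] = clade
        out.add((clade, round(float(h), 10)))
    return out


def brute_force_recovered(assignment, edges):
    """Oracle: scan every edge, count those whose endpoints share a cluster."""
    n = 0
    for e in edges:
        a, b = tuple(e)
        if a in assignment and b in assignment and assignment[a] == assignment[b]:
            n += 1
    return n
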