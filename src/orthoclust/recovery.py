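"""Interaction catalogs and recovery scoring of clusterings.

A clustering of co-expressed ortholog families is useful to the extent that
experimentally established interaction partners (a GTPase and its GEFs/GAPs,
say) end up in the same cluster.  The catalog holds *primary* edges (direct,
experimentally established partners); *secondary* edges connect a family to
the other interactors of its primary partners (the endpoints of length-2
paths).  A catalog edge is recovered by a clustering when both endpoints are
assigned and share a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

Edge = frozenset  # of two family ids


@dataclass
class InteractionCatalog:
    """Primary edges plus derived secondary edges between families."""

    primary_edges: set[Edge]
    secondary_edges: set[Edge]
    sources: dict[Edge, str] = field(default_factory=dict)
    out_of_matrix: set[str] = field(default_factory=set)
    """Partners that are not rows of the clustering matrix (e.g. scaffold
    proteins); their edges stay in the catalog but are excluded from
    recovery denominators."""

    def edges(self, level: str) -> set[Edge]:
        if level == "primary":
            return set(self.primary_edges)
        if level == "primary_and_secondary":
            return self.primary_edges | self.secondary_edges
        raise ValueError(f"unknown level {level!r}")

    def scoreable_edges(self, level: str) -> set[Edge]:
        """Edges whose endpoints are all in-matrix families."""
        return {
            e for e in self.edges(level) if not (e & self.out_of_matrix)
        }


def expand_secondary(
    primary_edges: set[Edge],
    sources: dict[Edge, str] | None = None,
    out_of_matrix: set[str] | None = None,
) -> InteractionCatalog:
    """Derive secondary edges as endpoints of length-2 primary paths.

    Secondary edges never duplicate primary edges and never form
    self-pairs.
    """
    primary = set()
    for e in primary_edges:
        if len(e) != 2:
            raise ValueError(f"self-edge or malformed edge: {set(e)}")
        primary.add(frozenset(e))
    neighbours: dict[str, set[str]] = {}
    for e in primary:
        a, b = tuple(e)
        neighbours.setdefault(a, set()).add(b)
        neighbours.setdefault(b, set()).add(a)
    secondary: set[Edge] = set()
    for partners in neighbours.values():
        secondary.update(
            frozenset(pair) for pair in combinations(sorted(partners), 2)
        )
    secondary -= primary
    return InteractionCatalog(
        primary, secondary, sources or {}, out_of_matrix or set()
    )


@dataclass
class RecoveryReport:
    """Recovery score of one clustering against one catalog."""

    name: str
    k: int
    cut_fraction: float
    level: str
    recovered: int
    total_edges: int
    absent_endpoint_edges: int
    per_cluster_edges: dict[int, list[tuple[str, str]]]

    @property
    def recovered_fraction(self) -> float:
        return self.recovered / self.total_edges if self.total_edges else 0.0


def count_recovered(
    assignment: dict[str, int],
    catalog: InteractionCatalog,
    level: str = "primary_and_secondary",
    name: str = "clustering",
    cut_fraction: float = float("nan"),
) -> RecoveryReport:
    """Count catalog edges whose endpoints share a cluster.

    Edges with an endpoint absent from the assignment (dropped row, missing
    family) count as not recovered and are reported separately; each catalog
    edge is counted at most once globally.
    """
    edges = catalog.scoreable_edges(level)
    per_cluster: dict[int, list[tuple[str, str]]] = {}
    recovered = 0
    absent = 0
    for edge in sorted(edges, key=lambda e: tuple(sorted(e))):
        a, b = tuple(sorted(edge))
        ca, cb = assignment.get(a), assignment.get(b)
        if ca is None or cb is None:
            absent += 1
        elif ca == cb:
            recovered += 1
            per_cluster.setdefault(int(ca), []).append((a, b))
    k = len(set(assignment.values()))
    return RecoveryReport(
        name=name,
        k=k,
        cut_fraction=cut_fraction,
        level=level,
        recovered=recovered,
        total_edges=len(edges),
        absent_endpoint_edges=absent,
        per_cluster_edges=per_cluster,
    )


def compare_clusterings(reports: list[RecoveryReport]) -> pd.DataFrame:
    """Rank clusterings by recovered interactions (descending, ties by name)."""
    if len(reports) < 2:
        raise ValueError("need at least 2 clusterings to compare")
    df = pd.DataFrame(
        {
            "name": [r.name for r in reports],
            "k": [r.k for r in reports],
            "cut_fraction": [r.cut_fraction for r in reports],
            "level": [r.level for r in reports],
            "recovered": [r.recovered for r in reports],
            "total_edges": [r.total_edges for r in reports],
            "absent_endpoint_edges": [r.absent_endpoint_edges for r in reports],
        }
    )
    return df.sort_values(
        ["recovered", "name"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
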