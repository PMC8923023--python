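"""Score clusterings by how many known interactions they recover.

Expands a primary interaction catalog with secondary edges (partners of
partners), counts edges whose endpoints co-cluster, and ranks an
average-linkage against a complete-linkage clustering of the same data.
"""

from orthoclust import SimConfig, simulate_dataset
from orthoclust.hcluster import agglomerate, cut_relative, pairwise_distances
from orthoclust.io import blocks_from_tables
from orthoclust.recovery import (
    compare_clusterings,
    count_recovered,
    expand_secondary,
)
from orthoclust.standardize import assemble_matrix

dataset = simulate_dataset(SimConfig(seed=3, n_families=80, n_modules=10))
blocks = blocks_from_tables(dataset.tables, dataset.block_layout)
matrix = assemble_matrix(blocks, dataset.ortholog_map, ["Ddis", "Dpur"])

catalog = expand_secondary(dataset.truth.planted_edges)
print(
    f"catalog: {len(catalog.primary_edges)} primary edges, "
    f"{len(catalog.secondary_edges)} derived secondary edges"
)

reports = []
for linkage in ("average", "complete"):
    tree = agglomerate(pairwise_distances(matrix.values, matrix.mask), linkage)
    cut = cut_relative(tree, 0.75)
    reports.append(
        count_recovered(
            cut.as_dict(matrix.family_ids),
            catalog,
            level="primary_and_secondary",
            name=linkage,
            cut_fraction=0.75,
        )
    )

print(compare_clusterings(reports).to_string(index=False))
# "recovered" counts catalog edges whose two families share a cluster;
# the ranking shows which linkage keeps interacting proteins together.
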