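"""End-to-end driver: the five clustering analyses, comparison and scoring.

``run_pipeline`` assembles one standardized ortholog matrix per named
species subset, builds the dendrogram (Pearson distance, configurable
linkage), cuts at the relative height, scores interaction recovery, and --
optionally -- attaches multiscale bootstrap support; it then compares all
subset trees pairwise and ranks the clusterings by recovered interactions.
The default subsets mirror the canonical analysis design: Group4
(Ddis + Dpur), BranchII (+ Dlac), Ddisonly, Fullprofile (all five), plus a
complete-linkage rerun of Group4.

All outputs are plain text (TSV / Newick / JSON); a manifest records the
config, seed and input checksums so reruns are verifiable byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .hcluster import (
    agglomerate,
    cut_relative,
    pairwise_distances,
    to_newick,
)
from .msboot import BootConfig, node_support, support_table
from .recovery import compare_clusterings, count_recovered, expand_secondary
from .treecmp import compare_trees, tree_from_dendrogram

logger = logging.getLogger(__name__)

DEFAULT_SUBSETS: dict[str, tuple[tuple[str, ...], str]] = {
    "Group4": (("Ddis", "Dpur"), "average"),
    "BranchII": (("Ddis", "Dpur", "Dlac"), "average"),
    "Ddisonly": (("Ddis",), "average"),
    "Fullprofile": (("Ddis", "Dpur", "Dlac", "Ppal", "Dfas"), "average"),
    "Group4Complete": (("Ddis", "Dpur"), "complete"),
}


@dataclass
class PipelineConfig:
    subsets: dict[str, tuple[tuple[str, ...], str]] = field(
        default_factory=lambda: dict(DEFAULT_SUBSETS)
    )
    cut_fraction: float = 0.75
    recovery_level: str = "primary_and_secondary"
    min_features: int = 4
    low_coverage_threshold: int = 10
    bootstrap: BootConfig | None = None
    bootstrap_subsets: tuple[str, ...] = ()
    seed: int = 0


@dataclass
class SubsetResult:
    name: str
    matrix: "object"
    tree: "object"
    assignment: "object"
    newick: str
    recovery: "object"
    supports: list | None = None


@dataclass
class PipelineResult:
    subsets: dict[str, SubsetResult]
    comparison_table: pd.DataFrame
    tree_comparisons: list
    manifest: dict


def validate_inputs(indir: str | Path) -> dict[str, list[str]]:
    """Schema checks before any computation; errors vs warnings separated."""
    indir = Path(indir)
    errors: list[str] = []
    warnings: list[str] = []
    try:
        tables, layout = oio.read_expression_tables(indir)
    except (OSError, ValueError, KeyError) as exc:
        return {"errors": [f"cannot read expression tables: {exc}"],
                "warnings": []}

    for sp, df in tables.items():
        missing = {"gene_id", "block_id", "label", "count"} - set(df.columns)
        if missing:
            errors.append(f"{sp}: missing columns {sorted(missing)}")
            continue
        bad = df[pd.to_numeric(df["count"], errors="coerce") < 0]
        for rec in bad.itertuples(index=False):
            errors.append(
                f"{sp}: negative count {rec.count} for gene {rec.gene_id} "
                f"block {rec.block_id}"
            )
        known_blocks = {b["block_id"] for b in layout[sp]}
        stray = set(df["block_id"]) - known_blocks
        if stray:
            errors.append(f"{sp}: blocks not in layout: {sorted(stray)}")
        labels_of = {
            b["block_id"]: list(b["labels"]) for b in layout[sp]
        }
        for (gene, block), sub in df.groupby(["gene_id", "block_id"], sort=False):
            if block in labels_of and sorted(sub["label"]) != sorted(
                labels_of[block]
            ):
                errors.append(
                    f"{sp}: gene {gene} block {block} has inconsistent labels"
                )

    try:
        omap = oio.read_ortholog_map(indir / "ortholog_map.tsv")
    except (OSError, ValueError) as exc:
        errors.append(f"ortholog map: {exc}")
        omap = None
    if omap is not None:
        for rec in omap.itertuples(index=False):
            if rec.species not in tables:
                errors.append(
                    f"ortholog map references unknown species {rec.species}"
                )
                break
        genes_by_sp = {sp: set(df["gene_id"]) for sp, df in tables.items()}
        for rec in omap.itertuples(index=False):
            if rec.species in genes_by_sp and rec.gene_id not in genes_by_sp[
                rec.species
            ]:
                warnings.append(
                    f"gene {rec.gene_id} ({rec.species}) in map but has no "
                    f"expression data"
                )

    cat_path = indir / "catalog.tsv"
    if cat_path.exists() and omap is not None:
        cat = oio.read_catalog_table(cat_path)
        families = set(omap["family_id"])
        for rec in cat.itertuples(index=False):
            for fam in (rec.family_a, rec.family_b):
                if fam not in families:
                    warnings.append(
                        f"catalog family {fam} absent from ortholog map "
                        f"(out-of-matrix partner)"
                    )
    return {"errors": errors, "warnings": warnings}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    indir: str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every named subset analysis plus cross-subset comparison.

    ``indir`` holds a dataset bundle as written by
    :func:`orthoclust.io.write_dataset` (or hand-prepared in the same
    layout).  When ``outdir`` is given, all artefacts are written there.
    """
    config = config or PipelineConfig()
    indir = Path(indir)

    report = validate_inputs(indir)
    if report["errors"]:
        raise ValueError(
            "input validation failed:\n" + "\n".join(report["errors"])
        )
    for w in report["warnings"]:
        logger.info("validation warning: %s", w)

    tables, layout = oio.read_expression_tables(indir)
    blocks = oio.blocks_from_tables(tables, layout)
    omap = oio.read_ortholog_map(indir / "ortholog_map.tsv")

    catalog = None
    cat_path = indir / "catalog.tsv"
    if cat_path.exists():
        cat = oio.read_catalog_table(cat_path)
        primary = {
            frozenset((r.family_a, r.family_b))
            for r in cat.itertuples(index=False)
            if r.level == "primary"
        }
        known = set(omap["family_id"])
        out_of_matrix = {
            f
            for r in cat.itertuples(index=False)
            for f in (r.family_a, r.family_b)
            if f not in known
        }
        catalog = expand_secondary(primary, out_of_matrix=out_of_matrix)

    from .standardize import assemble_matrix

    results: dict[str, SubsetResult] = {}
    for name, (species, linkage) in config.subsets.items():
        matrix = assemble_matrix(
            blocks,
            omap,
            list(species),
            min_features=config.min_features,
            low_coverage_threshold=config.low_coverage_threshold,
        )
        logger.info(
            "subset %s: %d families x %d features (%d dropped)",
            name,
            *matrix.shape,
            len(matrix.dropped),
        )
        D = pairwise_distances(matrix.values, matrix.mask)
        tree = agglomerate(D, linkage)
        assignment = cut_relative(tree, config.cut_fraction)
        newick = to_newick(tree, matrix.family_ids)
        recovery = None
        if catalog is not None:
            recovery = count_recovered(
                assignment.as_dict(matrix.family_ids),
                catalog,
                level=config.recovery_level,
                name=name,
                cut_fraction=config.cut_fraction,
            )
        supports = None
        if config.bootstrap and name in config.bootstrap_subsets:
            supports = node_support(
                matrix.values, tree, config.bootstrap, matrix.mask
            )
        results[name] = SubsetResult(
            name, matrix, tree, assignment, newick, recovery, supports
        )

    comparison = None
    if catalog is not None:
        comparison = compare_clusterings(
            [r.recovery for r in results.values()]
        )

    tree_cmps = []
    names = list(results)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = results[names[i]], results[names[j]]
            try:
                tree_cmps.append(
                    compare_trees(
                        tree_from_dendrogram(a.tree, a.matrix.family_ids),
                        tree_from_dendrogram(b.tree, b.matrix.family_ids),
                        names[i],
                        names[j],
                    )
                )
            except ValueError as exc:
                logger.warning(
                    "tree comparison %s vs %s skipped: %s",
                    names[i], names[j], exc,
                )

    manifest = {
        "seed": config.seed,
        "cut_fraction": config.cut_fraction,
        "recovery_level": config.recovery_level,
        "subsets": {
            name: {"species": list(sp), "linkage": lk}
            for name, (sp, lk) in config.subsets.items()
        },
        "inputs": {
            p.name: _sha256(p) for p in sorted(indir.glob("*")) if p.is_file()
        },
        "rows": {name: r.matrix.shape[0] for name, r in results.items()},
        "features": {name: r.matrix.shape[1] for name, r in results.items()},
    }

    out = PipelineResult(results, comparison, tree_cmps, manifest)
    if outdir is not None:
        _write_bundle(out, Path(outdir))
    return out


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, r in result.subsets.items():
        (outdir / f"{name}.nwk").write_text(r.newick + "\n")
        oio.write_matrix(r.matrix, outdir / f"{name}.matrix")
        pd.DataFrame(
            {
                "family_id": r.matrix.family_ids,
                "cluster_id": r.assignment.cluster_of_row,
            }
        ).to_csv(outdir / f"{name}.clusters.tsv", sep="\t", index=False)
        if r.recovery is not None:
            rows = [
                (cl, a, b)
                for cl, edges in sorted(r.recovery.per_cluster_edges.items())
                for a, b in edges
            ]
            pd.DataFrame(
                rows, columns=["cluster_id", "family_a", "family_b"]
            ).to_csv(outdir / f"{name}.cluster_edges.tsv", sep="\t", index=False)
        if r.supports is not None:
            support_table(r.supports, r.matrix.family_ids).to_csv(
                outdir / f"{name}.support.tsv", sep="\t", index=False
            )
    if result.comparison_table is not None:
        result.comparison_table.to_csv(
            outdir / "clustering_comparison.tsv", sep="\t", index=False
        )
    with open(outdir / "tree_comparisons.json", "w") as fh:
        json.dump([c.as_dict() for c in result.tree_comparisons], fh, indent=1)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
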