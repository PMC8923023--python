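"""Readers and writers for the pipeline's tabular formats.

Everything on disk is plain text: per-species expression TSVs
(``gene_id, block_id, label, count``) with a ``blocks.json`` sidecar
describing each species' block layout, an ortholog-map TSV
(``family_id, species, gene_id``), an interaction-catalog TSV
(``family_a, family_b, level, source``), ground truth as JSON, assembled
matrices as TSV with a JSON sidecar for features and masks, and trees as
Newick.  A reader for supplementary-table-style XLSX workbooks (one sheet
per analysis, one row per family, labelled feature columns) lets the
pipeline ingest pre-standardized matrices directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .standardize import BlockKind, Feature, ProfileBlock, ProfileMatrix
from .synthdata import SyntheticDataset


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write a synthetic dataset bundle (expression, map, catalog, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, df in dataset.tables.items():
        df.to_csv(outdir / f"expression_{sp}.tsv", sep="\t", index=False)
    with open(outdir / "blocks.json", "w") as fh:
        json.dump(dataset.block_layout, fh, indent=1, sort_keys=True)
    dataset.ortholog_map.to_csv(
        outdir / "ortholog_map.tsv", sep="\t", index=False
    )
    dataset.catalog.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    truth = {
        "module_of_family": dataset.truth.module_of_family,
        "planted_edges": sorted(
            sorted(edge) for edge in dataset.truth.planted_edges
        ),
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_expression_tables(
    indir: str | Path,
) -> tuple[dict[str, pd.DataFrame], dict[str, list[dict]]]:
    """Read per-species expression TSVs and the block-layout sidecar."""
    indir = Path(indir)
    with open(indir / "blocks.json") as fh:
        layout = json.load(fh)
    tables = {}
    for sp in layout:
        path = indir / f"expression_{sp}.tsv"
        tables[sp] = pd.read_csv(
            path, sep="\t", dtype={"gene_id": str, "block_id": str, "label": str}
        )
    return tables, layout


def blocks_from_tables(
    tables: dict[str, pd.DataFrame], layout: dict[str, list[dict]]
) -> dict[str, dict[str, list[ProfileBlock]]]:
    """Regroup long-format count tables into per-gene ProfileBlock lists."""
    out: dict[str, dict[str, list[ProfileBlock]]] = {}
    for sp, df in tables.items():
        per_gene: dict[str, list[ProfileBlock]] = {}
        pivot: dict[tuple[str, str], dict[str, float]] = {}
        for rec in df.itertuples(index=False):
            pivot.setdefault((rec.gene_id, rec.block_id), {})[rec.label] = (
                rec.count
            )
        genes = dict.fromkeys(df["gene_id"])
        for gene in genes:
            blocks = []
            for spec in layout[sp]:
                lab2val = pivot.get((gene, spec["block_id"]), {})
                values = np.array(
                    [lab2val.get(lab, 0.0) for lab in spec["labels"]], dtype=float
                )
                blocks.append(
                    ProfileBlock(
                        gene_id=gene,
                        species=sp,
                        kind=BlockKind(spec["kind"]),
                        labels=tuple(spec["labels"]),
                        values=values,
                    )
                )
            per_gene[gene] = blocks
        out[sp] = per_gene
    return out


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "species", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"ortholog map needs columns {sorted(required)}")
    return df


def read_catalog_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_a", "family_b", "level"}
    if not required <= set(df.columns):
        raise ValueError(f"catalog needs columns {sorted(required)}")
    return df


def write_matrix(matrix: ProfileMatrix, prefix: str | Path) -> None:
    """Assembled matrix as TSV plus JSON sidecar (features, masks, drops)."""
    prefix = Path(prefix)
    cols = [f"{f.species}|{f.block_id}|{f.label}" for f in matrix.features]
    pd.DataFrame(
        matrix.values, index=matrix.family_ids, columns=cols
    ).rename_axis("family_id").to_csv(f"{prefix}.tsv", sep="\t")
    sidecar = {
        "features": [
            {"species": f.species, "block_id": f.block_id, "label": f.label}
            for f in matrix.features
        ],
        "mask": matrix.mask.astype(int).tolist(),
        "family_ids": matrix.family_ids,
        "dropped": matrix.dropped,
    }
    with open(f"{prefix}.features.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_matrix(prefix: str | Path) -> ProfileMatrix:
    prefix = Path(prefix)
    df = pd.read_csv(f"{prefix}.tsv", sep="\t", index_col="family_id")
    with open(f"{prefix}.features.json") as fh:
        sidecar = json.load(fh)
    features = [Feature(**f) for f in sidecar["features"]]
    return ProfileMatrix(
        family_ids=list(df.index),
        features=features,
        values=df.to_numpy(dtype=float),
        mask=np.asarray(sidecar["mask"], dtype=bool),
        dropped=sidecar.get("dropped", {}),
    )


def read_xlsx_matrix(
    path: str | Path,
    sheet: str,
    family_column: str | int = 0,
    feature_columns: list[str] | None = None,
) -> ProfileMatrix:
    """Read a pre-standardized matrix from a supplementary-style workbook.

    One row per ortholog family; the first (or named) column holds the
    family identifier and every numeric column is a feature.  Missing cells
    become masked positions.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    if isinstance(family_column, int):
        family_column = df.columns[family_column]
    df = df.set_index(family_column)
    if feature_columns is not None:
        df = df[feature_columns]
    df = df.apply(pd.to_numeric, errors="coerce")
    df = df.dropna(axis=1, how="all")
    values = df.to_numpy(dtype=float)
    mask = np.isfinite(values)
    values = np.nan_to_num(values)
    features = [Feature("xlsx", "sheet", str(c)) for c in df.columns]
    return ProfileMatrix(
        family_ids=[str(i) for i in df.index],
        features=features,
        values=values,
        mask=mask,
    )
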