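"""Standardisation of raw read counts and assembly of ortholog linear arrays.

Developmental (and encystation) time courses are rescaled to the fraction of
their maximum read count; cell-type blocks (prestalk/prespore fractions,
mature cell types) to the fraction of their summed reads.  The standardized
blocks of one ortholog family's members across a chosen species subset are
concatenated, in a fixed (species, block) order, into a single "linear
array" -- one row of the clustering matrix.

Blocks with at most ``LOW_COVERAGE_THRESHOLD`` total reads carry little
information and are masked out of distance computations (the heatmap
equivalent is a washed-out colour), as are blocks of a species where the
family has no member.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

LOW_COVERAGE_THRESHOLD = 10
MIN_FEATURES = 4  # Pearson needs >= 3 points; one extra for margin


class BlockKind(str, Enum):
    DEVELOPMENTAL = "developmental"
    TWO_PART_FRACTION = "two_part_fraction"
    MULTI_CELLTYPE = "multi_celltype"
    ENCYSTATION = "encystation"

    @property
    def standardizer(self) -> str:
        """Which rescaling applies: time series -> max, cell types -> sum."""
        if self in (BlockKind.DEVELOPMENTAL, BlockKind.ENCYSTATION):
            return "max"
        return "sum"


@dataclass(frozen=True)
class ProfileBlock:
    """One experiment's raw counts for one gene."""

    gene_id: str
    species: str
    kind: BlockKind
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(self.labels) != len(values):
            raise ValueError("labels and values must have equal length")
        if len(values) and values.min() < 0:
            raise ValueError("read counts must be non-negative")
        if self.kind == BlockKind.TWO_PART_FRACTION and len(values) != 2:
            raise ValueError("two_part_fraction blocks carry exactly 2 values")


@dataclass(frozen=True)
class StandardizedBlock:
    gene_id: str
    species: str
    kind: BlockKind
    labels: tuple[str, ...]
    values: np.ndarray  # in [0, 1]
    all_zero: bool
    low_coverage: bool

    @property
    def usable(self) -> bool:
        return not (self.all_zero or self.low_coverage)


def fraction_of_max(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Rescale to fraction of the maximum; all-zero input stays zero."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value vector")
    top = v.max()
    if top <= 0:
        return np.zeros_like(v), True
    return v / top, False


def fraction_of_sum(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Rescale to fraction of the sum; zero-sum input stays zero."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value vector")
    total = v.sum()
    if total <= 0:
        return np.zeros_like(v), True
    return v / total, False


def mask_low_coverage(
    values: np.ndarray, threshold: int = LOW_COVERAGE_THRESHOLD
) -> bool:
    """True when the block's summed reads are at or below ``threshold``."""
    v = np.asarray(values, dtype=float)
    return bool(v.sum() <= threshold) if v.size else True


def standardize_block(
    block: ProfileBlock, threshold: int = LOW_COVERAGE_THRESHOLD
) -> StandardizedBlock:
    fn = fraction_of_max if block.kind.standardizer == "max" else fraction_of_sum
    values, all_zero = fn(block.values)
    return StandardizedBlock(
        gene_id=block.gene_id,
        species=block.species,
        kind=block.kind,
        labels=block.labels,
        values=values,
        all_zero=all_zero,
        low_coverage=mask_low_coverage(block.values, threshold),
    )


@dataclass(frozen=True)
class Feature:
    """Descriptor of one column of the assembled matrix."""

    species: str
    block_id: str
    label: str


@dataclass
class ProfileMatrix:
    """Assembled linear arrays: one row per ortholog family.

    ``mask`` marks usable positions; masked values carry no semantics.
    """

    family_ids: list[str]
    features: list[Feature]
    values: np.ndarray  # (n_families, n_features) in [0, 1]
    mask: np.ndarray  # boolean, same shape
    dropped: dict[str, str] = field(default_factory=dict)  # family -> reason

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, family_id: str) -> int:
        return self.family_ids.index(family_id)


def assemble_matrix(
    blocks: dict[str, dict[str, list[ProfileBlock]]],
    ortholog_map: pd.DataFrame,
    species_subset: list[str],
    min_features: int = MIN_FEATURES,
    low_coverage_threshold: int = LOW_COVERAGE_THRESHOLD,
) -> ProfileMatrix:
    """Concatenate per-family standardized blocks across a species subset.

    Parameters
    ----------
    blocks
        ``blocks[species][gene_id]`` -> the gene's ProfileBlocks, in the
        species' canonical block order (identical for all genes of a
        species).
    ortholog_map
        Columns ``family_id, species, gene_id``.
    species_subset
        Ordered species identifiers; fixes the feature order.

    When a family has several paralogs in one species, the member with the
    highest summed reads represents the family.  Families with fewer than
    ``min_features`` usable features are dropped and reported in
    ``ProfileMatrix.dropped``.
    """
    missing = [s for s in species_subset if s not in blocks]
    if missing:
        raise ValueError(f"no expression data for species: {missing}")

    # canonical block layout per species, taken from the first gene
    layout: dict[str, list[tuple[str, BlockKind, tuple[str, ...]]]] = {}
    for sp in species_subset:
        first = next(iter(blocks[sp].values()))
        layout[sp] = [(_block_id(i, b), b.kind, b.labels) for i, b in enumerate(first)]

    features: list[Feature] = []
    spans: dict[str, slice] = {}
    for sp in species_subset:
        start = len(features)
        for block_id, _kind, labels in layout[sp]:
            features.extend(Feature(sp, block_id, lab) for lab in labels)
        spans[sp] = slice(start, len(features))

    fam_members: dict[str, dict[str, list[str]]] = {}
    for rec in ortholog_map.itertuples(index=False):
        fam_members.setdefault(rec.family_id, {}).setdefault(
            rec.species, []
        ).append(rec.gene_id)

    rows: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    kept: list[str] = []
    dropped: dict[str, str] = {}

    for family_id in sorted(fam_members):
        values = np.zeros(len(features))
        mask = np.zeros(len(features), dtype=bool)
        for sp in species_subset:
            genes = [
                g
                for g in fam_members[family_id].get(sp, [])
                if g in blocks[sp]
            ]
            if not genes:
                continue  # species span stays masked
            gene = max(
                genes, key=lambda g: sum(b.values.sum() for b in blocks[sp][g])
            )
            offset = spans[sp].start
            for block in blocks[sp][gene]:
                std = standardize_block(block, low_coverage_threshold)
                width = len(std.values)
                values[offset : offset + width] = std.values
                mask[offset : offset + width] = std.usable
                offset += width
        if int(mask.sum()) < min_features:
            dropped[family_id] = (
                f"only {int(mask.sum())} usable features (< {min_features})"
            )
            continue
        kept.append(family_id)
        rows.append(values)
        masks.append(mask)

    if not kept:
        return ProfileMatrix([], features, np.empty((0, len(features))),
                             np.empty((0, len(features)), dtype=bool), dropped)
    return ProfileMatrix(
        kept, features, np.vstack(rows), np.vstack(masks), dropped
    )


def _block_id(index: int, block: ProfileBlock) -> str:
    return f"{block.kind.value}_{index}"
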