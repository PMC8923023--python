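"""Synthetic multi-species expression datasets with planted co-expression.

Emulates the statistical structure of the developmental transcriptomes the
pipeline consumes: per species a read-count time course over the
developmental stages, two replicate prestalk/prespore fraction experiments
and a mature cell-type block; ortholog families spanning up to five
dictyostelid species with occasional missing members; and planted
GTPase-GEF-GAP modules whose members share a developmental archetype and a
cell-type signature, together with the ground-truth interaction edges they
imply.

Developmental archetypes follow the six canonical profile classes seen in
these organisms (constitutive, decrease after growth, mid-development peak
or dip, early or late upregulation); the template curves are fixed
piecewise-linear shapes on a unit time axis so that shape predicates are
assertable.  Counts are the template scaled to a sequencing depth with
multiplicative lognormal noise, rounded to non-negative integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ARCHETYPES = (
    "constitutive",
    "decrease_after_growth",
    "mid_peak",
    "mid_dip",
    "early_up",
    "late_up",
)

DEFAULT_SPECIES = ("Ddis", "Dpur", "Dlac", "Ppal", "Dfas")

# piecewise-linear control points on the unit time axis
_TEMPLATES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "constitutive": ((0.0, 1.0), (1.0, 1.0)),
    "decrease_after_growth": ((0.0, 0.04, 1.0), (1.0, 0.2, 0.05)),
    "mid_peak": ((0.0, 0.55, 1.0), (0.05, 1.0, 0.05)),
    "mid_dip": ((0.0, 0.45, 1.0), (1.0, 0.0, 1.0)),
    "early_up": ((0.0, 0.3, 1.0), (0.05, 1.0, 1.0)),
    "late_up": ((0.0, 0.7, 1.0), (0.05, 0.1, 1.0)),
}


def archetype_curve(name: str, n_timepoints: int) -> np.ndarray:
    """Template curve for one of the six profile classes, values in [0, 1]."""
    if name not in ARCHETYPES:
        raise ValueError(f"unknown archetype {name!r}; choose from {ARCHETYPES}")
    if n_timepoints < 4:
        raise ValueError("need at least 4 time points")
    t = np.linspace(0.0, 1.0, n_timepoints)
    xs, ys = _TEMPLATES[name]
    return np.interp(t, xs, ys)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the dataset the package's evaluation experiments run
    on: 300 ortholog families over the five species, 40 planted modules of
    3-6 co-expressed members, a 12-point developmental course plus two
    replicate 2-part fraction blocks and one 4-type mature block per
    species.
    """

    n_families: int = 300
    n_modules: int = 40
    module_size_range: tuple[int, int] = (3, 6)
    species_list: tuple[str, ...] = DEFAULT_SPECIES
    n_timepoints: int = 12
    celltype_blocks: tuple[int, ...] = (2, 2, 4)
    noise_sd: float = 0.25
    base_depth: float = 1000.0
    missing_family_rate: float = 0.2
    low_coverage_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.module_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid module size range")
        if self.n_modules * hi > self.n_families:
            raise ValueError("modules exceed available families")
        for p in (self.missing_family_rate, self.low_coverage_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.species_list) > 5:
            raise ValueError("at most 5 species supported")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    module_of_family: dict[str, int | None]
    planted_edges: set[frozenset[str]]

    def module_labels(self, family_ids: list[str]) -> np.ndarray:
        """Integer labels per family; singletons get unique negative ids."""
        labels = np.empty(len(family_ids), dtype=int)
        next_single = -1
        for i, fam in enumerate(family_ids):
            mod = self.module_of_family.get(fam)
            if mod is None:
                labels[i] = next_single
                next_single -= 1
            else:
                labels[i] = mod
        return labels


@dataclass
class SyntheticDataset:
    config: SimConfig
    tables: dict[str, pd.DataFrame]  # species -> (gene_id, block_id, label, count)
    block_layout: dict[str, list[dict]]  # species -> block descriptors
    ortholog_map: pd.DataFrame  # family_id, species, gene_id
    catalog: pd.DataFrame  # family_a, family_b, level, source
    truth: GroundTruth


def _module_plan(cfg: SimConfig, rng: np.random.Generator) -> dict[str, int | None]:
    fams = [f"fam{i:04d}" for i in range(cfg.n_families)]
    lo, hi = cfg.module_size_range
    module_of: dict[str, int | None] = {f: None for f in fams}
    cursor = 0
    for mod in range(cfg.n_modules):
        size = int(rng.integers(lo, hi + 1))
        for f in fams[cursor : cursor + size]:
            module_of[f] = mod
        cursor += size
    return module_of


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate the dataset, ortholog map, interaction catalog and truth.

    Module members share one developmental archetype and one cell-type
    signature across every species where they are present; background
    families draw their own.  Each module is wired as a hub (the GTPase)
    with primary edges to every other member (its regulators).
    """
    root = np.random.SeedSequence(config.seed)
    ss_plan, ss_profiles, *ss_species = root.spawn(2 + len(config.species_list))
    rng = np.random.default_rng(ss_plan)

    module_of = _module_plan(config, rng)
    fams = list(module_of)

    prof_rng = np.random.default_rng(ss_profiles)
    module_arch = {
        m: ARCHETYPES[int(prof_rng.integers(len(ARCHETYPES)))]
        for m in range(config.n_modules)
    }
    module_sig = {
        m: [prof_rng.dirichlet(np.ones(k)) for k in config.celltype_blocks]
        for m in range(config.n_modules)
    }
    fam_arch: dict[str, str] = {}
    fam_sig: dict[str, list[np.ndarray]] = {}
    for fam in fams:
        mod = module_of[fam]
        if mod is None:
            fam_arch[fam] = ARCHETYPES[int(prof_rng.integers(len(ARCHETYPES)))]
            fam_sig[fam] = [
                prof_rng.dirichlet(np.ones(k)) for k in config.celltype_blocks
            ]
        else:
            fam_arch[fam] = module_arch[mod]
            fam_sig[fam] = module_sig[mod]

    # presence: each family may lack a species member, but keeps >= 1 member
    presence: dict[str, list[str]] = {}
    for fam in fams:
        drop = rng.random(len(config.species_list)) < config.missing_family_rate
        if drop.all():
            drop[int(rng.integers(len(config.species_list)))] = False
        presence[fam] = [
            sp for sp, d in zip(config.species_list, drop) if not d
        ]

    block_specs: list[tuple[str, str, list[str]]] = [
        (
            "developmental_0",
            "developmental",
            [f"t{i}" for i in range(config.n_timepoints)],
        )
    ]
    for bi, k in enumerate(config.celltype_blocks):
        if k == 2:
            block_specs.append(
                (f"two_part_fraction_{bi + 1}", "two_part_fraction",
                 ["prestalk", "prespore"])
            )
        else:
            block_specs.append(
                (f"multi_celltype_{bi + 1}", "multi_celltype",
                 [f"cell{j}" for j in range(k)])
            )

    tables: dict[str, pd.DataFrame] = {}
    layout: dict[str, list[dict]] = {}
    map_rows: list[tuple[str, str, str]] = []
    for sp, ss in zip(config.species_list, ss_species):
        sp_rng = np.random.default_rng(ss)
        rows: list[tuple[str, str, str, int]] = []
        for fam in fams:
            if sp not in presence[fam]:
                continue
            gene = f"{sp}_{fam}"
            map_rows.append((fam, sp, gene))
            dev = archetype_curve(fam_arch[fam], config.n_timepoints)
            profiles = [dev] + [np.asarray(sig) for sig in fam_sig[fam]]
            for (block_id, _kind, labels), template in zip(block_specs, profiles):
                depth = config.base_depth
                if sp_rng.random() < config.low_coverage_rate:
                    depth = 10.0 / max(len(labels), 1)
                noise = (
                    np.exp(sp_rng.normal(0.0, config.noise_sd, len(labels)))
                    if config.noise_sd > 0
                    else np.ones(len(labels))
                )
                counts = np.rint(depth * template * noise).astype(int)
                counts = np.maximum(counts, 0)
                rows.extend(
                    (gene, block_id, lab, int(c))
                    for lab, c in zip(labels, counts)
                )
        tables[sp] = pd.DataFrame(
            rows, columns=["gene_id", "block_id", "label", "count"]
        )
        layout[sp] = [
            {"block_id": bid, "kind": kind, "labels": labels}
            for bid, kind, labels in block_specs
        ]

    edges: set[frozenset[str]] = set()
    modules: dict[int, list[str]] = {}
    for fam, mod in module_of.items():
        if mod is not None:
            modules.setdefault(mod, []).append(fam)
    for members in modules.values():
        hub = members[0]
        edges.update(frozenset((hub, other)) for other in members[1:])

    catalog = pd.DataFrame(
        sorted((tuple(sorted(e)) + ("primary", "planted")) for e in edges),
        columns=["family_a", "family_b", "level", "source"],
    )
    ortholog_map = pd.DataFrame(
        map_rows, columns=["family_id", "species", "gene_id"]
    )
    truth = GroundTruth(module_of, edges)
    return SyntheticDataset(config, tables, layout, ortholog_map, catalog, truth)
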