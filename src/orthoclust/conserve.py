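"""Expression-class calls, phylogenetic change patterns, and conservation tables.

Each ortholog family's standardized developmental series is assigned to one
of six canonical profile classes (constitutive, decrease after growth,
mid-development peak/dip, early/late upregulation) by explicit threshold
rules; cell-type specificity (prestalk/prespore, mature cell types,
encystation) is called from fraction blocks; and 5-species
presence/conservation flags are summarised as phylogenetic change patterns
(all five conserved, group-4-specific change, branch I vs branch II change,
single-species change, scattered).  ``tabulate`` turns a set of records into
percentage tables split by conservation class, family, or both.

The five species in fixed order are Ddis and Dpur (group 4), Dlac (group 3;
groups 3+4 form branch II) and Ppal and Dfas (groups 1-2, branch I).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .synthdata import ARCHETYPES

SPECIES_ORDER = ("Ddis", "Dpur", "Dlac", "Ppal", "Dfas")
GROUP4 = frozenset({0, 1})  # Ddis, Dpur
BRANCH_II = frozenset({0, 1, 2})  # Ddis, Dpur, Dlac
BRANCH_I = frozenset({3, 4})  # Ppal, Dfas

PHYLO_PATTERNS = (
    "all_five",
    "group4_specific_change",
    "branchI_vs_branchII",
    "single_species",
    "scattered",
)

SLUG_CALLS = ("prestalk", "prespore", "none", "conflict")
MATURE_CALLS = ("spore", "stalk", "cup", "growth", "none", "conflict")
ENCYSTATION_CALLS = ("up", "down", "constitutive", "none")


@dataclass(frozen=True)
class ClassifierRules:
    """Threshold constants for the six-class profile call."""

    constitutive_range: float = 0.5  # max-min at or below -> constitutive
    decrease_tail_mean: float = 0.5  # mean after t0 below -> decrease
    dip_end_min: float = 0.75  # both ends at least -> mid_dip eligible
    peak_end_max: float = 0.5  # both ends at most -> mid_peak eligible
    specificity_fraction: float = 2.0 / 3.0  # cell-type call threshold


DEFAULT_RULES = ClassifierRules()


def _in_middle_third(i: int, n: int) -> bool:
    """Index fraction within the central third of the series."""
    t = i / (n - 1)
    return 1.0 / 3.0 <= t <= 2.0 / 3.0


def classify_profile(
    s: np.ndarray, rules: ClassifierRules = DEFAULT_RULES
) -> str:
    """Assign a standardized developmental series to one of the six classes.

    Rules apply in order: constitutive (small range), decrease after growth
    (maximal at t0, low afterwards), mid-development dip, mid-development
    peak, early upregulation, else late upregulation.  All-zero series are
    classified ``none`` and excluded from tabulations.
    """
    s = np.asarray(s, dtype=float)
    n = len(s)
    if n < 4:
        raise ValueError("need at least 4 time points")
    if s.min() < 0 or s.max() > 1:
        raise ValueError("series must be standardized to [0, 1]")
    if s.max() == 0:
        return "none"
    argmax = int(np.argmax(s))
    argmin = int(np.argmin(s))
    if s.max() - s.min() <= rules.constitutive_range:
        return "constitutive"
    if argmax == 0 and s[1:].mean() < rules.decrease_tail_mean:
        return "decrease_after_growth"
    if (
        _in_middle_third(argmin, n)
        and s[0] >= rules.dip_end_min
        and s[-1] >= rules.dip_end_min
    ):
        return "mid_dip"
    if (
        _in_middle_third(argmax, n)
        and s[0] <= rules.peak_end_max
        and s[-1] <= rules.peak_end_max
    ):
        return "mid_peak"
    if 0 < argmax < n / 2:
        return "early_up"
    return "late_up"


def phylo_pattern(diff: tuple[bool, ...]) -> str:
    """Pattern of a 5-species difference vector (True = differs from majority).

    Symmetric under complementing the vector, so the result does not depend
    on which state is called the majority.
    """
    if len(diff) != 5:
        raise ValueError("difference vector must cover the 5 species")
    changed = frozenset(i for i, d in enumerate(diff) if d)
    for group in (changed, frozenset(range(5)) - changed):
        if group == frozenset():
            return "all_five"
        if group == GROUP4:
            return "group4_specific_change"
        if group in (BRANCH_I, BRANCH_II):
            return "branchI_vs_branchII"
        if len(group) == 1:
            return "single_species"
    return "scattered"


def call_slug_specificity(
    replicates: list[np.ndarray],
    rules: ClassifierRules = DEFAULT_RULES,
) -> str:
    """Prestalk/prespore call from replicate 2-part fraction blocks.

    Specific when the same cell type holds at least the threshold fraction
    in every replicate; ``conflict`` when replicates call different types;
    ``none`` otherwise (no preference, or no data).
    """
    calls = []
    for rep in replicates:
        rep = np.asarray(rep, dtype=float)
        if rep.shape != (2,):
            raise ValueError("slug blocks carry (prestalk, prespore) fractions")
        if rep[0] >= rules.specificity_fraction:
            calls.append("prestalk")
        elif rep[1] >= rules.specificity_fraction:
            calls.append("prespore")
        else:
            calls.append("none")
    if not calls:
        return "none"
    distinct = set(calls)
    specific = distinct - {"none"}
    if len(specific) > 1:
        return "conflict"
    if len(specific) == 1 and distinct == specific:
        return specific.pop()
    return "none"


def call_mature_specificity(
    fractions: np.ndarray,
    celltypes: tuple[str, ...] = ("growth", "spore", "stalk", "cup"),
    rules: ClassifierRules = DEFAULT_RULES,
) -> str:
    """Mature cell-type call from a fraction-of-sum block."""
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != len(celltypes):
        raise ValueError("one fraction per cell type required")
    if fractions.sum() <= 0:
        return "none"
    top = int(np.argmax(fractions))
    if fractions[top] >= rules.specificity_fraction:
        return celltypes[top]
    return "none"


def call_encystation(series: np.ndarray, rules: ClassifierRules = DEFAULT_RULES) -> str:
    """Up/down/constitutive call for an encystation time course."""
    s = np.asarray(series, dtype=float)
    if s.size == 0 or s.max() <= 0:
        return "none"
    s = s / s.max()
    if s.max() - s.min() <= rules.constitutive_range:
        return "constitutive"
    return "up" if int(np.argmax(s)) > int(np.argmin(s)) else "down"


def majority_profile(calls: list[str]) -> str:
    """Modal expression class across species; ties or no data give ``none``."""
    valid = [c for c in calls if c in ARCHETYPES]
    if not valid:
        return "none"
    counts = pd.Series(valid).value_counts()
    top = counts.max()
    winners = counts[counts == top]
    return winners.index[0] if len(winners) == 1 else "none"


@dataclass
class ConservationRecord:
    """Per-family conservation and expression summary."""

    family_id: str
    category: str  # GTPase / GEF / GAP / ...
    present_in: tuple[bool, bool, bool, bool, bool]
    domain_conserved: tuple[bool, ...]
    regulation_conserved: tuple[bool, ...]
    majority_profile: str
    slug_call: str = "none"
    mature_call: str = "none"
    encystation_call: str = "none"

    def __post_init__(self) -> None:
        if not any(self.present_in):
            raise ValueError("family must be present in at least one species")

    @property
    def n_species(self) -> int:
        return sum(self.present_in)

    @property
    def is_unique(self) -> bool:
        return self.n_species == 1

    @property
    def host_species(self) -> str | None:
        if not self.is_unique:
            return None
        return SPECIES_ORDER[self.present_in.index(True)]

    def domain_pattern(self) -> str:
        return phylo_pattern(
            tuple(
                p and not d for p, d in zip(self.present_in, self.domain_conserved)
            )
        )

    def regulation_pattern(self) -> str:
        return phylo_pattern(
            tuple(
                p and not r
                for p, r in zip(self.present_in, self.regulation_conserved)
            )
        )


PROFILE_COLUMNS = ARCHETYPES  # printed column order of the class table


def _round_to_sum(raw: np.ndarray, total: float = 100.0, decimals: int = 1) -> np.ndarray:
    """Largest-remainder rounding so the row sums exactly to ``total``."""
    scale = 10**decimals
    scaled = raw * scale
    floored = np.floor(scaled)
    shortfall = int(round(total * scale - floored.sum()))
    order = np.argsort(-(scaled - floored), kind="stable")
    floored[order[:shortfall]] += 1
    return floored / scale


def _percent_table(
    groups: dict[str, list[str]], columns: tuple[str, ...]
) -> pd.DataFrame:
    rows = {}
    for group, calls in groups.items():
        valid = [c for c in calls if c in columns]
        if not valid:
            continue  # empty group omitted (noted by absence)
        counts = pd.Series(valid).value_counts()
        raw = np.array(
            [100.0 * counts.get(col, 0) / len(valid) for col in columns]
        )
        rows[group] = _round_to_sum(raw)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(columns))


def tabulate(
    records: list[ConservationRecord], split_by: str = "conservation_class"
) -> dict[str, pd.DataFrame]:
    """Percentage tables over a set of conservation records.

    ``split_by``: ``conservation_class`` (conserved = present in all five
    species vs unique to one, the class-table layout), ``family`` (the
    ``category`` field), or ``combined`` (one row over all records).
    Every row of every table sums to 100 within rounding.
    """
    if not records:
        raise ValueError("no records to tabulate")

    def group_of(rec: ConservationRecord) -> str:
        if split_by == "conservation_class":
            if rec.n_species == 5:
                return "conserved"
            return "unique" if rec.is_unique else "partial"
        if split_by == "family":
            return rec.category
        if split_by == "combined":
            return "all"
        raise ValueError(f"unknown split_by {split_by!r}")

    def collect(value_of) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for rec in records:
            groups.setdefault(group_of(rec), []).append(value_of(rec))
        return groups

    n_species_cols = tuple(str(i) for i in range(1, 6))
    host_cols = SPECIES_ORDER
    return {
        "profile": _percent_table(
            collect(lambda r: r.majority_profile), PROFILE_COLUMNS
        ),
        "slug": _percent_table(collect(lambda r: r.slug_call), SLUG_CALLS),
        "mature": _percent_table(collect(lambda r: r.mature_call), MATURE_CALLS),
        "encystation": _percent_table(
            collect(lambda r: r.encystation_call), ENCYSTATION_CALLS
        ),
        "orthologs_of_five": _percent_table(
            collect(lambda r: str(r.n_species)), n_species_cols
        ),
        "unique_host": _percent_table(
            collect(lambda r: r.host_species or "not_unique"),
            host_cols + ("not_unique",),
        ),
        "domain_pattern": _percent_table(
            collect(lambda r: r.domain_pattern()), PHYLO_PATTERNS
        ),
        "regulation_pattern": _percent_table(
            collect(lambda r: r.regulation_pattern()), PHYLO_PATTERNS
        ),
    }
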