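"""Multiscale bootstrap support (BP and AU) for dendrogram clades.

Feature columns (stage or cell-type measurements) are resampled with
replacement at a range of sample-size scales; each replicate matrix is
re-clustered and a clade's *bootstrap probability* at scale ``r`` is the
fraction of replicate trees containing its exact leaf set.  Fitting the
normal-quantile transform of those proportions against the scale,

    z_r = Phi^-1(1 - bp_r) ~ v * sqrt(r) + c / sqrt(r),

separates signed distance ``v`` from boundary curvature ``c`` and yields the
approximately unbiased support ``au = 1 - Phi(v - c)`` and the bias-corrected
plain bootstrap ``bp = 1 - Phi(v + c)``.

Degenerate clades (recovered in essentially none or all replicates at nearly
every scale, leaving fewer than 3 scales with proportions strictly inside
(0, 1)) cannot support the two-parameter fit; they fall back to the plain
recovery proportion at scale 1.0 with ``fit_ok=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .hcluster import Dendrogram, agglomerate, pairwise_distances

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5..1.4


@dataclass(frozen=True)
class BootConfig:
    scales: tuple[float, ...] = DEFAULT_SCALES
    B: int = 1000
    seed: int = 0
    linkage: str = "average"
    min_support: int = 3

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")
        if self.B < 100:
            raise ValueError("need B >= 100 replicates for AU fitting")


@dataclass
class NodeSupport:
    """Support values for one internal clade."""

    clade: frozenset[int]
    bp_at_scale: dict[float, float]
    v: float
    c: float
    au: float
    bp: float
    fit_ok: bool


def resample_columns(
    values: np.ndarray,
    mask: np.ndarray | None,
    scale: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw ``round(scale * m)`` feature columns with replacement.

    Masks travel with their columns so pairwise-complete distances stay
    meaningful on the replicate.
    """
    m = values.shape[1]
    if m < 4:
        raise ValueError("need at least 4 feature columns")
    m_star = int(round(scale * m))
    if m_star < 3:
        raise ValueError(f"scale {scale} leaves fewer than 3 columns")
    idx = rng.integers(0, m, size=m_star)
    return values[:, idx], None if mask is None else mask[:, idx]


def fit_au(
    counts: np.ndarray, scales: np.ndarray, B: int
) -> tuple[float, float, float, float, bool]:
    """Least-squares AU/BP fit from per-scale recovery counts.

    Returns ``(v, c, au, bp, fit_ok)``.  Only scales with raw proportion
    strictly inside (0, 1) enter the fit; with fewer than 3 such scales the
    plain proportion at the scale nearest 1.0 is returned instead.
    Weighted least squares (weights ``B * phi(z)^2 / (p (1 - p))``) is used
    when every fitted proportion is interior, which all are by construction.
    """
    counts = np.asarray(counts, dtype=float)
    scales = np.asarray(scales, dtype=float)
    usable = (counts > 0) & (counts < B)
    if usable.sum() < 3:
        nearest = int(np.argmin(np.abs(scales - 1.0)))
        p = counts[nearest] / B
        return 0.0, 0.0, float(p), float(p), False

    r = scales[usable]
    p = (counts[usable] + 0.5) / (B + 1)  # continuity correction
    z = norm.ppf(1.0 - p)
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    w = B * norm.pdf(z) ** 2 / (p * (1.0 - p))
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    au = float(1.0 - norm.cdf(v - c))
    bp = float(1.0 - norm.cdf(v + c))
    return v, c, au, bp, True


def clade_recovery_counts(
    values: np.ndarray,
    clades: list[frozenset[int]],
    config: BootConfig,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-clade, per-scale counts of replicate trees containing each clade.

    Replicates derive per-scale seeds deterministically from
    ``config.seed``; the clades may be arbitrary leaf sets (they need not
    come from a tree).
    """
    import logging

    counts = np.zeros((len(clades), len(config.scales)), dtype=int)
    # undefined-distance fallbacks inside replicates are routine; silence them
    hlog = logging.getLogger("orthoclust.hcluster")
    old_level = hlog.level
    hlog.setLevel(logging.ERROR)
    try:
        seed_seqs = np.random.SeedSequence(config.seed).spawn(len(config.scales))
        for si, (scale, ss) in enumerate(zip(config.scales, seed_seqs)):
            rng = np.random.default_rng(ss)
            for _ in range(config.B):
                v_star, m_star = resample_columns(values, mask, scale, rng)
                D = pairwise_distances(v_star, m_star, config.min_support)
                rep_tree = agglomerate(D, config.linkage)
                rep_clades = set(rep_tree.clades(include_root=False))
                for ci, clade in enumerate(clades):
                    if clade in rep_clades:
                        counts[ci, si] += 1
    finally:
        hlog.setLevel(old_level)
    return counts


def node_support(
    values: np.ndarray,
    tree: Dendrogram,
    config: BootConfig,
    mask: np.ndarray | None = None,
) -> list[NodeSupport]:
    """BP/AU support for every internal clade of ``tree`` (root excluded).

    ``tree`` should have been built from ``values``/``mask`` with the same
    linkage and distance settings.
    """
    clades = tree.clades(include_root=False)
    targets = [c for c in clades if len(c) >= 2]
    counts = clade_recovery_counts(values, targets, config, mask)

    scales = np.asarray(config.scales, dtype=float)
    out: list[NodeSupport] = []
    for ci, clade in enumerate(targets):
        v, c, au, bp, ok = fit_au(counts[ci], scales, config.B)
        out.append(
            NodeSupport(
                clade=clade,
                bp_at_scale={
                    float(s): counts[ci, si] / config.B
                    for si, s in enumerate(config.scales)
                },
                v=v,
                c=c,
                au=au,
                bp=bp,
                fit_ok=ok,
            )
        )
    return out


def support_table(supports: list[NodeSupport], labels: list[str]):
    """Tabular view (one row per clade) ready for TSV export."""
    import pandas as pd

    rows = []
    for s in supports:
        row = {
            "clade": ",".join(sorted(labels[i] for i in s.clade)),
            "size": len(s.clade),
            "au": s.au,
            "bp": s.bp,
            "v": s.v,
            "c": s.c,
            "fit_ok": s.fit_ok,
        }
        row.update({f"bp_scale_{k}": v for k, v in s.bp_at_scale.items()})
        rows.append(row)
    return pd.DataFrame(rows)
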