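"""Per-genome COG-category profiles and guild comparison statistics.

A genome's profile is the percentage of its protein-coding genes in
each single-letter COG functional category (the denominator is the
total gene count, so unannotated genes dilute all categories; a gene
annotated with several letters counts once in each).

The guild comparison labels a category ``+``/``-`` for the guild with
the larger/smaller mean when a two-sided rank-sum test is significant
*and* the mean difference is at least ``min_diff`` percentage points —
a declared, testable stand-in for the unstated labelling rule of the
published per-guild table.  Marker COG frequency ratios (e.g. a
cytochrome-P450-like family about 11x more abundant in K-strategists)
are reported as guild means of copies per genome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import COG_CATEGORIES, Proteome

log = logging.getLogger("guildphylo")


@dataclass
class COGProfile:
    """Category gene counts and percentages for one genome."""

    genome_id: str
    total_protein_genes: int
    counts: dict[str, int]
    marker_copies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_protein_genes <= 0:
            raise ValueError(f"genome {self.genome_id!r} has no genes")

    def percentage(self, category: str) -> float:
        return 100.0 * self.counts.get(category, 0) / self.total_protein_genes

    @property
    def percentages(self) -> dict[str, float]:
        return {c: self.percentage(c) for c in self.counts}


@dataclass
class CategoryComparison:
    mean_k: float
    mean_r: float
    label_k: str  # '+', '-' or ''
    label_r: str
    p_value: float

    @property
    def rounded(self) -> tuple[int, int]:
        """Means at the table's printed precision (whole percent)."""
        return round(self.mean_k), round(self.mean_r)


@dataclass
class GuildComparison:
    categories: dict[str, CategoryComparison]
    n_k: int
    n_r: int

    def labelled(self) -> dict[str, str]:
        """category -> guild-K label for every non-blank category."""
        return {c: v.label_k for c, v in self.categories.items() if v.label_k}


def category_percentages(proteome: Proteome) -> COGProfile:
    """Count category memberships; the denominator is all protein genes."""
    if len(proteome) == 0:
        raise ValueError(f"genome {proteome.genome_id!r} has zero genes")
    counts: dict[str, int] = {}
    markers: dict[str, int] = {}
    for gid, _seq in proteome.genes:
        ann = proteome.annotations.get(gid)
        if ann is None:
            continue
        cog_id, cats = ann
        bad = set(cats) - COG_CATEGORIES
        if bad:
            raise ValueError(f"unknown COG category letter(s) {sorted(bad)} on {gid!r}")
        for c in cats:
            counts[c] = counts.get(c, 0) + 1
        markers[cog_id] = markers.get(cog_id, 0) + 1
    return COGProfile(
        genome_id=proteome.genome_id,
        total_protein_genes=len(proteome),
        counts=counts,
        marker_copies=markers,
    )


def guild_comparison(
    profiles: list[COGProfile],
    guild_of: dict[str, str],
    alpha: float = 0.05,
    min_diff: float = 1.0,
) -> GuildComparison:
    """Two-sided rank-sum comparison of category percentages between guilds.

    A category is labelled iff ``p < alpha`` and the absolute mean
    difference is at least ``min_diff`` percentage points; the guild
    with the larger mean gets ``+`` and the other ``-`` (antisymmetric
    by construction).  A guild with fewer than two genomes suppresses
    all labels (means are still reported).
    """
    k_prof = [p for p in profiles if guild_of.get(p.genome_id) == "K"]
    r_prof = [p for p in profiles if guild_of.get(p.genome_id) == "r"]
    if not k_prof or not r_prof:
        raise ValueError("both guilds must be non-empty")
    can_test = len(k_prof) >= 2 and len(r_prof) >= 2
    if not can_test:
        log.warning("a guild has < 2 genomes; labels suppressed")
    cats = sorted({c for p in profiles for c in p.counts})
    out: dict[str, CategoryComparison] = {}
    for c in cats:
        xk = np.array([p.percentage(c) for p in k_prof])
        xr = np.array([p.percentage(c) for p in r_prof])
        mean_k, mean_r = float(xk.mean()), float(xr.mean())
        if can_test and (np.ptp(xk) > 0 or np.ptp(xr) > 0 or mean_k != mean_r):
            p_value = float(stats.mannwhitneyu(xk, xr, alternative="two-sided").pvalue)
        else:
            p_value = 1.0
        label_k = label_r = ""
        if can_test and p_value < alpha and abs(mean_k - mean_r) >= min_diff:
            label_k, label_r = ("+", "-") if mean_k > mean_r else ("-", "+")
        out[c] = CategoryComparison(mean_k, mean_r, label_k, label_r, p_value)
    return GuildComparison(categories=out, n_k=len(k_prof), n_r=len(r_prof))


def marker_ratio(
    profiles: list[COGProfile], cog_id: str, guild_of: dict[str, str]
) -> tuple[float, float, float]:
    """Mean copies per genome of one COG per guild, and their K/r ratio.

    With no copies at all in guild r the ratio is reported as ``inf``
    (flagged by the caller via ``math.isinf``).
    """
    if not any(cog_id in p.marker_copies for p in profiles):
        raise ValueError(f"{cog_id} is not annotated in any genome")
    k = [p.marker_copies.get(cog_id, 0) for p in profiles if guild_of.get(p.genome_id) == "K"]
    r = [p.marker_copies.get(cog_id, 0) for p in profiles if guild_of.get(p.genome_id) == "r"]
    if not k or not r:
        raise ValueError("both guilds must be non-empty")
    mean_k = float(np.mean(k))
    mean_r = float(np.mean(r))
    if mean_r == 0.0:
        log.warning("%s absent from guild r; ratio is infinite", cog_id)
        return mean_k, mean_r, math.inf
    return mean_k, mean_r, mean_k / mean_r


def comparison_rows(comp: GuildComparison) -> list[list[object]]:
    """TSV rows mirroring the published table layout."""
    rows: list[list[object]] = []
    for c, v in sorted(comp.categories.items()):
        rk, rr = v.rounded
        rows.append([c, f"{v.mean_k:.3f}", rk, v.label_k, f"{v.mean_r:.3f}", rr, v.label_r,
                     f"{v.p_value:.3g}"])
    return rows
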