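"""CpG-island-anchored regions, variant collapsing, and cis/trans pair enumeration.

Intervals are handled 0-based half-open internally; VCF positions (1-based)
are converted at the boundary.  A CpG island can be expanded symmetrically by
2 kb ("shores") or 4 kb ("shores and shelves"), and the variants falling in
the expanded interval at a given MAF cutoff form the collapsed set tested
jointly against each methylation probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Tier",
    "GenomicInterval",
    "CpGIslandRegion",
    "TestPair",
    "expand_region",
    "collapse_variants",
    "tiered_eligibility",
    "exclude_prior_mqtl_regions",
    "enumerate_pairs",
    "trans_test_count",
    "build_regions",
]


class Tier(str, Enum):
    ISLAND = "island"
    ISLAND_SHORE = "island_shore"
    ISLAND_SHORE_SHELF = "island_shore_shelf"


TIER_PAD = {Tier.ISLAND: 0, Tier.ISLAND_SHORE: 2000, Tier.ISLAND_SHORE_SHELF: 4000}
MIN_VARIANTS_PER_REGION = 2


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("interval start must be >= 0")
        if self.start >= self.end:
            raise ValueError("interval must satisfy start < end")

    def distance_to(self, pos0: int) -> int:
        """bp distance from a 0-based point to the nearest base of the interval."""
        if pos0 < self.start:
            return self.start - pos0
        if pos0 >= self.end:
            return pos0 - (self.end - 1)
        return 0


@dataclass
class CpGIslandRegion:
    region_id: str
    island: GenomicInterval
    tier: Tier
    expanded: GenomicInterval
    variant_ids: list[str] = field(default_factory=list)
    prior_mqtl_nearby: bool = False

    @property
    def eligible(self) -> bool:
        return len(self.variant_ids) >= MIN_VARIANTS_PER_REGION


@dataclass(frozen=True)
class TestPair:
    region_id: str
    probe_id: str
    probe_pos: int  # 1-based
    relation: str  # "cis" | "trans"


def expand_region(island: GenomicInterval, tier: Tier | str) -> GenomicInterval:
    """Pad an island symmetrically by its tier (0 / 2,000 / 4,000 bp), clamped at 0."""
    tier = Tier(tier)
    pad = TIER_PAD[tier]
    return GenomicInterval(island.chrom, max(0, island.start - pad), island.end + pad)


def collapse_variants(
    variants: pd.DataFrame, region: GenomicInterval, maf_cutoff: float
) -> list[str]:
    """Variant ids inside the (expanded) region with MAF <= cutoff.

    ``variants`` needs columns id, chrom, pos (1-based), maf.  Interval
    membership uses the half-open convention on 0-based coordinates.
    """
    pos0 = variants["pos"].to_numpy() - 1
    inside = (
        (variants["chrom"].to_numpy() == region.chrom)
        & (pos0 >= region.start)
        & (pos0 < region.end)
        & (variants["maf"].to_numpy() <= maf_cutoff)
    )
    return variants.loc[inside, "id"].tolist()


def tiered_eligibility(
    islands: list[GenomicInterval], variants: pd.DataFrame, maf_cutoff: float
) -> dict[str, int]:
    """Incremental eligibility counts per tier.

    Each island is attributed to the narrowest tier at which its collapsed
    set first reaches two variants, mirroring incremental reporting
    ("islands alone / a further ... with shores / a further ... with shelves").
    """
    counts = {t.value: 0 for t in Tier}
    for island in islands:
        for tier in (Tier.ISLAND, Tier.ISLAND_SHORE, Tier.ISLAND_SHORE_SHELF):
            ids = collapse_variants(variants, expand_region(island, tier), maf_cutoff)
            if len(ids) >= MIN_VARIANTS_PER_REGION:
                counts[tier.value] += 1
                break
    return counts


def exclude_prior_mqtl_regions(
    islands: list[GenomicInterval],
    known_mqtl: pd.DataFrame | None,
    exclusion_pad: int = 5000,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Partition islands into a novel-scan set and a conditional set.

    An island joins the conditional set iff any known single-variant mQTL SNP
    lies within island +/- ``exclusion_pad`` bp (inclusive at the pad).  Such
    regions are not scanned for novel signal; they are re-tested conditioning
    on the known index SNP.  ``known_mqtl`` needs columns chrom, pos (1-based).
    """
    novel: list[GenomicInterval] = []
    conditional: list[GenomicInterval] = []
    if known_mqtl is None or len(known_mqtl) == 0:
        return list(islands), []
    chroms = known_mqtl["chrom"].to_numpy()
    pos0 = known_mqtl["pos"].to_numpy() - 1
    for island in islands:
        mask = (
            (chroms == island.chrom)
            & (pos0 >= island.start - exclusion_pad)
            & (pos0 < island.end + exclusion_pad)
        )
        (conditional if bool(mask.any()) else novel).append(island)
    return novel, conditional


def enumerate_pairs(
    regions: list[CpGIslandRegion],
    probes: pd.DataFrame,
    window_bp: int = 1_000_000,
    relation: str | None = None,
) -> list[TestPair]:
    """All region x probe test pairs, split into cis and trans.

    A pair is cis iff the probe sits on the region's chromosome within
    ``window_bp`` (inclusive) of the expanded region's nearest edge; every
    other combination is trans, so cis and trans partition the full product.
    ``probes`` needs columns probe_id, chrom, pos (1-based).
    """
    if probes["pos"].isna().any():
        missing = probes.loc[probes["pos"].isna(), "probe_id"].tolist()
        raise ValueError(f"probes without position: {missing}")
    pairs: list[TestPair] = []
    probe_rows = list(probes[["probe_id", "chrom", "pos"]].itertuples(index=False))
    for region in regions:
        exp = region.expanded
        for probe_id, chrom, pos in probe_rows:
            pos0 = int(pos) - 1
            is_cis = chrom == exp.chrom and exp.distance_to(pos0) <= window_bp
            rel = "cis" if is_cis else "trans"
            if relation is None or rel == relation:
                pairs.append(TestPair(region.region_id, probe_id, int(pos), rel))
    return pairs


def trans_test_count(n_regions: int, n_probes: int, n_cis: int) -> int:
    """Bookkeeping identity: trans tests = regions x probes - cis tests."""
    total = int(n_regions) * int(n_probes)
    if n_cis > total or n_cis < 0:
        raise ValueError("cis count must lie in [0, regions x probes]")
    return total - int(n_cis)


def build_regions(
    islands: list[GenomicInterval],
    variants: pd.DataFrame,
    tier: Tier | str,
    maf_cutoff: float,
    known_mqtl: pd.DataFrame | None = None,
    exclusion_pad: int = 5000,
) -> list[CpGIslandRegion]:
    """Construct collapsed regions at one tier/cutoff with prior-mQTL flags."""
    tier = Tier(tier)
    _, conditional = exclude_prior_mqtl_regions(islands, known_mqtl, exclusion_pad)
    conditional_set = {(i.chrom, i.start, i.end) for i in conditional}
    out = []
    for k, island in enumerate(islands):
        expanded = expand_region(island, tier)
        ids = collapse_variants(variants, expanded, maf_cutoff)
        out.append(
            CpGIslandRegion(
                region_id=f"region_{k:04d}",
                island=island,
                tier=tier,
                expanded=expanded,
                variant_ids=ids,
                prior_mqtl_nearby=(island.chrom, island.start, island.end)
                in conditional_set,
            )
        )
    return out


def region_table(regions_by_tier: dict[str, list[CpGIslandRegion]]) -> pd.DataFrame:
    """Flat TSV-ready table of regions across tiers and cutoffs."""
    rows = []
    for tier, regs in regions_by_tier.items():
        for r in regs:
            rows.append(
                {
                    "region_id": r.region_id,
                    "tier": tier,
                    "chrom": r.expanded.chrom,
                    "expanded_start": r.expanded.start,
                    "expanded_end": r.expanded.end,
                    "n_variants": len(r.variant_ids),
                    "eligible": r.eligible,
                    "conditional_flag": r.prior_mqtl_nearby,
                }
            )
    return pd.DataFrame(rows)
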