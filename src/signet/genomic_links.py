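"""Region-gene neighborhood distances and TF-region binding inclusion.

All coordinates are BED conventions: 0-based, half-open.  Distances are
measured between the two closest extremities of the intervals regardless of
orientation; overlapping or abutting intervals are at distance 0.  Pairs on
different chromosomes have no distance.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

DEFAULT_MAX_DISTANCE = 500_000  # bp


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.name!r}: [{self.start}, {self.end})"
            )
        if not self.name:
            raise ValueError("interval name must be non-empty")


@dataclass(frozen=True, order=True)
class RegionClosest:
    region_id: str
    gene_id: str
    distance: int


@dataclass(frozen=True, order=True)
class TFInclusion:
    tf_id: str
    region_id: str


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap in bp between the closest extremities of two intervals.

    Returns ``None`` for intervals on different chromosomes, 0 for
    overlapping or abutting intervals, otherwise the gap length.
    """
    if a.chrom != b.chrom:
        return None
    gap = max(a.start, b.start) - min(a.end, b.end)
    return max(gap, 0)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what} ids: {sorted(set(dups))}")


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        out[iv.chrom].append(iv)
    return out


def region_gene_neighbors(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> list[RegionClosest]:
    """All (region, gene) pairs within ``max_distance`` bp on one chromosome."""
    _check_unique([r.name for r in regions], "region")
    _check_unique([g.name for g in genes], "gene")
    out: list[RegionClosest] = []
    for chrom, chrom_genes in _by_chrom(genes).items():
        chrom_genes.sort(key=lambda g: g.start)
        gs = np.array([g.start for g in chrom_genes])
        ge = np.array([g.end for g in chrom_genes])
        names = [g.name for g in chrom_genes]
        # genes within range have start in a window bounded by the longest gene
        longest = int((ge - gs).max())
        for region in regions:
            if region.chrom != chrom:
                continue
            lo = int(np.searchsorted(gs, region.start - max_distance - longest, "left"))
            hi = int(np.searchsorted(gs, region.end + max_distance, "right"))
            if lo >= hi:
                continue
            gap = np.maximum(
                np.maximum(region.start, gs[lo:hi]) - np.minimum(region.end, ge[lo:hi]),
                0,
            )
            for idx in np.flatnonzero(gap <= max_distance):
                out.append(RegionClosest(region.name, names[lo + idx], int(gap[idx])))
    out.sort()
    return out


def tf_region_inclusion(
    tfbs: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
) -> list[TFInclusion]:
    """Binary TF-region relations: a TF is included in a region when at
    least one of its binding sites overlaps the region by >=1 bp.

    The TFBS ``name`` field holds the TF symbol; multiple sites of one TF
    in one region collapse to a single relation.
    """
    _check_unique([r.name for r in regions], "region")
    if not tfbs:
        warnings.warn("empty TFBS input: no TF-region inclusions produced")
        return []
    pairs: set[TFInclusion] = set()
    for chrom, sites in _by_chrom(tfbs).items():
        sites.sort(key=lambda s: s.start)
        ss = np.array([s.start for s in sites])
        se = np.array([s.end for s in sites])
        tf_names = [s.name for s in sites]
        longest = int((se - ss).max())
        for region in regions:
            if region.chrom != chrom:
                continue
            lo = int(np.searchsorted(ss, region.start - longest, "left"))
            hi = int(np.searchsorted(ss, region.end, "right"))
            if lo >= hi:
                continue
            hit = (ss[lo:hi] < region.end) & (se[lo:hi] > region.start)
            for idx in np.flatnonzero(hit):
                pairs.add(TFInclusion(tf_names[lo + idx], region.name))
    return sorted(pairs)
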