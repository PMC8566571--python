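"""Genomic partitioning: CpG sites, CG-groups, estimation and analysis regions.

A chromosome is tiled with fixed-size, non-overlapping *estimation regions*;
one CPEL parameter triple is fitted per estimation region.  Within a region,
nearby CpG sites form *CG-groups* (scored jointly by nanopore callers with a
single shared methylation state), and the region is split into the minimum
number of equally-sized *analysis regions* of at most ``s_max`` bp, the
resolution at which methylation statistics are reported.

Coordinates are 0-based half-open throughout.  CpG sites are strand
symmetric; only the forward-strand C position is indexed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .config import (
    DEFAULT_CG_GAP,
    DEFAULT_DENSITY_WINDOW,
    DEFAULT_MIN_CPGS,
    DEFAULT_MIN_GROUP_FRAC,
    DEFAULT_REGION_SIZE,
    DEFAULT_SMAX,
)

_DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class CpGSite:
    """Position of the forward-strand C of one CG dinucleotide."""

    chrom: str
    pos: int


@dataclass(frozen=True)
class CGGroup:
    """A cluster of nearby CpG sites called jointly with one state.

    ``first_site_idx``/``last_site_idx`` are inclusive indices into the
    parent region's CpG list; ``start``/``end`` span the member CGs
    (half-open, so ``end`` is one past the G of the last CG).
    """

    first_site_idx: int
    last_site_idx: int
    start: int
    end: int

    @property
    def n_sites(self) -> int:
        return self.last_site_idx - self.first_site_idx + 1


@dataclass(frozen=True)
class AnalysisRegion:
    """Sub-interval of an estimation region; holds K >= 0 CpG sites."""

    start: int
    end: int
    cpg_idx_range: tuple[int, int]  # half-open index range into region CpGs

    @property
    def n_sites(self) -> int:
        return self.cpg_idx_range[1] - self.cpg_idx_range[0]


@dataclass
class EstimationRegion:
    """Genomic interval carrying the full CpG hierarchy for one model fit.

    Attributes
    ----------
    cpg_positions : positions of the N CpG sites inside [start, end).
    rho : local CpG densities, one per site, each in [0, 1].
    dist : distances (bp) between consecutive CpG sites, length N - 1.
    groups : ordered CG-groups partitioning the sites.
    analysis_regions : equally-sized sub-intervals tiling [start, end).
    """

    chrom: str
    start: int
    end: int
    cpg_positions: list[int] = field(default_factory=list)
    rho: np.ndarray = field(default_factory=lambda: np.empty(0))
    dist: np.ndarray = field(default_factory=lambda: np.empty(0))
    groups: list[CGGroup] = field(default_factory=list)
    analysis_regions: list[AnalysisRegion] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.cpg_positions)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def group_of_site(self, site_idx: int) -> int:
        for g, grp in enumerate(self.groups):
            if grp.first_site_idx <= site_idx <= grp.last_site_idx:
                return g
        raise IndexError(f"site index {site_idx} not in any CG-group")

    def group_sizes(self) -> np.ndarray:
        return np.array([g.n_sites for g in self.groups], dtype=int)


def locate_cpg_sites(sequence: str, chrom: str) -> list[CpGSite]:
    """Scan a DNA sequence for CG dinucleotides (case-insensitive).

    Returns one :class:`CpGSite` per forward-strand CG occurrence, in
    ascending position order.  Characters outside {A, C, G, T, N} raise
    ``ValueError``.
    """
    seq = sequence.upper()
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    sites: list[CpGSite] = []
    i = seq.find("CG")
    while i != -1:
        sites.append(CpGSite(chrom=chrom, pos=i))
        i = seq.find("CG", i + 1)
    return sites


def build_cg_groups(positions: Sequence[int], max_gap: int = DEFAULT_CG_GAP) -> list[CGGroup]:
    """Merge consecutive CpG sites closer than ``max_gap`` bp into CG-groups.

    ``positions`` must be sorted ascending; the returned groups partition
    the sites and are ordered left to right.
    """
    if max_gap < 2:
        raise ValueError("max_gap must be >= 2")
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("CpG positions must be strictly increasing")
    groups: list[CGGroup] = []
    if not positions:
        return groups
    first = 0
    for i in range(1, len(positions) + 1):
        if i == len(positions) or positions[i] - positions[i - 1] >= max_gap:
            groups.append(
                CGGroup(
                    first_site_idx=first,
                    last_site_idx=i - 1,
                    start=positions[first],
                    end=positions[i - 1] + 2,
                )
            )
            first = i
    return groups


def make_estimation_regions(
    chrom: str, chrom_length: int, region_size: int = DEFAULT_REGION_SIZE
) -> list[EstimationRegion]:
    """Tile ``[0, chrom_length)`` with consecutive ``region_size`` intervals.

    The final interval is truncated at the chromosome end.  Returns bare
    region shells; populate them with :func:`assign_sites`.
    """
    if region_size <= 0:
        raise ValueError("region_size must be positive")
    regions = []
    for start in range(0, chrom_length, region_size):
        regions.append(
            EstimationRegion(chrom=chrom, start=start, end=min(start + region_size, chrom_length))
        )
    return regions


def make_analysis_regions(region: EstimationRegion, s_max: int = DEFAULT_SMAX) -> list[AnalysisRegion]:
    """Split a region into the minimum number of equally-sized sub-intervals.

    The count is ``ceil(length / s_max)``; sizes differ by at most 1 bp with
    the larger sizes assigned to the leftmost sub-intervals.  Each CpG site
    is assigned to the sub-interval containing its C position.
    """
    if s_max <= 0:
        raise ValueError("s_max must be positive")
    length = region.end - region.start
    if length == 0:
        return []
    count = -(-length // s_max)  # ceil division
    base, rem = divmod(length, count)
    out: list[AnalysisRegion] = []
    pos = region.start
    for i in range(count):
        size = base + (1 if i < rem else 0)
        start, end = pos, pos + size
        lo = bisect.bisect_left(region.cpg_positions, start)
        hi = bisect.bisect_left(region.cpg_positions, end)
        out.append(AnalysisRegion(start=start, end=end, cpg_idx_range=(lo, hi)))
        pos = end
    return out


def cpg_density(
    site_pos: int,
    all_positions: Sequence[int],
    chrom_length: int,
    window: int = DEFAULT_DENSITY_WINDOW,
) -> float:
    """Local CpG density rho in [0, 1] around one site.

    Counts CpG sites within the ``window`` bp interval centered on
    ``site_pos`` (clipped at the chromosome ends) and divides by the
    maximum number of CG dinucleotides such an interval can hold, i.e.
    half its effective length.
    """
    if window % 2 != 0 or window <= 0:
        raise ValueError("window must be a positive even integer")
    half = window // 2
    lo = max(0, site_pos - half)
    hi = min(chrom_length, site_pos + half)
    effective = hi - lo
    if effective <= 0:
        return 0.0
    count = bisect.bisect_left(all_positions, hi) - bisect.bisect_left(all_positions, lo)
    return count / (effective / 2)


def assign_sites(
    region: EstimationRegion,
    all_positions: Sequence[int],
    chrom_length: int,
    *,
    cg_gap: int = DEFAULT_CG_GAP,
    density_window: int = DEFAULT_DENSITY_WINDOW,
    s_max: int = DEFAULT_SMAX,
) -> EstimationRegion:
    """Populate a region shell with sites, densities, groups and sub-regions.

    ``all_positions`` is the sorted CpG position list of the whole
    chromosome (density windows may extend past the region boundary).
    """
    lo = bisect.bisect_left(all_positions, region.start)
    hi = bisect.bisect_left(all_positions, region.end)
    region.cpg_positions = list(all_positions[lo:hi])
    region.rho = np.array(
        [cpg_density(p, all_positions, chrom_length, density_window) for p in region.cpg_positions]
    )
    region.dist = np.diff(region.cpg_positions).astype(float)
    region.groups = build_cg_groups(region.cpg_positions, cg_gap)
    region.analysis_regions = make_analysis_regions(region, s_max)
    return region


def partition_chromosome(
    sequence: str,
    chrom: str,
    *,
    region_size: int = DEFAULT_REGION_SIZE,
    cg_gap: int = DEFAULT_CG_GAP,
    density_window: int = DEFAULT_DENSITY_WINDOW,
    s_max: int = DEFAULT_SMAX,
) -> list[EstimationRegion]:
    """Full pipeline: sequence -> populated estimation regions."""
    sites = locate_cpg_sites(sequence, chrom)
    positions = [s.pos for s in sites]
    regions = make_estimation_regions(chrom, len(sequence), region_size)
    for region in regions:
        assign_sites(
            region,
            positions,
            len(sequence),
            cg_gap=cg_gap,
            density_window=density_window,
            s_max=s_max,
        )
    return regions


def qualify_region(
    region: EstimationRegion,
    reads: Iterable,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    min_group_cov: float = 2.5,
    min_group_frac: float = DEFAULT_MIN_GROUP_FRAC,
) -> bool:
    """Decide whether a region carries enough data for model fitting.

    Requires at least ``min_cpgs`` CpG sites, average per-CG-group coverage
    of at least ``min_group_cov``, and calls on at least ``min_group_frac``
    of the CG-groups (default two thirds).
    """
    if region.n_sites < min_cpgs:
        return False
    if region.n_groups == 0:
        return False
    coverage = np.zeros(region.n_groups)
    for read in reads:
        for g, _, _ in read.entries:
            coverage[g] += 1
    if coverage.mean() < min_group_cov:
        return False
    if (coverage > 0).mean() < min_group_frac:
        return False
    return True


def write_regions_bed(regions: Sequence[EstimationRegion], path, *, analysis: bool = False) -> None:
    """Write estimation (or analysis) regions as a 4-column BED file."""
    with open(path, "w") as fh:
        for region in regions:
            if analysis:
                for j, ar in enumerate(region.analysis_regions):
                    fh.write(f"{region.chrom}\t{ar.start}\t{ar.end}\t{region.region_id}.{j}\n")
            else:
                fh.write(f"{region.chrom}\t{region.start}\t{region.end}\t{region.region_id}\n")
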