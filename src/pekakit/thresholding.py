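"""Partition crosslinks into thresholded (tXn), out-of-peak (oXn) and other sites.

tXn — in-peak sites whose cDNA count strictly exceeds the regional
threshold — are the high-occupancy foreground; oXn — all sites outside
peaks — are the intrinsic background of the experiment.  Thresholds are
regional: all exons of a gene form one region, each intron and each
contiguous intergenic stretch is its own region, and the threshold is the
smallest count c such that at least the configured fraction (default 70%)
of the region's sites have a count <= c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from pekakit.formats_io import (
    CrosslinkSite,
    GenomicInterval,
    RegionSegmentation,
    intergenic_gaps,
)

EXONIC_LABELS = frozenset({"CDS", "UTR5", "UTR3", "ncRNA"})


@dataclass
class ThresholdConfig:
    regional_percentile: float = 0.70
    cap_txn: int = 1_000_000
    cap_oxn: int = 3_000_000
    seed: int = 0
    subsample_enabled: bool = True

    def __post_init__(self):
        if not 0.0 <= self.regional_percentile <= 1.0:
            raise ValueError("regional_percentile must be in [0, 1]")
        if self.cap_txn <= 0 or self.cap_oxn <= 0:
            raise ValueError("subsampling caps must be positive")


@dataclass
class ThresholdRegion:
    """One thresholding unit: a gene's merged exons, an intron, or an intergenic stretch."""

    region_id: str
    intervals: list[GenomicInterval]


@dataclass
class PartitionResult:
    txn: list[CrosslinkSite] = field(default_factory=list)
    oxn: list[CrosslinkSite] = field(default_factory=list)
    other: list[CrosslinkSite] = field(default_factory=list)
    per_region_threshold: dict[str, int] = field(default_factory=dict)


def regional_threshold(counts: Sequence[int], percentile: float) -> int:
    """Smallest integer c >= 0 such that (#counts <= c) / len(counts) >= percentile.

    A percentile of 0 returns 0, so every in-peak crosslink qualifies as tXn.
    """
    if len(counts) == 0:
        raise ValueError("empty count multiset")
    if percentile <= 0:
        return 0
    values, freq = np.unique(np.asarray(counts, dtype=int), return_counts=True)
    cumfrac = np.cumsum(freq) / len(counts)
    idx = int(np.searchsorted(cumfrac, percentile, side="left"))
    # nearest rank: first value whose cumulative fraction reaches the percentile
    return int(values[min(idx, len(values) - 1)])


def build_threshold_regions(
    segmentation: RegionSegmentation,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[ThresholdRegion]:
    """Regions over which cDNA-count thresholds are computed.

    All exons (CDS, UTRs, ncRNA) of a gene merge into one region; each intron
    is its own region; each maximal intergenic stretch is its own region.
    """
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    regions: list[ThresholdRegion] = []
    for iv in segmentation.intervals:
        if iv.label in EXONIC_LABELS or iv.label == "genic_other":
            if iv.gene_id is None:
                raise ValueError(
                    f"genic interval {iv.chrom}:{iv.start}-{iv.end} ({iv.label}) has no gene_id"
                )
            exons_by_gene.setdefault(iv.gene_id, []).append(iv)
        elif iv.label == "intron":
            regions.append(
                ThresholdRegion(f"intron:{iv.chrom}:{iv.start}-{iv.end}:{iv.strand}", [iv])
            )
    for gene_id in sorted(exons_by_gene):
        regions.append(ThresholdRegion(f"exon:{gene_id}", exons_by_gene[gene_id]))
    for gap in intergenic_gaps(segmentation, chrom_lengths):
        regions.append(
            ThresholdRegion(f"intergenic:{gap.chrom}:{gap.start}-{gap.end}", [gap])
        )
    return regions


class RegionAssigner:
    """Point -> thresholding-region lookup.

    Exonic regions take precedence over introns over intergenic (matching the
    label precedence); a site covered by regions of two genes uses the first
    region in sorted order.
    """

    _PRIORITY = {"exon": 0, "intron": 1, "intergenic": 2}

    def __init__(self, regions: Iterable[ThresholdRegion]):
        self._trees: dict[str, IntervalTree] = {}
        for order, region in enumerate(sorted(regions, key=lambda r: r.region_id)):
            kind = region.region_id.split(":", 1)[0]
            prio = self._PRIORITY.get(kind, 3)
            for iv in region.intervals:
                self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, (prio, order, iv.strand, region.region_id)
                )

    def assign(self, site: CrosslinkSite) -> str | None:
        tree = self._trees.get(site.chrom)
        if tree is None:
            return None
        hits = [
            h.data
            for h in tree.at(site.pos)
            if h.data[2] in (".", site.strand)
        ]
        if not hits:
            return None
        return min(hits)[3]


def compute_regional_thresholds(
    sites: Sequence[CrosslinkSite],
    assigner: RegionAssigner,
    percentile: float,
) -> tuple[dict[str, int], dict[int, str]]:
    """Per-region thresholds plus the site-index -> region assignment used."""
    assignment: dict[int, str] = {}
    counts_by_region: dict[str, list[int]] = {}
    for i, site in enumerate(sites):
        region_id = assigner.assign(site)
        if region_id is None:
            region_id = f"unassigned:{site.chrom}"
        assignment[i] = region_id
        counts_by_region.setdefault(region_id, []).append(site.cdna_count)
    thresholds = {
        rid: regional_threshold(counts, percentile)
        for rid, counts in counts_by_region.items()
    }
    return thresholds, assignment


class PeakIndex:
    """Strand-aware point-in-peak queries (strandless peaks match both strands)."""

    def __init__(self, peaks: Iterable[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        for p in peaks:
            self._trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p.strand)

    def covers(self, site: CrosslinkSite) -> bool:
        tree = self._trees.get(site.chrom)
        if tree is None:
            return False
        return any(strand in (".", site.strand) for _, _, strand in tree.at(site.pos))


def partition_crosslinks(
    sites: Sequence[CrosslinkSite],
    peaks: Sequence[GenomicInterval],
    thresholds: Mapping[str, int],
    assignment: Mapping[int, str],
    config: ThresholdConfig | None = None,
) -> PartitionResult:
    """Split sites into tXn (in peak, count > regional threshold), oXn (out of
    peak) and other (in peak, at or below threshold).

    A site whose region has no computed threshold uses threshold 0.
    """
    del config  # partitioning itself is deterministic
    peak_index = PeakIndex(peaks)
    result = PartitionResult(per_region_threshold=dict(thresholds))
    for i, site in enumerate(sites):
        if not peak_index.covers(site):
            result.oxn.append(site)
            continue
        threshold = thresholds.get(assignment.get(i, ""), 0)
        if site.cdna_count > threshold:
            result.txn.append(site)
        else:
            result.other.append(site)
    return result


def subsample_partition(
    result: PartitionResult,
    config: ThresholdConfig,
    rng: np.random.Generator | None = None,
) -> PartitionResult:
    """Uniform subsample of tXn/oXn down to the configured caps (without
    replacement); sets at or below cap — and runs with subsampling off —
    pass through unchanged."""
    if not config.subsample_enabled:
        return result
    if rng is None:
        rng = np.random.default_rng(config.seed)

    def sample(sites: list[CrosslinkSite], cap: int) -> list[CrosslinkSite]:
        if len(sites) <= cap:
            return list(sites)
        idx = rng.choice(len(sites), size=cap, replace=False)
        idx.sort()
        return [sites[j] for j in idx]

    return PartitionResult(
        txn=sample(result.txn, config.cap_txn),
        oxn=sample(result.oxn, config.cap_oxn),
        other=list(result.other),
        per_region_threshold=dict(result.per_region_threshold),
    )
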