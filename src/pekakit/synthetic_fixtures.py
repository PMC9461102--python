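"""Self-contained synthetic datasets with planted motif structure.

Generates a random genome, a gene annotation (UTR5 - CDS/intron - UTR3
structure), peaks, and crosslink sites: "signal" crosslinks cluster inside
peaks, carry elevated cDNA counts and have a motif physically written into
the genome near the crosslink; "background" crosslinks sit outside peaks at
count 1.  Everything is seeded end to end so fixtures are byte-identical
under identical configuration.

What this emulates — and what it does not: the generator reproduces the
geometry of CLIP data (single-nucleotide sites, count skew, peak
clustering, regional structure) but not sequencing noise, crosslinking
sequence preferences or realistic transcriptome composition.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from pekakit.formats_io import (
    CrosslinkSite,
    Genome,
    GenomicInterval,
    RegionSegmentation,
    reverse_complement,
    write_crosslinks,
    write_segmentation,
)


@dataclass
class FixtureConfig:
    genome_length: int = 100_000
    gc_fraction: float = 0.5
    n_genes: int = 5
    exons_per_gene: int = 3
    #: (motif, (min, max) center offset relative to the crosslink, planting probability)
    planted_motifs: list[tuple[str, tuple[int, int], float]] = field(
        default_factory=lambda: [("UGUGU", (-2, 2), 1.0)]
    )
    n_signal_crosslinks: int = 500
    n_background_crosslinks: int = 5000
    signal_count_range: tuple[int, int] = (2, 10)  # uniform, inclusive
    background_count: int = 1
    sites_per_peak: int = 5
    peak_margin: int = 10
    softmask_fraction: float = 0.0
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        if self.genome_length < 2000 * max(1, self.n_genes):
            raise ValueError("genome too short to host the requested genes")
        for motif, _, prob in self.planted_motifs:
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"planting probability {prob} outside [0, 1]")
            if set(motif.upper().replace("T", "U")) - set("ACGU"):
                raise ValueError(f"invalid motif {motif!r}")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if not 0.0 <= self.softmask_fraction <= 1.0:
            raise ValueError("softmask_fraction must be in [0, 1]")


@dataclass
class FixtureSet:
    genome: Genome
    segmentation: RegionSegmentation
    crosslinks: list[CrosslinkSite]
    peaks: list[GenomicInterval]
    config: FixtureConfig
    paths: dict[str, Path] = field(default_factory=dict)


def generate_genome(config: FixtureConfig, rng: np.random.Generator) -> list[str]:
    """Random sequence at the requested GC fraction, as a mutable char list;
    a softmask_fraction of positions is lowercased in contiguous blocks."""
    p_gc = config.gc_fraction / 2
    p_at = (1 - config.gc_fraction) / 2
    bases = rng.choice(list("ACGT"), size=config.genome_length, p=[p_at, p_gc, p_gc, p_at])
    seq = list(map(str, bases))
    masked = 0
    target = int(config.softmask_fraction * config.genome_length)
    while masked < target:
        block = int(rng.integers(50, 500))
        start = int(rng.integers(0, config.genome_length - block))
        for i in range(start, start + block):
            seq[i] = seq[i].lower()
        masked += block
    return seq


def generate_annotation(config: FixtureConfig, rng: np.random.Generator) -> RegionSegmentation:
    """Non-overlapping genes with UTR5 - [CDS exon / intron]* - UTR3 structure,
    evenly spaced along the chromosome, alternating strands."""
    utr5_len, cds_len, intron_len, utr3_len = 150, 300, 500, 300
    n_introns = max(config.exons_per_gene - 1, 0)
    gene_len = utr5_len + config.exons_per_gene * cds_len + n_introns * intron_len + utr3_len
    slot = config.genome_length // (config.n_genes + 1)
    if gene_len > slot - 400:
        raise ValueError("genes do not fit: reduce exons_per_gene or n_genes")
    intervals: list[GenomicInterval] = []
    for g in range(config.n_genes):
        anchor = slot * (g + 1) - gene_len // 2
        strand = "+" if g % 2 == 0 else "-"
        gene_id = f"gene{g + 1}"
        parts = [("UTR5", utr5_len)]
        for e in range(config.exons_per_gene):
            parts.append(("CDS", cds_len))
            if e < n_introns:
                parts.append(("intron", intron_len))
        parts.append(("UTR3", utr3_len))
        if strand == "-":
            parts = parts[::-1]
        pos = anchor
        for label, length in parts:
            intervals.append(
                GenomicInterval(config.chrom, pos, pos + length, strand, label, gene_id)
            )
            pos += length
    return RegionSegmentation(intervals)


def _write_motif(
    seq: list[str], site_pos: int, strand: str, motif_dna: str, center_offset: int
) -> None:
    """Overwrite the genome so the extracted window shows the motif centered
    at ``center_offset`` (window coordinates, 5'->3' of the site's strand)."""
    k = len(motif_dna)
    c = (k - 1) // 2
    if strand == "+":
        start = site_pos + center_offset - c
        for i, ch in enumerate(motif_dna):
            seq[start + i] = ch
    else:
        rc = reverse_complement(motif_dna)
        start = site_pos - center_offset - (k - 1 - c)
        for i, ch in enumerate(rc):
            seq[start + i] = ch


def plant_crosslinks(
    config: FixtureConfig,
    seq: list[str],
    segmentation: RegionSegmentation,
    rng: np.random.Generator,
) -> tuple[list[CrosslinkSite], list[GenomicInterval]]:
    """Signal crosslinks clustered under peaks with planted motifs and elevated
    counts; background crosslinks uniform outside peaks at count 1."""
    genic = [iv for iv in segmentation.intervals if iv.label != "intergenic"]
    margin = 200
    lo, hi = config.signal_count_range

    # keep signal sites far enough apart that planted motifs cannot overwrite
    # one another (k-mer width plus the offset span, with slack)
    min_spacing = max(
        len(m) + (hi_off - lo_off) for m, (lo_off, hi_off), _ in config.planted_motifs
    ) + 2

    sites: list[CrosslinkSite] = []
    peaks: list[GenomicInterval] = []
    used: set[int] = set()
    signal_positions: set[int] = set()
    placed = 0
    attempts = 0
    span = config.sites_per_peak * (min_spacing + 4)
    while placed < config.n_signal_crosslinks:
        attempts += 1
        if attempts > 200 * config.n_signal_crosslinks:
            raise ValueError(
                "could not place the requested signal crosslinks; "
                "genome or genes too small for n_signal_crosslinks"
            )
        iv = genic[int(rng.integers(0, len(genic)))]
        if iv.end - iv.start <= span:
            center = (iv.start + iv.end) // 2
        else:
            center = int(rng.integers(iv.start + span // 2, iv.end - span // 2))
        if center - margin < 0 or center + margin >= config.genome_length:
            continue
        n_here = min(config.sites_per_peak, config.n_signal_crosslinks - placed)
        cluster = []
        for _ in range(n_here):
            pos = center + int(rng.integers(-span // 2, span // 2 + 1))
            pos = int(np.clip(pos, margin, config.genome_length - margin - 1))
            if pos in used or any(
                abs(pos - q) < min_spacing for q in signal_positions
            ):
                continue
            used.add(pos)
            signal_positions.add(pos)
            count = int(rng.integers(lo, hi + 1))
            site = CrosslinkSite(config.chrom, pos, iv.strand, count)
            cluster.append(site)
            for motif, (off_lo, off_hi), prob in config.planted_motifs:
                # common random numbers: draw unconditionally so fixtures that
                # differ only in planting probability share all other structure
                # (planted sets are then nested across a probability sweep)
                u = rng.random()
                offset = int(rng.integers(off_lo, off_hi + 1))
                if u < prob:
                    _write_motif(seq, pos, iv.strand, motif.upper().replace("U", "T"), offset)
        if not cluster:
            continue
        sites.extend(cluster)
        placed += len(cluster)
        start = min(s.pos for s in cluster) - config.peak_margin
        end = max(s.pos for s in cluster) + config.peak_margin + 1
        peaks.append(GenomicInterval(config.chrom, start, end, iv.strand, f"peak{len(peaks) + 1}"))

    peak_mask = np.zeros(config.genome_length, dtype=bool)
    for p in peaks:
        peak_mask[max(p.start, 0) : min(p.end, config.genome_length)] = True
    n_bg = 0
    while n_bg < config.n_background_crosslinks:
        pos = int(rng.integers(margin, config.genome_length - margin))
        if peak_mask[pos] or pos in used:
            continue
        used.add(pos)
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append(CrosslinkSite(config.chrom, pos, strand, config.background_count))
        n_bg += 1
    sites.sort(key=lambda s: (s.chrom, s.pos, s.strand))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return sites, peaks


def generate_fixture(config: FixtureConfig | None = None, outdir: str | os.PathLike | None = None) -> FixtureSet:
    """Build the full fixture; optionally write FASTA(+fai), GTF, BEDs and a
    JSON sidecar recording the configuration."""
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    seq = generate_genome(config, rng)
    segmentation = generate_annotation(config, rng)
    sites, peaks = plant_crosslinks(config, seq, segmentation, rng)
    genome = Genome({config.chrom: "".join(seq)})
    fixture = FixtureSet(genome, segmentation, sites, peaks, config)
    if outdir is not None:
        fixture.paths = write_fixture(fixture, outdir)
    return fixture


def write_fixture(fixture: FixtureSet, outdir: str | os.PathLike) -> dict[str, Path]:
    from pyfaidx import Faidx

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = fixture.config
    paths = {
        "genome": outdir / "genome.fa",
        "segmentation": outdir / "segmentation.gtf",
        "crosslinks": outdir / "crosslinks.bed",
        "peaks": outdir / "peaks.bed",
        "sidecar": outdir / "fixture.json",
    }
    with open(paths["genome"], "w") as fh:
        seq = fixture.genome.fetch(cfg.chrom, 0, cfg.genome_length)
        fh.write(f">{cfg.chrom}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    Faidx(str(paths["genome"])).close()  # building the index is a side effect of opening
    write_segmentation(fixture.segmentation, paths["segmentation"])
    write_crosslinks(fixture.crosslinks, paths["crosslinks"])
    with open(paths["peaks"], "w") as fh:
        for p in fixture.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.label}\t0\t{p.strand}\n")
    with open(paths["sidecar"], "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, default=list)
        fh.write("\n")
    return paths
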