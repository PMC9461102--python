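"""Readers/writers for the genomic formats the toolkit touches.

Conventions
-----------
* BED is 0-based half-open; every crosslink record covers exactly one
  nucleotide (``end == start + 1``) and its score column is the cDNA count.
* GTF is 1-based inclusive and converted to 0-based half-open on read.
* The genome is read as DNA with case preserved (lowercase = repeat-masked);
  k-mers are reported in the RNA alphabet (T shown as U).
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

REGION_LABELS = ("intron", "CDS", "UTR5", "UTR3", "ncRNA", "intergenic", "genic_other")

#: overlap resolution: first label wins.  The source annotation does not
#: prescribe an order, so a fixed one keeps assignment deterministic.
REGION_PRECEDENCE = ("ncRNA", "UTR3", "UTR5", "CDS", "intron", "genic_other", "intergenic")

#: accepted synonyms in the GTF feature column
_LABEL_SYNONYMS = {
    "intron": "intron",
    "cds": "CDS",
    "utr5": "UTR5",
    "five_prime_utr": "UTR5",
    "5utr": "UTR5",
    "utr3": "UTR3",
    "three_prime_utr": "UTR3",
    "3utr": "UTR3",
    "ncrna": "ncRNA",
    "intergenic": "intergenic",
    "genic_other": "genic_other",
}

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class CrosslinkSite:
    """One crosslinked nucleotide: the unit of all positional analysis."""

    chrom: str
    pos: int  # 0-based genomic coordinate
    strand: str  # "+" or "-"
    cdna_count: int

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.cdna_count < 1:
            raise ValueError(f"cdna_count must be >= 1, got {self.cdna_count}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open, optionally stranded interval (peak or segmentation record)."""

    chrom: str
    start: int
    end: int
    strand: str = "."  # "." = both strands
    label: str = ""
    gene_id: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError(f"start >= end for {self.chrom}:{self.start}-{self.end}")

    def contains(self, chrom: str, pos: int, strand: str) -> bool:
        return (
            chrom == self.chrom
            and self.start <= pos < self.end
            and (self.strand == "." or self.strand == strand)
        )


class Genome:
    """Chromosome sequences with case preserved (lowercase = repeat-masked)."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = dict(sequences)
        self.lengths = {c: len(s) for c, s in self._seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Genome":
        from pyfaidx import Fasta

        with Fasta(str(path), as_raw=True, sequence_always_upper=False) as fa:
            return cls({name: str(fa[name][:]) for name in fa.keys()})

    def fetch(self, chrom: str, start: int, end: int) -> str | None:
        """Sequence of [start, end), or None when out of bounds."""
        seq = self._seqs.get(chrom)
        if seq is None or start < 0 or end > len(seq):
            return None
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RegionSegmentation:
    """Strand-aware region-labelled intervals with precedence-resolved lookup.

    A position covered by no interval is ``intergenic``.  Overlaps resolve by
    :data:`REGION_PRECEDENCE`; within the same label the first interval in
    sorted order wins (relevant for gene assignment only).
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    precedence: tuple[str, ...] = REGION_PRECEDENCE

    def __post_init__(self):
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._rank = {lab: i for i, lab in enumerate(self.precedence)}

    def overlapping(self, chrom: str, pos: int, strand: str) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.at(pos)]
        hits = [iv for iv in hits if iv.strand in (".", strand)]
        hits.sort(key=lambda iv: (self._rank.get(iv.label, 99), iv.start, iv.end))
        return hits

    def lookup(self, chrom: str, pos: int, strand: str) -> str:
        hits = self.overlapping(chrom, pos, strand)
        return hits[0].label if hits else "intergenic"

    def lookup_interval(self, chrom: str, pos: int, strand: str) -> GenomicInterval | None:
        hits = self.overlapping(chrom, pos, strand)
        return hits[0] if hits else None


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise FormatError(f"line {lineno}: cannot parse {what} {text!r}") from None


def read_crosslinks(path: str | os.PathLike) -> list[CrosslinkSite]:
    """Read single-nucleotide crosslink sites from BED6.

    Records sharing (chrom, pos, strand) have their cDNA counts summed
    (replicate merging).  Each record must span exactly one nucleotide.
    """
    merged: dict[tuple[str, int, str], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"line {lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start_s, end_s, _name, score_s, strand = fields[:6]
            start = _parse_int(start_s, "start", lineno)
            end = _parse_int(end_s, "end", lineno)
            if end != start + 1:
                raise FormatError(f"line {lineno}: crosslink record spans {end - start} nt, expected 1")
            count = _parse_int(score_s, "score", lineno)
            if count < 1:
                raise FormatError(f"line {lineno}: score (cDNA count) must be positive, got {count}")
            if strand not in ("+", "-"):
                raise FormatError(f"line {lineno}: bad strand {strand!r}")
            key = (chrom, start, strand)
            merged[key] = merged.get(key, 0) + count
    return [
        CrosslinkSite(chrom, pos, strand, count)
        for (chrom, pos, strand), count in sorted(merged.items())
    ]


def write_crosslinks(sites: Iterable[CrosslinkSite], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos, s.strand)):
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t.\t{s.cdna_count}\t{s.strand}\n")


def read_peaks(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read peak intervals from BED3/BED6; missing strand means both strands."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            start = _parse_int(fields[1], "start", lineno)
            end = _parse_int(fields[2], "end", lineno)
            if start >= end:
                raise FormatError(f"line {lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            peaks.append(GenomicInterval(chrom, start, end, strand, label=name))
    return peaks


def _gtf_attribute(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key):
            value = part[len(key):].strip().strip('"')
            if value:
                return value
    return None


def read_segmentation(path: str | os.PathLike) -> RegionSegmentation:
    """Read a region segmentation GTF.

    The feature column (or a ``region`` attribute) names one of the supported
    region labels; ``gene_id`` is carried along for regional thresholding.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"line {lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            raw_label = _gtf_attribute(attrs, "region") or feature
            label = _LABEL_SYNONYMS.get(raw_label.lower())
            if label is None:
                raise FormatError(f"line {lineno}: unknown region label {raw_label!r}")
            start = _parse_int(start_s, "start", lineno) - 1  # GTF is 1-based inclusive
            end = _parse_int(end_s, "end", lineno)
            if strand not in ("+", "-", "."):
                raise FormatError(f"line {lineno}: bad strand {strand!r}")
            gene_id = _gtf_attribute(attrs, "gene_id")
            intervals.append(GenomicInterval(chrom, start, end, strand, label, gene_id))
    return RegionSegmentation(intervals)


def write_segmentation(seg: RegionSegmentation, path: str | os.PathLike, source: str = "pekakit") -> None:
    with open(path, "w") as fh:
        for iv in sorted(seg.intervals, key=lambda i: (i.chrom, i.start, i.end)):
            attrs = f'gene_id "{iv.gene_id}";' if iv.gene_id else ""
            fh.write(
                f"{iv.chrom}\t{source}\t{iv.label}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )


def extract_window(
    genome: Genome, site: CrosslinkSite, upstream: int, downstream: int
) -> str | None:
    """Sequence around a crosslink in 5'->3' orientation of the site's strand.

    Returns ``upstream + 1 + downstream`` characters with the crosslinked
    nucleotide in the middle, reverse-complemented for "-" strand sites;
    ``None`` when the window leaves the chromosome (caller drops the site).
    """
    if site.strand == "+":
        seq = genome.fetch(site.chrom, site.pos - upstream, site.pos + downstream + 1)
        return seq
    seq = genome.fetch(site.chrom, site.pos - downstream, site.pos + upstream + 1)
    return None if seq is None else reverse_complement(seq)


KMER_TABLE_COLUMNS = (
    "kmer",
    "peka_score",
    "p_value",
    "rank",
    "n_relevant_positions",
    "artxn",
    "mean_aroxn",
    "std_aroxn",
    "max_rtxn_position",
)


def write_kmer_table(results: Sequence, path: str | os.PathLike) -> None:
    """Write ranked per-k-mer enrichment results as TSV (row order: rank, ties alphabetical)."""
    rows = sorted(results, key=lambda r: (r.rank, r.kmer))
    df = pd.DataFrame(
        {
            "kmer": [r.kmer for r in rows],
            "peka_score": [r.peka_score for r in rows],
            "p_value": [r.p_value for r in rows],
            "rank": [r.rank for r in rows],
            "n_relevant_positions": [len(r.relevant_positions) for r in rows],
            "artxn": [r.artxn for r in rows],
            "mean_aroxn": [r.mean_aroxn for r in rows],
            "std_aroxn": [r.std_aroxn for r in rows],
            "max_rtxn_position": [r.max_rtxn_position for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_kmer_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def intergenic_gaps(
    seg: RegionSegmentation, chrom_lengths: Mapping[str, int] | None = None
) -> list[GenomicInterval]:
    """Maximal genomic stretches covered by no genic interval, per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in seg.intervals:
        if iv.label != "intergenic":
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    chroms = set(by_chrom)
    if chrom_lengths:
        chroms |= set(chrom_lengths)
    gaps = []
    for chrom in sorted(chroms):
        length = (chrom_lengths or {}).get(chrom)
        spans = sorted(by_chrom.get(chrom, []))
        cursor = 0
        for start, end in spans:
            if start > cursor:
                gaps.append(GenomicInterval(chrom, cursor, start, ".", "intergenic"))
            cursor = max(cursor, end)
        tail_end = length if length is not None else cursor + 10**9
        if tail_end > cursor:
            gaps.append(GenomicInterval(chrom, cursor, tail_end, ".", "intergenic"))
    return gaps


def find_gap(gaps_for_chrom: list[GenomicInterval], pos: int) -> GenomicInterval | None:
    starts = [g.start for g in gaps_for_chrom]
    i = bisect_right(starts, pos) - 1
    if i >= 0 and gaps_for_chrom[i].start <= pos < gaps_for_chrom[i].end:
        return gaps_for_chrom[i]
    return None
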