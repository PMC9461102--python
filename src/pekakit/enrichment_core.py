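"""Positional k-mer enrichment around crosslink sites.

The method, in brief: foreground sequences (+/- the maximal distal offset,
default 150 nt) are extracted around thresholded crosslinks (tXn) and
background sequences (+/- the proximal half-width w, default 20 nt) around
out-of-peak crosslinks (oXn).  For every k-mer, per-position occurrence is
the fraction of sequences carrying it centered at that offset; dividing by
the k-mer's mean occurrence across the distal windows of the foreground
gives relative occurrence (RtXn for foreground; RoXn for each of 100
size-matched random background samples).  Per-position thresholds are taken
from the pooled RoXn values of all k-mers; the proximal offsets where RtXn
exceeds the threshold are that k-mer's "relevant positions".  The PEKA
score is (ARtXn - mean(ARoXn)) / std(ARoXn), the mean relative occurrence
over relevant positions expressed in background standard deviations, and
p-values come from the upper normal tail of z-scored PEKA scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import ndtr

from pekakit.formats_io import (
    CrosslinkSite,
    Genome,
    GenomicInterval,
    RegionSegmentation,
    extract_window,
)
from pekakit.thresholding import (
    RegionAssigner,
    ThresholdConfig,
    build_threshold_regions,
    compute_regional_thresholds,
    partition_crosslinks,
    subsample_partition,
)

REPEAT_MODES = ("exclude-repeats", "with-repeats", "repeats-only")

#: analysis regions -> segmentation labels (None = keep every site)
ANALYSIS_REGIONS: dict[str, frozenset[str] | None] = {
    "genome": None,
    "whole-genome": None,
    "protein-coding-gene": frozenset({"intron", "CDS", "UTR5", "UTR3"}),
    "intron": frozenset({"intron"}),
    "UTR3": frozenset({"UTR3"}),
    "utr3": frozenset({"UTR3"}),
    "other-exon": frozenset({"CDS", "UTR5"}),
    "ncRNA": frozenset({"ncRNA"}),
    "ncrna": frozenset({"ncRNA"}),
    "intergenic": frozenset({"intergenic"}),
}

_CODES = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i
_CODES[ord("U")] = 3
_CODES[ord("u")] = 3
_IS_LOWER = np.zeros(256, dtype=bool)
for _b in "acgtun":
    _IS_LOWER[ord(_b)] = True

_RNA = "ACGU"


class InsufficientDataError(RuntimeError):
    """Raised when a region yields zero foreground or background sites."""


def all_kmers(k: int) -> list[str]:
    """All 4**k k-mers in the RNA alphabet, lexicographic (A<C<G<U)."""
    return ["".join(p) for p in itertools.product(_RNA, repeat=k)]


def center_offset_in_kmer(k: int) -> int:
    """Index of the nucleotide that receives the count: the middle base for
    odd k, the (k/2)-th overlapping base for even k (e.g. 3rd for a 6-mer)."""
    return (k - 1) // 2


@dataclass
class EnrichmentConfig:
    k: int = 5
    proximal_half_width: int = 20
    distal_span: tuple[tuple[int, int], tuple[int, int]] = ((-150, -100), (100, 150))
    n_background_samples: int = 100
    position_percentile: float | str = "auto"
    relevant_position_mode: str = "thresholded"  # or "all-proximal"
    repeat_mode: str = "exclude-repeats"
    seed: int = 0

    #: fallback used when the automatic percentile is requested; the original
    #: derives it from k and the foreground size by an unpublished rule, so
    #: "auto" resolves to this fixed, logged value.
    AUTO_PERCENTILE = 0.7

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.repeat_mode not in REPEAT_MODES:
            raise ValueError(f"repeat_mode must be one of {REPEAT_MODES}")
        if self.relevant_position_mode not in ("thresholded", "all-proximal"):
            raise ValueError("relevant_position_mode must be 'thresholded' or 'all-proximal'")
        if self.n_background_samples < 1:
            raise ValueError("n_background_samples must be >= 1")
        lo = min(min(abs(a), abs(b)) for a, b in self.distal_span)
        if self.proximal_half_width > lo:
            raise ValueError("proximal window overlaps the distal span")
        if self.k > 2 * self.proximal_half_width + 1:
            raise ValueError("k exceeds the proximal window width")
        if self.position_percentile != "auto" and not 0 <= float(self.position_percentile) <= 1:
            raise ValueError("position_percentile must be in [0, 1] or 'auto'")

    @property
    def max_offset(self) -> int:
        return max(max(abs(a), abs(b)) for a, b in self.distal_span)

    @property
    def resolved_percentile(self) -> float:
        if self.position_percentile == "auto":
            return self.AUTO_PERCENTILE
        return float(self.position_percentile)


@dataclass
class OccurrenceMatrix:
    """k-mer x position grid of occurrence fractions (count / n_sequences)."""

    values: np.ndarray  # (4**k, n_positions)
    positions: np.ndarray  # offsets relative to the crosslink
    n_sequences: int
    k: int


@dataclass
class RelativeOccurrence:
    """Occurrence normalized by the per-k-mer mean over the foreground distal window."""

    values: np.ndarray  # (4**k, n_positions)
    positions: np.ndarray
    distal_mean: np.ndarray  # (4**k,)


@dataclass
class PekaResult:
    kmer: str
    peka_score: float
    rank: int
    p_value: float
    relevant_positions: tuple[int, ...]
    artxn: float
    mean_aroxn: float
    std_aroxn: float
    max_rtxn_position: int


@dataclass
class PekaRunResult:
    region: str
    results: list[PekaResult]
    rtxn: RelativeOccurrence
    proximal_positions: np.ndarray
    resolved_percentile: float
    n_txn: int
    n_oxn: int
    per_region_threshold: dict[str, int]
    config: EnrichmentConfig
    txn: list[CrosslinkSite] = field(default_factory=list)
    oxn: list[CrosslinkSite] = field(default_factory=list)


def kmer_id_matrix(
    sequences: Sequence[str], k: int, repeat_mode: str = "exclude-repeats"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sequence, per-center-offset k-mer identities.

    Returns ``(ids, positions)`` where ``ids[i, j]`` is the lexicographic id
    of the k-mer whose counted (center) nucleotide sits at offset
    ``positions[j]`` in sequence ``i``, or -1 for an invalid window (crossing
    an N, or failing the repeat-mask rule).  Offsets are relative to the
    middle nucleotide of the (odd-length) sequences.
    """
    if not sequences:
        raise ValueError("no sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    L = lengths.pop()
    if L % 2 != 1:
        raise ValueError("sequences must have odd length (centered on the crosslink)")
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    arr = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8).reshape(
        len(sequences), L
    )
    codes = _CODES[arr]
    lower = _IS_LOWER[arr]
    wins = sliding_window_view(codes, k, axis=1)  # (n, L-k+1, k)
    valid = (wins >= 0).all(axis=-1)
    lw = sliding_window_view(lower, k, axis=1)
    if repeat_mode == "exclude-repeats":
        valid &= ~lw.any(axis=-1)
    elif repeat_mode == "repeats-only":
        valid &= lw.all(axis=-1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    ids = (wins.astype(np.int64) * powers).sum(axis=-1)
    ids[~valid] = -1
    mid = L // 2
    c = center_offset_in_kmer(k)
    positions = np.arange(0, L - k + 1) + c - mid
    return ids, positions


def occurrence_from_ids(ids: np.ndarray, k: int) -> np.ndarray:
    """Occurrence fractions (4**k x n_positions) from a k-mer id matrix."""
    n_kmers = 4**k
    n_seq, n_pos = ids.shape
    values = np.empty((n_kmers, n_pos), dtype=float)
    for j in range(n_pos):
        col = ids[:, j]
        values[:, j] = np.bincount(col[col >= 0], minlength=n_kmers) / n_seq
    return values


def scan_kmers(
    sequences: Sequence[str], k: int, repeat_mode: str = "exclude-repeats"
) -> OccurrenceMatrix:
    """Per-position k-mer occurrence across equal-length, crosslink-centered
    sequences.  A sequence contributes 1 to (k-mer, p) when the k-mer occurs
    with its counted nucleotide at offset p; windows containing N are
    skipped, as are windows failing the repeat-mask rule of ``repeat_mode``."""
    ids, positions = kmer_id_matrix(sequences, k, repeat_mode)
    return OccurrenceMatrix(occurrence_from_ids(ids, k), positions, len(sequences), k)


def restrict(occ: OccurrenceMatrix, positions: Sequence[int]) -> OccurrenceMatrix:
    """Sub-matrix at the requested offsets (all must be present)."""
    wanted = np.asarray(positions)
    idx = np.searchsorted(occ.positions, wanted)
    if not np.array_equal(occ.positions[idx], wanted):
        raise ValueError("requested positions not present in matrix")
    return OccurrenceMatrix(occ.values[:, idx], wanted.copy(), occ.n_sequences, occ.k)


def distal_positions(
    positions: np.ndarray, distal_span: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Offsets of the matrix that fall inside the distal span(s)."""
    mask = np.zeros(len(positions), dtype=bool)
    for lo, hi in distal_span:
        mask |= (positions >= lo) & (positions <= hi)
    return positions[mask]


def relative_occurrence(
    occ: OccurrenceMatrix, distal_occ: OccurrenceMatrix
) -> RelativeOccurrence:
    """Occurrence normalized by the per-k-mer distal mean of the foreground.

    A zero distal mean is floored at ``1 / (n_sequences * n_distal_positions)``
    (the smallest occurrence observable once), so rare k-mers keep finite,
    conservative relative occurrences.
    """
    n_distal = distal_occ.values.shape[1]
    if n_distal == 0:
        raise ValueError("distal occurrence matrix has no positions")
    floor = 1.0 / (occ.n_sequences * n_distal)
    distal_mean = distal_occ.values.mean(axis=1)
    distal_mean[distal_mean == 0] = floor
    return RelativeOccurrence(occ.values / distal_mean[:, None], occ.positions.copy(), distal_mean)


def draw_sample_indices(
    rng: np.random.Generator, n_background: int, n_samples: int, sample_size: int
) -> np.ndarray:
    """Index draws for the background samples: without replacement when the
    background is large enough, with replacement otherwise."""
    if n_background == 0:
        raise ValueError("empty background")
    without = n_background >= sample_size
    return np.stack(
        [
            rng.choice(n_background, size=sample_size, replace=not without)
            for _ in range(n_samples)
        ]
    )


def sample_background(
    bg_ids: np.ndarray,
    k: int,
    distal_mean: np.ndarray,
    indices: np.ndarray,
) -> np.ndarray:
    """RoXn for each background sample: (n_samples, 4**k, n_positions).

    ``bg_ids`` is the k-mer id matrix of the background sequences; each
    sample's occurrences are normalized by the foreground distal mean
    (background windows carry no distal window of their own).
    """
    n_kmers = 4**k
    n_samples, sample_size = indices.shape
    n_pos = bg_ids.shape[1]
    out = np.empty((n_samples, n_kmers, n_pos), dtype=float)
    for s in range(n_samples):
        sub = bg_ids[indices[s]]
        for j in range(n_pos):
            col = sub[:, j]
            out[s, :, j] = np.bincount(col[col >= 0], minlength=n_kmers) / sample_size
    out /= distal_mean[None, :, None]
    return out


def nearest_rank(sorted_values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile of a pre-sorted array (q=0 -> min, q=1 -> max)."""
    n = len(sorted_values)
    if q <= 0:
        return float(sorted_values[0])
    idx = int(np.ceil(q * n)) - 1
    return float(sorted_values[min(max(idx, 0), n - 1)])


def position_thresholds(bg_samples: np.ndarray, percentile: float) -> np.ndarray:
    """Per-position threshold: the nearest-rank percentile of the pooled RoXn
    values of all k-mers across all background samples at that position."""
    n_samples, n_kmers, n_pos = bg_samples.shape
    out = np.empty(n_pos, dtype=float)
    for j in range(n_pos):
        pool = np.sort(bg_samples[:, :, j].ravel())
        out[j] = nearest_rank(pool, percentile)
    return out


def relevant_positions(
    rtxn_proximal: np.ndarray,
    thresholds: np.ndarray,
    mode: str = "thresholded",
) -> list[np.ndarray]:
    """Per-k-mer indices (into the proximal positions) where RtXn exceeds the
    position threshold; k-mers passing nowhere fall back to all proximal
    positions, as does every k-mer in "all-proximal" mode."""
    n_kmers, n_pos = rtxn_proximal.shape
    everything = np.arange(n_pos)
    if mode == "all-proximal":
        return [everything] * n_kmers
    out = []
    for m in range(n_kmers):
        idx = np.nonzero(rtxn_proximal[m] > thresholds)[0]
        out.append(idx if len(idx) else everything)
    return out


#: last-resort floor on the background standard deviation; with a zero
#: numerator this yields score 0 for flat cases rather than NaN
STD_FLOOR = 1e-12


def peka_score(
    rtxn_proximal: np.ndarray,
    bg_samples: np.ndarray,
    relevant: Sequence[np.ndarray],
    distal_mean: np.ndarray | None = None,
    sample_size: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(scores, ARtXn, mean(ARoXn), std(ARoXn)) per k-mer.

    ARtXn is the mean RtXn over the k-mer's relevant positions; each
    background sample contributes one ARoXn over the same positions; the
    score is their separation in population standard deviations.

    The denominator is floored at the sampling granularity of ARoXn — the
    increment one background count makes, ``1 / (sample_size * distal_mean
    * n_relevant)`` — when ``distal_mean`` and ``sample_size`` are given
    (rare k-mers whose background never occurs at the relevant positions
    would otherwise divide by ~0 and dominate the ranking), and at
    :data:`STD_FLOOR` otherwise.
    """
    n_kmers = rtxn_proximal.shape[0]
    artxn = np.empty(n_kmers)
    mean_aroxn = np.empty(n_kmers)
    std_aroxn = np.empty(n_kmers)
    floors = np.full(n_kmers, STD_FLOOR)
    for m in range(n_kmers):
        rel = relevant[m]
        artxn[m] = rtxn_proximal[m, rel].mean()
        per_sample = bg_samples[:, m, rel].mean(axis=1)
        mean_aroxn[m] = per_sample.mean()
        std_aroxn[m] = per_sample.std()  # population std over the samples
        if distal_mean is not None and sample_size is not None:
            floors[m] = max(1.0 / (sample_size * distal_mean[m] * len(rel)), STD_FLOOR)
    scores = (artxn - mean_aroxn) / np.maximum(std_aroxn, floors)
    return scores, artxn, mean_aroxn, std_aroxn


def score_pvalues(scores: np.ndarray) -> np.ndarray:
    """Upper-tail normal p-values of z-scored PEKA scores."""
    std = scores.std()
    if std == 0:
        raise ValueError("degenerate score distribution: all PEKA scores identical")
    z = (scores - scores.mean()) / std
    return ndtr(-z)


def _display_kmer(kmer: str) -> str:
    return kmer.replace("T", "U")


def rank_kmers(scores: np.ndarray, kmers: Sequence[str]) -> np.ndarray:
    """1-based ranks, best score first, ties broken alphabetically."""
    order = sorted(range(len(scores)), key=lambda m: (-scores[m], kmers[m]))
    ranks = np.empty(len(scores), dtype=int)
    for r, m in enumerate(order, 1):
        ranks[m] = r
    return ranks


def enrichment_from_sequences(
    fg_sequences: Sequence[str],
    bg_sequences: Sequence[str],
    config: EnrichmentConfig,
    rng: np.random.Generator | None = None,
    sample_indices: np.ndarray | None = None,
) -> dict:
    """Core computation given already-extracted foreground/background windows.

    Foreground windows span +/- the maximal distal offset; background windows
    span +/- the proximal half-width.  Returns the intermediate matrices and
    the ranked per-k-mer statistics.
    """
    if not fg_sequences:
        raise InsufficientDataError("no foreground sequences")
    if not bg_sequences:
        raise InsufficientDataError("no background sequences")
    k = config.k
    occ = scan_kmers(fg_sequences, k, config.repeat_mode)
    dist = restrict(occ, distal_positions(occ.positions, config.distal_span))
    rtxn = relative_occurrence(occ, dist)

    bg_ids, bg_positions = kmer_id_matrix(bg_sequences, k, config.repeat_mode)
    if sample_indices is None:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        sample_indices = draw_sample_indices(
            rng, len(bg_sequences), config.n_background_samples, len(fg_sequences)
        )
    bg_samples = sample_background(bg_ids, k, rtxn.distal_mean, sample_indices)

    # score over the offsets where both foreground and background windows exist
    prox_idx = np.searchsorted(rtxn.positions, bg_positions)
    rtxn_prox = rtxn.values[:, prox_idx]

    percentile = config.resolved_percentile
    thresholds = position_thresholds(bg_samples, percentile)
    relevant = relevant_positions(rtxn_prox, thresholds, config.relevant_position_mode)
    scores, artxn, mean_aroxn, std_aroxn = peka_score(
        rtxn_prox, bg_samples, relevant,
        distal_mean=rtxn.distal_mean, sample_size=sample_indices.shape[1],
    )
    pvalues = score_pvalues(scores)
    kmers = all_kmers(k)
    ranks = rank_kmers(scores, kmers)
    return {
        "kmers": kmers,
        "occ": occ,
        "rtxn": rtxn,
        "bg_samples": bg_samples,
        "proximal_positions": bg_positions,
        "rtxn_proximal": rtxn_prox,
        "thresholds": thresholds,
        "relevant": relevant,
        "scores": scores,
        "artxn": artxn,
        "mean_aroxn": mean_aroxn,
        "std_aroxn": std_aroxn,
        "pvalues": pvalues,
        "ranks": ranks,
        "resolved_percentile": percentile,
    }


def _results_from_core(core: dict) -> list[PekaResult]:
    positions = core["proximal_positions"]
    results = []
    for m, kmer in enumerate(core["kmers"]):
        prox = core["rtxn_proximal"][m]
        max_pos = int(positions[int(np.argmax(prox))])
        results.append(
            PekaResult(
                kmer=_display_kmer(kmer),
                peka_score=float(core["scores"][m]),
                rank=int(core["ranks"][m]),
                p_value=float(core["pvalues"][m]),
                relevant_positions=tuple(int(positions[i]) for i in core["relevant"][m]),
                artxn=float(core["artxn"][m]),
                mean_aroxn=float(core["mean_aroxn"][m]),
                std_aroxn=float(core["std_aroxn"][m]),
                max_rtxn_position=max_pos,
            )
        )
    results.sort(key=lambda r: (r.rank, r.kmer))
    return results


def run_peka(
    crosslinks: Sequence[CrosslinkSite],
    peaks: Sequence[GenomicInterval],
    genome: Genome,
    segmentation: RegionSegmentation,
    region: str = "genome",
    config: EnrichmentConfig | None = None,
    threshold_config: ThresholdConfig | None = None,
) -> PekaRunResult:
    """Full enrichment analysis in one transcriptomic region.

    Filters crosslinks to the region, applies regional thresholding and
    subsampling, extracts strand-aware windows (sites whose window crosses a
    chromosome boundary are dropped), and computes ranked PEKA scores with
    p-values for all 4**k k-mers.
    """
    config = config or EnrichmentConfig()
    threshold_config = threshold_config or ThresholdConfig(seed=config.seed)
    if region not in ANALYSIS_REGIONS:
        raise ValueError(f"unknown analysis region {region!r}; choose from {sorted(ANALYSIS_REGIONS)}")
    labels = ANALYSIS_REGIONS[region]

    sites = sorted(crosslinks, key=lambda s: (s.chrom, s.pos, s.strand))
    if labels is not None:
        sites = [s for s in sites if segmentation.lookup(s.chrom, s.pos, s.strand) in labels]

    regions = build_threshold_regions(segmentation, genome.lengths)
    assigner = RegionAssigner(regions)
    thresholds, assignment = compute_regional_thresholds(
        sites, assigner, threshold_config.regional_percentile
    )
    partition = partition_crosslinks(sites, peaks, thresholds, assignment)

    rng = np.random.default_rng(config.seed)
    partition = subsample_partition(partition, threshold_config, rng)
    if not partition.txn:
        raise InsufficientDataError(f"region {region!r}: no thresholded crosslinks (tXn)")
    if not partition.oxn:
        raise InsufficientDataError(f"region {region!r}: no out-of-peak crosslinks (oXn)")

    max_off = config.max_offset
    w = config.proximal_half_width
    fg_pairs = [(s, extract_window(genome, s, max_off, max_off)) for s in partition.txn]
    bg_pairs = [(s, extract_window(genome, s, w, w)) for s in partition.oxn]
    fg_kept = [(s, q) for s, q in fg_pairs if q is not None]
    bg_kept = [(s, q) for s, q in bg_pairs if q is not None]
    if not fg_kept:
        raise InsufficientDataError(f"region {region!r}: all foreground windows out of bounds")
    if not bg_kept:
        raise InsufficientDataError(f"region {region!r}: all background windows out of bounds")

    core = enrichment_from_sequences(
        [q for _, q in fg_kept], [q for _, q in bg_kept], config, rng=rng
    )
    return PekaRunResult(
        region=region,
        results=_results_from_core(core),
        rtxn=core["rtxn"],
        proximal_positions=core["proximal_positions"],
        resolved_percentile=core["resolved_percentile"],
        n_txn=len(fg_kept),
        n_oxn=len(bg_kept),
        per_region_threshold=partition.per_region_threshold,
        config=config,
        txn=[s for s, _ in fg_kept],
        oxn=[s for s, _ in bg_kept],
    )
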