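"""Independent brute-force re-implementations used as test oracles.

Everything here is written with plain Python loops and dictionaries,
deliberately sharing no code with the package's vectorized paths.
"""

from __future__ import annotations

import itertools
import math

RNA = "ACGU"
DNA_TO_RNA = str.maketrans("Tt", "Uu")


def _window_valid(window: str, repeat_mode: str) -> bool:
    up = window.upper()
    if any(ch not in "ACGTU" for ch in up):
        return False
    has_lower = any(ch.islower() for ch in window)
    has_upper = any(ch.isupper() for ch in window)
    if repeat_mode == "exclude-repeats":
        return not has_lower
    if repeat_mode == "repeats-only":
        return not has_upper
    return True


def brute_occurrence(sequences, k, repeat_mode="exclude-repeats"):
    """occurrence[(kmer, offset)] by direct per-sequence scanning."""
    L = len(sequences[0])
    mid = L // 2
    c = (k - 1) // 2
    kmers = ["".join(p) for p in itertools.product(RNA, repeat=k)]
    occ = {}
    positions = [i + c - mid for i in range(L - k + 1)]
    for kmer in kmers:
        for start in range(L - k + 1):
            pos = start + c - mid
            count = 0
            for seq in sequences:
                window = seq[start : start + k]
                if not _window_valid(window, repeat_mode):
                    continue
                if window.upper().translate(DNA_TO_RNA) == kmer:
                    count += 1
            occ[(kmer, pos)] = count / len(sequences)
    return occ, positions, kmers


def brute_relative(occ, positions, kmers, distal_span, n_sequences):
    distal = [p for p in positions if any(lo <= p <= hi for lo, hi in distal_span)]
    floor = 1.0 / (n_sequences * len(distal))
    distal_mean = {}
    rel = {}
    for kmer in kmers:
        dm = sum(occ[(kmer, p)] for p in distal) / len(distal)
        if dm == 0:
            dm = floor
        distal_mean[kmer] = dm
        for p in positions:
            rel[(kmer, p)] = occ[(kmer, p)] / dm
    return rel, distal_mean


def brute_enrichment(fg, bg, k, w, distal_span, percentile, sample_indices,
                     repeat_mode="exclude-repeats", mode="thresholded"):
    """Full pipeline by loops: occurrences, RtXn, RoXn samples, thresholds,
    relevant positions, PEKA scores.  ``sample_indices`` are the background
    draws (shared with the path under test; the draws are inputs, the
    computation is not)."""
    occ_fg, fg_positions, kmers = brute_occurrence(fg, k, repeat_mode)
    rtxn, distal_mean = brute_relative(occ_fg, fg_positions, kmers, distal_span, len(fg))

    Lb = len(bg[0])
    midb = Lb // 2
    c = (k - 1) // 2
    bg_positions = [i + c - midb for i in range(Lb - k + 1)]

    samples = []
    for draw in sample_indices:
        chosen = [bg[i] for i in draw]
        occ_s, pos_s, _ = brute_occurrence(chosen, k, repeat_mode)
        assert pos_s == bg_positions
        roxn = {
            (kmer, p): occ_s[(kmer, p)] / distal_mean[kmer]
            for kmer in kmers
            for p in bg_positions
        }
        samples.append(roxn)

    thresholds = {}
    for p in bg_positions:
        pool = sorted(s[(kmer, p)] for s in samples for kmer in kmers)
        if percentile <= 0:
            thresholds[p] = pool[0]
        else:
            idx = math.ceil(percentile * len(pool)) - 1
            thresholds[p] = pool[min(max(idx, 0), len(pool) - 1)]

    relevant = {}
    for kmer in kmers:
        if mode == "all-proximal":
            relevant[kmer] = list(bg_positions)
            continue
        rel = [p for p in bg_positions if rtxn[(kmer, p)] > thresholds[p]]
        relevant[kmer] = rel if rel else list(bg_positions)

    sample_size = len(sample_indices[0])
    scores, artxns = {}, {}
    for kmer in kmers:
        rel = relevant[kmer]
        artxn = sum(rtxn[(kmer, p)] for p in rel) / len(rel)
        aroxn = [sum(s[(kmer, p)] for p in rel) / len(rel) for s in samples]
        mean_a = sum(aroxn) / len(aroxn)
        var = sum((x - mean_a) ** 2 for x in aroxn) / len(aroxn)
        # std floored at the one-count sampling granularity of ARoXn
        floor = max(1.0 / (sample_size * distal_mean[kmer] * len(rel)), 1e-12)
        std = max(math.sqrt(var), floor)
        scores[kmer] = (artxn - mean_a) / std
        artxns[kmer] = artxn
    return {
        "kmers": kmers,
        "occ": occ_fg,
        "positions": fg_positions,
        "bg_positions": bg_positions,
        "rtxn": rtxn,
        "thresholds": thresholds,
        "relevant": relevant,
        "scores": scores,
        "artxn": artxns,
    }


def enumerate_alignments(a, b):
    """All global alignments of a and b as (gapped_a, gapped_b) pairs."""
    out = []

    def rec(i, j, ga, gb):
        if i == len(a) and j == len(b):
            out.append(("".join(ga), "".join(gb)))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ga + [a[i]], gb + [b[j]])
        if i < len(a):
            rec(i + 1, j, ga + [a[i]], gb + ["-"])
        if j < len(b):
            rec(i, j + 1, ga + ["-"], gb + [b[j]])

    rec(0, 0, [], [])
    return out


def score_alignment(ga, gb, match=2, mismatch=-1, gap_open=5, gap_extend=2):
    """Affine-gap semiglobal score of one alignment; terminal gap runs free."""
    score = 0
    for row in (ga, gb):
        runs = []
        start = None
        for idx, ch in enumerate(row):
            if ch == "-" and start is None:
                start = idx
            elif ch != "-" and start is not None:
                runs.append((start, idx))
                start = None
        if start is not None:
            runs.append((start, len(row)))
        for s, e in runs:
            if s == 0 or e == len(row):
                continue
            score -= gap_open + gap_extend * (e - s - 1)
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            score += match if x == y else mismatch
    return score


def best_alignment_score(a, b, **kw):
    return max(score_alignment(ga, gb, **kw) for ga, gb in enumerate_alignments(a, b))
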