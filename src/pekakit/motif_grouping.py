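"""Group top k-mers by sequence/profile similarity; build MSAs, PFMs and
IUPAC consensus strings.

Sequence similarity is a Jaccard index over positional substring tokens;
clustering is affinity propagation (damping 0.5, max_iter 1000,
convergence_iter 200).  Alignments are semiglobal Needleman-Wunsch with
match +2, mismatch -1, gap open 5, gap extend 2 and free terminal gaps;
the multiple alignment is built progressively from pairwise alignments in
descending score order under a "once a gap, always a gap" merge rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cluster import AffinityPropagation

NUCLEOTIDES = "ACGU"

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "T": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}
_SET_TO_IUPAC = {v: k for k, v in IUPAC_CODES.items() if k != "T"}


@dataclass
class AlignmentParams:
    match: int = 2
    mismatch: int = -1
    gap_open: int = 5  # penalty for the first gap character in a run
    gap_extend: int = 2  # penalty per additional gap character


@dataclass
class MotifGroup:
    kmers: list[str]
    similarity: np.ndarray
    msa: list[str]
    pfm: pd.DataFrame
    consensus: str


def tokenize_kmer(kmer: str) -> frozenset[str]:
    """Positional substring tokens of a k-mer.

    Every contiguous substring becomes a token, suffixed with its cumulative
    left-to-right occurrence index among identical substrings, e.g. "AGGU"
    -> {A1, G1, G2, U1, AG1, GG1, GU1, AGG1, GGU1, AGGU1}.
    """
    if not kmer:
        raise ValueError("empty k-mer")
    kmer = kmer.upper().replace("T", "U")
    bad = set(kmer) - set(NUCLEOTIDES)
    if bad:
        raise ValueError(f"invalid characters in k-mer: {sorted(bad)}")
    seen: dict[str, int] = {}
    tokens = set()
    k = len(kmer)
    for length in range(1, k + 1):
        for start in range(k - length + 1):
            sub = kmer[start : start + length]
            seen[sub] = seen.get(sub, 0) + 1
            tokens.add(f"{sub}{seen[sub]}")
    return frozenset(tokens)


def jaccard_similarity(a: frozenset[str], b: frozenset[str]) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 1.0


def token_similarity_matrix(kmers: Sequence[str]) -> np.ndarray:
    tokens = [tokenize_kmer(k) for k in kmers]
    n = len(kmers)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = jaccard_similarity(tokens[i], tokens[j])
    return sim


def cluster_by_affinity(
    similarity: np.ndarray,
    damping: float = 0.5,
    max_iter: int = 1000,
    convergence_iter: int = 200,
    preference: float | None = None,
) -> np.ndarray:
    """Affinity-propagation cluster labels from a precomputed similarity matrix.

    The preference defaults to the matrix median; when the algorithm fails to
    converge everything is placed in a single cluster.
    """
    similarity = np.asarray(similarity, dtype=float)
    if similarity.ndim != 2 or similarity.shape[0] != similarity.shape[1]:
        raise ValueError("similarity matrix must be square")
    n = similarity.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    if preference is None:
        preference = float(np.median(similarity))
    ap = AffinityPropagation(
        affinity="precomputed",
        damping=damping,
        max_iter=max_iter,
        convergence_iter=convergence_iter,
        preference=preference,
        random_state=0,
    )
    labels = ap.fit(similarity).labels_
    if np.any(labels < 0):  # did not converge
        return np.zeros(n, dtype=int)
    return np.asarray(labels, dtype=int)


def _profile_similarity(profiles: np.ndarray) -> np.ndarray:
    """Similarity of occurrence profiles from (1) Spearman rank correlation,
    (2) profile maxima and (3) positions of the maxima, each scaled to [0, 1]
    and averaged."""
    n, n_pos = profiles.shape
    if n == 1:
        return np.ones((1, 1))
    rho = spearmanr(profiles, axis=1).statistic
    rho = np.atleast_2d(rho) if n > 2 else np.array([[1.0, rho], [rho, 1.0]])
    rho = np.nan_to_num(rho, nan=0.0)
    corr_sim = (rho + 1.0) / 2.0

    maxima = profiles.max(axis=1)
    scale = max(maxima.max() - maxima.min(), 1e-12)
    max_sim = 1.0 - np.abs(maxima[:, None] - maxima[None, :]) / scale

    argmax = profiles.argmax(axis=1).astype(float)
    span = max(n_pos - 1, 1)
    pos_sim = 1.0 - np.abs(argmax[:, None] - argmax[None, :]) / span

    sim = (corr_sim + max_sim + pos_sim) / 3.0
    np.fill_diagonal(sim, 1.0)
    return sim


#: sequence-vs-profile weightings tried when clustering the top k-mers
WEIGHT_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


def cluster_top_kmers(
    kmers: Sequence[str],
    profiles: np.ndarray | pd.DataFrame,
    max_clusters: int = 5,
) -> np.ndarray:
    """Cluster the top k-mers on combined sequence + profile similarity.

    Token-Jaccard and profile similarity matrices are blended over a fixed
    weight grid; each blend is clustered by affinity propagation and the
    clustering with the lowest mean within-cluster standard deviation of the
    k-mers' profile medians wins, restricted to at most ``max_clusters``
    clusters.  Fewer than two k-mers trivially form a single cluster.
    """
    if isinstance(profiles, pd.DataFrame):
        profiles = profiles.to_numpy()
    profiles = np.asarray(profiles, dtype=float)
    n = len(kmers)
    if profiles.shape[0] != n:
        raise ValueError("one profile per k-mer required")
    if n < 2:
        return np.zeros(n, dtype=int)
    seq_sim = token_similarity_matrix(kmers)
    prof_sim = _profile_similarity(profiles)
    medians = np.median(profiles, axis=1)

    best_labels = None
    best_score = np.inf
    fallback = None
    fallback_k = np.inf
    for w in WEIGHT_GRID:
        combined = w * seq_sim + (1 - w) * prof_sim
        labels = cluster_by_affinity(combined)
        n_clusters = len(np.unique(labels))
        if n_clusters < fallback_k:
            fallback, fallback_k = labels, n_clusters
        if n_clusters > max_clusters:
            continue
        score = np.mean(
            [np.std(medians[labels == c]) for c in np.unique(labels)]
        )
        if score < best_score:
            best_score, best_labels = score, labels
    if best_labels is None:
        best_labels = fallback if fallback_k <= max_clusters else np.zeros(n, dtype=int)
    return best_labels


# ---------------------------------------------------------------------------
# pairwise semiglobal alignment

_NEG = float("-inf")


def _score_columns(ga: str, gb: str, params: AlignmentParams) -> float:
    """Score a gapped alignment: matches/mismatches plus affine gap runs;
    runs touching either end are free."""
    score = 0.0
    L = len(ga)
    for row in (ga, gb):
        i = 0
        while i < L:
            if row[i] == "-":
                j = i
                while j < L and row[j] == "-":
                    j += 1
                if i != 0 and j != L:
                    score -= params.gap_open + params.gap_extend * (j - i - 1)
                i = j
            else:
                i += 1
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            score += params.match if x == y else params.mismatch
    return score


def pairwise_align(
    a: str, b: str, params: AlignmentParams | None = None
) -> tuple[str, str, float]:
    """Optimal semiglobal alignment of two k-mers.

    Affine gap costs (open + extend per additional position), terminal gaps
    free on both ends.  Ties are broken deterministically: fewest gap
    characters, then leftmost gap placement, then lexicographic.
    """
    params = params or AlignmentParams()
    a = a.upper().replace("T", "U")
    b = b.upper().replace("T", "U")
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        raise ValueError("cannot align empty strings")

    # states: 0 = match/mismatch, 1 = gap in b (consumes a), 2 = gap in a
    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)
    Y = np.full((la + 1, lb + 1), _NEG)
    M[0, 0] = 0.0
    X[1:, 0] = 0.0  # leading gaps in b are terminal -> free
    Y[0, 1:] = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = params.match if a[i - 1] == b[j - 1] else params.mismatch
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(
                M[i - 1, j] - params.gap_open,
                X[i - 1, j] - params.gap_extend,
                Y[i - 1, j] - params.gap_open,
            )
            Y[i, j] = max(
                M[i, j - 1] - params.gap_open,
                Y[i, j - 1] - params.gap_extend,
                X[i, j - 1] - params.gap_open,
            )
    # trailing gaps are free: finish on the last row or column in any state
    best = _NEG
    ends = []
    for i in range(la + 1):
        for j in range(lb + 1):
            if i != la and j != lb:
                continue
            local = max(M[i, j], X[i, j], Y[i, j])
            if local > best:
                best = local
    if best == _NEG:
        raise RuntimeError("alignment failed")

    # enumerate co-optimal alignments (k-mers are short) and pick by tie-break
    candidates: list[tuple[str, str]] = []

    def emit(i: int, j: int, ops: list[str]):
        # ops collected backwards from (i, j); prepend leading context, append trailing
        ga = []
        gb = []
        ai, bj = 0, 0
        for op in reversed(ops):
            if op == "M":
                ga.append(a[ai])
                gb.append(b[bj])
                ai += 1
                bj += 1
            elif op == "X":
                ga.append(a[ai])
                gb.append("-")
                ai += 1
            else:
                ga.append("-")
                gb.append(b[bj])
                bj += 1
        # trailing unconsumed characters sit against free terminal gaps
        tail_a = a[ai:]
        tail_b = b[bj:]
        ga.extend(tail_a)
        gb.extend("-" * len(tail_a))
        ga.extend("-" * len(tail_b))
        gb.extend(tail_b)
        candidates.append(("".join(ga), "".join(gb)))

    def walk(state: int, i: int, j: int, ops: list[str]):
        if i == 0 and j == 0:
            emit(i, j, ops)
            return
        if state == 0:
            if i == 0 or j == 0:
                return
            s = params.match if a[i - 1] == b[j - 1] else params.mismatch
            target = M[i, j] - s
            for st, grid in ((0, M), (1, X), (2, Y)):
                if np.isclose(grid[i - 1, j - 1], target):
                    walk(st, i - 1, j - 1, ops + ["M"])
        elif state == 1:
            if i == 0:
                return
            if j == 0:  # free leading run in b
                emit(i, j, ops + ["X"] * i)
                return
            if np.isclose(M[i - 1, j] - params.gap_open, X[i, j]):
                walk(0, i - 1, j, ops + ["X"])
            if np.isclose(X[i - 1, j] - params.gap_extend, X[i, j]):
                walk(1, i - 1, j, ops + ["X"])
            if np.isclose(Y[i - 1, j] - params.gap_open, X[i, j]):
                walk(2, i - 1, j, ops + ["X"])
        else:
            if j == 0:
                return
            if i == 0:
                emit(i, j, ops + ["Y"] * j)
                return
            if np.isclose(M[i, j - 1] - params.gap_open, Y[i, j]):
                walk(0, i, j - 1, ops + ["Y"])
            if np.isclose(Y[i, j - 1] - params.gap_extend, Y[i, j]):
                walk(2, i, j - 1, ops + ["Y"])
            if np.isclose(X[i, j - 1] - params.gap_open, Y[i, j]):
                walk(1, i, j - 1, ops + ["Y"])

    for i in range(la + 1):
        for j in range(lb + 1):
            if i != la and j != lb:
                continue
            for st, grid in ((0, M), (1, X), (2, Y)):
                if np.isclose(grid[i, j], best):
                    walk(st, i, j, [])

    def tie_key(cand: tuple[str, str]):
        ga, gb = cand
        gaps = ga.count("-") + gb.count("-")
        gap_cols = tuple(
            idx for idx, (x, y) in enumerate(zip(ga, gb)) if x == "-" or y == "-"
        )
        return (len(ga), gaps, gap_cols, ga, gb)

    ga, gb = min(set(candidates), key=tie_key)
    assert _score_columns(ga, gb, params) == best
    return ga, gb, float(best)


def build_msa(kmers: Sequence[str], params: AlignmentParams | None = None) -> list[str]:
    """Progressive multiple alignment of k-mers.

    Pairwise alignments are merged in descending score order (ties broken
    alphabetically); each new k-mer joins through its alignment to an anchor
    already in the MSA, preserving existing gap columns and inserting new
    gap columns where the pairwise alignment demands them.
    """
    kmers = [k.upper().replace("T", "U") for k in kmers]
    if not kmers:
        raise ValueError("no k-mers")
    if len(kmers) == 1:
        return list(kmers)
    params = params or AlignmentParams()

    pairs = []
    for i, j in itertools.combinations(range(len(kmers)), 2):
        ga, gb, score = pairwise_align(kmers[i], kmers[j], params)
        pairs.append((score, kmers[i], kmers[j], i, j, ga, gb))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    first = pairs[0]
    rows: dict[int, str] = {first[3]: first[5], first[4]: first[6]}
    included = {first[3], first[4]}
    remaining = pairs[1:]
    while len(included) < len(kmers):
        chosen = None
        for entry in remaining:
            _, _, _, i, j, _, _ = entry
            if (i in included) != (j in included):
                chosen = entry
                break
        if chosen is None:  # only both-included pairs left; drop them
            remaining = [e for e in remaining if not ({e[3], e[4]} <= included)]
            continue
        remaining.remove(chosen)
        _, _, _, i, j, ga, gb = chosen
        if i in included:
            anchor_idx, new_idx, anchor_gapped, new_gapped = i, j, ga, gb
        else:
            anchor_idx, new_idx, anchor_gapped, new_gapped = j, i, gb, ga
        rows = _merge_into_msa(rows, anchor_idx, new_idx, anchor_gapped, new_gapped)
        included.add(new_idx)
    width = max(len(r) for r in rows.values())
    return [rows[i].ljust(width, "-") for i in range(len(kmers))]


def _merge_into_msa(
    rows: Mapping[int, str],
    anchor_idx: int,
    new_idx: int,
    anchor_gapped: str,
    new_gapped: str,
) -> dict[int, str]:
    """Insert ``new_gapped`` into the MSA via its pairwise alignment to the
    anchor row ("once a gap, always a gap")."""
    anchor_row = rows[anchor_idx]
    residue_cols = [c for c, ch in enumerate(anchor_row) if ch != "-"]
    # emitted: list of (existing_col | None, char for the new row)
    emitted: list[tuple[int | None, str]] = []
    ai = 0  # next anchor residue
    prev_col = -1
    for a_ch, b_ch in zip(anchor_gapped, new_gapped):
        if a_ch != "-":
            col = residue_cols[ai]
            for between in range(prev_col + 1, col):  # anchor-gap columns of the MSA
                emitted.append((between, "-"))
            emitted.append((col, b_ch))
            prev_col = col
            ai += 1
        else:
            emitted.append((None, b_ch))
    for between in range(prev_col + 1, len(anchor_row)):
        emitted.append((between, "-"))

    out: dict[int, str] = {}
    for idx, row in rows.items():
        out[idx] = "".join("-" if col is None else row[col] for col, _ in emitted)
    out[new_idx] = "".join(ch for _, ch in emitted)
    return out


def pfm_from_msa(msa: Sequence[str]) -> pd.DataFrame:
    """Position-frequency matrix: per-column A/C/G/U counts over non-gap characters."""
    widths = {len(r) for r in msa}
    if len(widths) != 1:
        raise ValueError("MSA rows have unequal lengths")
    width = widths.pop()
    counts = {nt: [0] * width for nt in NUCLEOTIDES}
    for row in msa:
        for col, ch in enumerate(row):
            if ch != "-":
                counts[ch][col] += 1
    return pd.DataFrame(counts, index=range(width))


def consensus_from_pfm(pfm: pd.DataFrame, window_length: int) -> str:
    """IUPAC consensus from the first maximal-count window of the PFM.

    The window of ``window_length`` columns with the greatest total
    nucleotide count (leftmost on ties) yields, per column, the majority
    nucleotide or the IUPAC code of the tied set ('N' for empty columns).
    """
    n_cols = len(pfm)
    if window_length > n_cols:
        raise ValueError("window_length exceeds PFM width")
    col_sums = pfm.sum(axis=1).to_numpy()
    window_sums = np.convolve(col_sums, np.ones(window_length, dtype=int), "valid")
    start = int(np.argmax(window_sums))  # argmax returns the first maximum
    out = []
    for col in range(start, start + window_length):
        row = pfm.iloc[col]
        peak = row.max()
        if peak == 0:
            out.append("N")
            continue
        tied = frozenset(row.index[row == peak])
        out.append(_SET_TO_IUPAC[tied])
    return "".join(out)


def expand_iupac(motif: str) -> set[str]:
    """All unambiguous k-mers encoded by an IUPAC motif (Cartesian expansion)."""
    motif = motif.upper()
    try:
        options = [sorted(IUPAC_CODES[ch]) for ch in motif]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC character {exc.args[0]!r}") from None
    return {"".join(p) for p in itertools.product(*options)}


def motif_group(kmers: Sequence[str], window_length: int | None = None) -> MotifGroup:
    """Convenience bundle: similarity matrix, MSA, PFM and consensus for one cluster."""
    kmers = [k.upper().replace("T", "U") for k in kmers]
    sim = token_similarity_matrix(kmers)
    msa = build_msa(kmers)
    pfm = pfm_from_msa(msa)
    window = window_length or max(len(k) for k in kmers)
    return MotifGroup(list(kmers), sim, msa, pfm, consensus_from_pfm(pfm, window))
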