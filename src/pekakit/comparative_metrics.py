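"""Compare k-mer rankings across datasets and methods.

Covers recall of in vitro motifs (RBNS/RNAcompete) by CLIP rankings,
inter-dataset similarity of top-k-mer sets, conversion of 7-mer scores to
5-mer scores, and Welch-test-based differential k-mer groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DifferentialGroupConfig:
    p_threshold: float = 0.05  # the figure-level analysis also uses 0.01; exposed
    fc_upper: float = 1.5
    fc_lower: float = 0.66

    def __post_init__(self):
        if not self.fc_lower < 1 < self.fc_upper:
            raise ValueError("require fc_lower < 1 < fc_upper")


def _top_set(ranking: pd.Series, n: int) -> set[str]:
    """k-mers with the n numerically smallest ranks (1 = most enriched)."""
    if n > len(ranking):
        raise ValueError(f"cutoff {n} exceeds k-mer universe of {len(ranking)}")
    return set(ranking.nsmallest(n).index)


def recall(
    in_vitro_ranking: pd.Series,
    clip_ranking: pd.Series,
    n_top_in_vitro: int = 20,
    n_top_clip: int = 50,
) -> float:
    """Fraction of the in vitro method's top k-mers recovered in the CLIP top list.

    Both arguments map k-mer -> 1-based rank over the same k-mer universe.
    """
    if set(in_vitro_ranking.index) != set(clip_ranking.index):
        raise ValueError("rankings cover different k-mer universes")
    top_vitro = _top_set(in_vitro_ranking, n_top_in_vitro)
    top_clip = _top_set(clip_ranking, n_top_clip)
    return len(top_vitro & top_clip) / n_top_in_vitro


def recall_curve(
    in_vitro_ranking: pd.Series,
    clip_ranking: pd.Series,
    n_top_in_vitro: int = 20,
    cutoffs: Sequence[int] = (10, 20, 50, 100, 200),
) -> pd.Series:
    return pd.Series(
        {c: recall(in_vitro_ranking, clip_ranking, n_top_in_vitro, c) for c in cutoffs},
        name="recall",
    )


def scores_to_ranks(scores: pd.Series) -> pd.Series:
    """1-based ranks, highest score first, ties broken alphabetically."""
    ordered = sorted(scores.index, key=lambda m: (-scores[m], m))
    return pd.Series({m: r for r, m in enumerate(ordered, 1)}, name="rank").reindex(
        scores.index
    )


def convert_scores_7to5(scores7: pd.Series) -> pd.Series:
    """Average 7-mer scores into 5-mer scores, weighting each 7-mer by the
    number of times it contains the 5-mer (e.g. UUUUUUG carries UUUUU twice)."""
    alphabet = "ACGU"
    universe7 = 4**7
    index = pd.Index([m.upper().replace("T", "U") for m in scores7.index])
    if index.duplicated().any() or len(index) != universe7:
        missing = universe7 - len(set(index))
        raise ValueError(f"expected scores for all {universe7} 7-mers; {missing} missing")
    totals: dict[str, float] = {}
    counts: dict[str, int] = {}
    values = scores7.to_numpy(dtype=float)
    for sevenmer, score in zip(index, values):
        for start in range(3):  # a 7-mer holds exactly three 5-mer windows
            five = sevenmer[start : start + 5]
            totals[five] = totals.get(five, 0.0) + score
            counts[five] = counts.get(five, 0) + 1
    fivemers = ["".join(p) for p in itertools.product(alphabet, repeat=5)]
    return pd.Series({m: totals[m] / counts[m] for m in fivemers}, name="score")


def similarity_scores(rank_table: pd.DataFrame, top_n: int = 50) -> pd.Series:
    """Per-dataset mean pairwise overlap of top-``top_n`` k-mer sets.

    ``rank_table`` has one row per dataset and one column per k-mer holding
    1-based ranks.  Self-comparison is excluded, so 0 means a dataset's top
    k-mers appear in no other dataset's top list.
    """
    if len(rank_table) < 2:
        raise ValueError("similarity scores need at least two datasets")
    tops = {ds: _top_set(rank_table.loc[ds], top_n) for ds in rank_table.index}
    out = {}
    for ds in rank_table.index:
        overlaps = [
            len(tops[ds] & tops[other]) / top_n
            for other in rank_table.index
            if other != ds
        ]
        out[ds] = float(np.mean(overlaps))
    return pd.Series(out, name="similarity_score")


def differential_kmer_groups(
    clip_ranks: pd.DataFrame,
    invitro_ranks: pd.DataFrame,
    pairing: Sequence[tuple[str, str]] | None = None,
    config: DifferentialGroupConfig | None = None,
) -> pd.DataFrame:
    """Welch's t-test on per-k-mer rank distributions: CLIP vs in vitro.

    Returns a per-k-mer table with the Welch p-value, the fold change of
    mean ranks (CLIP / in vitro on 1-based ranks) and a group label:
    "enriched" (significantly better, i.e. numerically lower, mean rank in
    CLIP), "depleted" (the reverse) or "ns".
    """
    config = config or DifferentialGroupConfig()
    if pairing is not None:
        clip_ranks = clip_ranks.loc[[c for c, _ in pairing]]
        invitro_ranks = invitro_ranks.loc[[v for _, v in pairing]]
    if len(clip_ranks) < 2 or len(invitro_ranks) < 2:
        raise ValueError("Welch's test needs at least two datasets per side")
    kmers = clip_ranks.columns
    if not kmers.equals(invitro_ranks.columns):
        raise ValueError("rank tables cover different k-mer universes")
    a = clip_ranks.to_numpy(dtype=float)
    b = invitro_ranks.to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    fc = a.mean(axis=0) / b.mean(axis=0)
    significant = (p < config.p_threshold) & ((fc > config.fc_upper) | (fc < config.fc_lower))
    group = np.where(
        significant & (fc < config.fc_lower),
        "enriched",
        np.where(significant & (fc > config.fc_upper), "depleted", "ns"),
    )
    return pd.DataFrame(
        {"p_value": p, "fold_change": fc, "group": group}, index=kmers
    )


def differential_sets(table: pd.DataFrame) -> tuple[set[str], set[str]]:
    enriched = set(table.index[table["group"] == "enriched"])
    depleted = set(table.index[table["group"] == "depleted"])
    return enriched, depleted
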