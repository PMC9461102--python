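"""Metaprofiles of motif-group coverage around crosslink sites.

For every offset in a window around each crosslink, the profile records the
fraction of crosslink sites (or, weighted, of cDNA counts) whose flanking
sequence carries any k-mer of the motif group covering that offset.
Profiles can be smoothed with a centered rolling mean and compared across
datasets with per-position z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pekakit.formats_io import CrosslinkSite, Genome, extract_window


@dataclass
class CoverageProfile:
    positions: np.ndarray  # contiguous offsets, default -150..150
    values: np.ndarray  # fractions in [0, 1]
    weighted: bool
    n_sites: int

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.positions, name="coverage")


def _flag_offsets(seq: str, motifs: Sequence[str], flag_mode: str) -> np.ndarray:
    """Boolean flags over the window: offsets covered by any motif match.

    ``flag_mode`` "span" flags every nucleotide of a match, "start" only the
    match's first nucleotide.
    """
    flags = np.zeros(len(seq), dtype=bool)
    upper = seq.upper().replace("T", "U")
    for motif in motifs:
        m = motif.upper().replace("T", "U")
        start = upper.find(m)
        while start != -1:
            if flag_mode == "span":
                flags[start : start + len(m)] = True
            else:
                flags[start] = True
            start = upper.find(m, start + 1)
    return flags


def motif_group_coverage(
    crosslinks: Iterable[CrosslinkSite],
    genome: Genome,
    motif_group: Sequence[str],
    window: int = 150,
    weighted: bool = False,
    flag_mode: str = "span",
) -> CoverageProfile:
    """Per-offset coverage of a motif group around crosslinks.

    Each site contributes at most once per offset (its cDNA count in
    weighted mode), no matter how many group k-mers match there; sites whose
    window leaves the chromosome are dropped.
    """
    motifs = [m for m in motif_group if m]
    if not motifs:
        raise ValueError("empty motif group")
    if flag_mode not in ("span", "start"):
        raise ValueError("flag_mode must be 'span' or 'start'")
    width = 2 * window + 1
    acc = np.zeros(width)
    total = 0.0
    n_sites = 0
    for site in crosslinks:
        seq = extract_window(genome, site, window, window)
        if seq is None:
            continue
        weight = float(site.cdna_count) if weighted else 1.0
        acc += weight * _flag_offsets(seq, motifs, flag_mode)
        total += weight
        n_sites += 1
    if n_sites == 0:
        raise ValueError("no crosslink site has a fully in-bounds window")
    return CoverageProfile(
        positions=np.arange(-window, window + 1),
        values=acc / total,
        weighted=weighted,
        n_sites=n_sites,
    )


def smooth_profile(profile: CoverageProfile, window: int = 6) -> CoverageProfile:
    """Centered rolling mean; even windows place the extra position on the
    right, and edges average over the available positions only."""
    if window < 1:
        raise ValueError("window must be >= 1")
    left = (window - 1) // 2
    right = window // 2
    values = profile.values
    n = len(values)
    smoothed = np.array(
        [values[max(0, i - left) : min(n, i + right + 1)].mean() for i in range(n)]
    )
    return CoverageProfile(profile.positions.copy(), smoothed, profile.weighted, profile.n_sites)


def coverage_zscores(
    profiles: pd.DataFrame, max_abs_offset: int = 50
) -> pd.DataFrame:
    """Per-dataset maximal cross-dataset z-score within +/- ``max_abs_offset``.

    ``profiles`` holds one row per dataset and one column per offset.  At
    each offset, z = (value - mean over datasets) / population std (0 when
    the std is 0); the result reports each dataset's maximum z and where it
    is achieved.
    """
    if len(profiles) < 2:
        raise ValueError("z-scores need at least two datasets")
    offsets = profiles.columns.to_numpy(dtype=int)
    keep = np.abs(offsets) <= max_abs_offset
    vals = profiles.to_numpy(dtype=float)[:, keep]
    offs = offsets[keep]
    mean = vals.mean(axis=0)
    std = vals.std(axis=0)
    z = np.where(std > 0, (vals - mean) / np.where(std > 0, std, 1.0), 0.0)
    best = z.argmax(axis=1)
    return pd.DataFrame(
        {
            "max_z": z[np.arange(len(profiles)), best],
            "argmax_offset": offs[best],
        },
        index=profiles.index,
    )
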