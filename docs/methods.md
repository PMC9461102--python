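# Methods

`pekakit` implements positionally enriched k-mer analysis (PEKA) for
nucleotide-resolution CLIP data: given crosslink sites (one nucleotide per
record, score = cDNA count), peak intervals, a genome and a region
segmentation, it ranks all 4^k k-mers by how strongly and how locally they
are enriched around high-occupancy crosslink sites relative to the
dataset's own low-occupancy background.

## Model and procedure

**Thresholding.** Crosslinks are partitioned into tXn (inside a
strand-compatible peak with cDNA count strictly above a regional
threshold), oXn (outside every peak) and "other" (in peak, at or below the
threshold). Thresholding regions are a gene's merged exons (CDS + UTRs +
ncRNA exons), each intron individually, and each maximal intergenic
stretch. The regional threshold is the smallest integer c such that at
least a fraction q (default 0.70) of the region's sites have count ≤ c;
q = 0 gives threshold 0, so every in-peak site becomes tXn. In CLIP
libraries dominated by single-cDNA crosslinks this mostly removes count-1
sites from the foreground. tXn and oXn are uniformly subsampled (without
replacement) to at most 10^6 and 3·10^6 sites by default.

**Occurrence and normalization.** Foreground windows span ±150 nt around
tXn, background windows ±w (default w = 20) around oXn; windows crossing a
chromosome end are dropped, all sequences are read 5'→3' on the site's
strand. For each k-mer, occurrence at offset p is the fraction of
sequences carrying the k-mer with its counted nucleotide at p — the middle
base for odd k, the (k/2)-th overlapping base for even k (the 3rd for a
6-mer). Windows containing N are skipped, and the repeat mode decides
whether windows touching lowercase (soft-masked) bases are excluded
(default), included, or exclusively analyzed. Relative occurrence divides
each k-mer's occurrence profile by its mean occurrence over the distal
windows (−150..−100 and 100..150) of the foreground; the same
foreground-derived denominator normalizes the background, which has no
distal window of its own. A zero distal mean is floored at
1/(n_foreground × n_distal_positions), the smallest occurrence observable
once.

**Background distribution and relevant positions.** 100 samples of
background sequences, each matching the foreground in size (without
replacement when the background is large enough), give 100 RoXn profiles
per k-mer. At each proximal offset, the pooled 100 × 4^k RoXn values
define a position threshold at a percentile (nearest-rank). Offsets where
RtXn exceeds the threshold are the k-mer's relevant positions; a k-mer
passing nowhere falls back to all proximal offsets, and an all-proximal
mode skips the selection entirely.

**Score and p-value.** ARtXn is the mean RtXn over the relevant positions;
each background sample yields one ARoXn over the same positions. The PEKA
score is (ARtXn − mean(ARoXn)) / std(ARoXn) with the population standard
deviation over the 100 samples. k-mers are ranked by score (ties broken
alphabetically in the U-alphabet); p-values are the upper normal tail of
z-scored PEKA scores, so they order exactly with the scores and are
relative to the dataset's own score distribution, not an absolute null.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 5 | k-mer length (4^k k-mers scored) |
| w | 20 nt | proximal half-width; enrichment is sought in ±w |
| distal span | ±100..150 nt | normalization baseline offsets |
| background samples | 100 | RoXn replicates, each foreground-sized |
| regional percentile | 0.70 | cDNA-count threshold quantile per region |
| position percentile | "auto" → 0.70 | quantile of pooled RoXn defining position thresholds |
| subsampling caps | 10^6 tXn / 3·10^6 oXn | tractability caps, can be disabled |

The upstream tool sets the position percentile automatically from k and
the foreground size by an unpublished rule; here "auto" resolves to a
fixed 0.70 and the resolved value is recorded in every run manifest, so
runs are reproducible rather than dependent on a guessed formula.

## Numerical choices

* **Percentiles** are nearest-rank everywhere (regional thresholds,
  position thresholds): integer-friendly and consistent with the
  worked-example threshold of 1 for nine count-1 sites and one count-2 site.
* **"Above the threshold" is strict** (count > c), which reproduces that
  same worked example (count-1 sites are excluded at threshold 1).
* **std(ARoXn) floor.** A k-mer whose background never occurs at its
  relevant positions has std(ARoXn) = 0; dividing by a tiny constant floor
  would let a single spurious foreground hit dominate the whole ranking
  (scores ~10^12 observed at desk scale). The denominator is therefore
  floored at the sampling granularity of ARoXn — the increment one
  background count makes, 1/(sample_size × distal_mean × n_relevant) —
  which leaves every non-degenerate score untouched (observed
  standard deviations are far above this floor) and caps degenerate cells
  at O(1). A zero numerator still gives score 0.
* **Ties.** Ranking ties break alphabetically; the consensus window and
  the progressive-MSA merge order use leftmost/alphabetical tie-breaks so
  all outputs are deterministic.
* **Alignment convention.** Semiglobal Needleman–Wunsch, match +2,
  mismatch −1; a gap run of length g costs 5 + 2(g−1); terminal gaps are
  free. Among co-optimal alignments the one with fewest gap characters,
  then leftmost gap placement, is returned. The progressive MSA merges
  pairwise alignments in descending score order (alphabetical on ties)
  under "once a gap, always a gap".
* **Affinity propagation** (damping 0.5, max_iter 1000, convergence_iter
  200) uses the similarity-matrix median as preference and a fixed random
  state; a non-converged run falls back to a single cluster. For the
  top-k-mer clustering, sequence (token-Jaccard) and profile similarities
  (Spearman correlation, profile maxima, argmax offsets, each scaled to
  [0,1]) are blended over sequence weights {0, 0.25, 0.5, 0.75, 1}; the
  blend minimizing the mean within-cluster standard deviation of profile
  medians wins, restricted to at most 5 clusters.
* **Metaprofiles** flag every offset a motif match spans (a switch
  restricts flagging to match starts); a site contributes at most once
  (or its cDNA count, weighted) per offset. The rolling-mean smoother
  centers even windows with the extra position on the right and shrinks at
  the edges. Cross-dataset z-scores use the population standard deviation
  and define z = 0 where the std is 0.

## Null behavior

When foreground and background windows come from the same sequence
distribution, the score in **all-proximal mode** is a calibrated z-like
statistic: its mean over all 5-mers is ≈ 0 (measured 0.015 at the fixture
scale) and no k-mer stands out. In the default **thresholded mode** the
mean is positive even under a null (measured ≈ 4 at fixture scale),
because relevant positions are by definition offsets where the foreground
exceeds a background quantile — a selection that conditions on upward
noise. This is inherent to the estimator, not a sample-size artifact; it
is why p-values are computed from the empirical score distribution rather
than from N(0,1), and why the test suite checks null calibration with
positional selection disabled while separately asserting that the
thresholded-mode bias is positive (a characterization, not a defect).

## Synthetic fixtures

The generator builds a random genome (configurable GC and soft-masked
fraction), non-overlapping genes with UTR5–CDS/intron–UTR3 structure on
alternating strands, clustered "signal" crosslinks inside peaks with
counts uniform on 2..10 and a motif physically written into the genome at
a random offset in −2..+2 around each site, and uniform count-1
background crosslinks outside peaks. Defaults: 100 kb genome, 5 genes,
500 signal and 5000 background sites, motif UGUGU, planting probability 1.
Signal sites keep a minimum spacing so planted motifs never overwrite one
another, and the planting decision consumes its random draws
unconditionally (common random numbers), so fixtures that differ only in
planting probability share all other structure and probability sweeps are
nested — rank monotonicity in the planting probability is then a
well-posed property. Everything is seeded end to end; identical
configurations produce byte-identical files.

What passing tests on these fixtures show — and what they do not: the
fixtures reproduce the geometry of CLIP data (single-nucleotide sites,
count skew, peaks, regional structure) but not crosslinking sequence
biases, non-uniform transcript abundance, or sequencing noise, so planted
-motif recovery demonstrates correctness of the computation, not
performance on real libraries.

## Known limitations

* The automatic position-percentile rule of the upstream tool is not
  published; "auto" here is a documented constant.
* Thresholded-mode scores are not centered under a null (see above);
  compare scores within a run, not across runs with different settings.
* With very few foreground sequences (tens), occurrence profiles are
  dominated by count discreteness; the regional percentile can be lowered
  to 0 to admit more sites, at some cost in specificity.
* Logo rendering is out of scope; PFMs and IUPAC consensus strings are the
  exported artifacts.
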