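import numpy as np
import pytest

from pekakit.enrichment_core import (
    EnrichmentConfig,
    InsufficientDataError,
    all_kmers,
    distal_positions,
    draw_sample_indices,
    enrichment_from_sequences,
    kmer_id_matrix,
    nearest_rank,
    peka_score,
    position_thresholds,
    rank_kmers,
    relative_occurrence,
    relevant_positions,
    restrict,
    run_peka,
    sample_background,
    scan_kmers,
    score_pvalues,
)
from pekakit.synthetic_fixtures import FixtureConfig, generate_fixture
from pekakit.thresholding import ThresholdConfig

from _oracles import brute_enrichment


class TestScanKmers:
    def test_homopolymer_occupies_every_center(self):
        occ = scan_kmers(["AAAAAAA"] * 3, k=5)
        aaaaa = occ.values[0]
        assert np.allclose(aaaaa, 1.0)
        assert occ.values[1:].sum() == 0
        assert list(occ.positions) == [-1, 0, 1]

    def test_per_position_sum_is_one_for_clean_sequences(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 21)) for _ in range(20)]
        occ = scan_kmers(seqs, k=5)
        assert np.allclose(occ.values.sum(axis=0), 1.0)

    def test_center_assignment_for_odd_k(self):
        occ = scan_kmers(["ACGUA", "ACGGA"], k=3)
        kmers = all_kmers(3)
        at0 = dict(zip(kmers, occ.values[:, list(occ.positions).index(0)]))
        assert at0["CGU"] == 0.5 and at0["CGG"] == 0.5

    def test_center_assignment_for_even_k(self):
        # a 6-mer's count lands on its 3rd overlapping nucleotide
        occ = scan_kmers(["ACGUAC G".replace(" ", "")], k=6)
        kmers = all_kmers(6)
        idx = kmers.index("ACGUAC")
        pos = occ.positions[np.nonzero(occ.values[idx])[0]]
        # sequence ACGUACG, mid offset 0 at index 3 (U); ACGUAC starts at 0,
        # 3rd overlapping base is index 2 -> offset -1
        assert list(pos) == [-1]

    def test_windows_with_n_are_skipped(self):
        occ = scan_kmers(["ANGUA", "ACGUA"], k=3)
        col = occ.values[:, list(occ.positions).index(0)]
        assert col.sum() == 0.5  # only the clean sequence contributes

    def test_repeat_modes(self):
        seqs = ["acgua", "ACGUA"]
        center = lambda occ: occ.values[:, list(occ.positions).index(0)].sum()
        assert center(scan_kmers(seqs, 3, "exclude-repeats")) == 0.5
        assert center(scan_kmers(seqs, 3, "repeats-only")) == 0.5
        assert center(scan_kmers(seqs, 3, "with-repeats")) == 1.0

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError, match="unequal"):
            scan_kmers(["ACGUA", "ACG"], k=3)


class TestRelativeOccurrence:
    def test_flat_occurrence_gives_one_everywhere(self):
        occ = scan_kmers(["AAAAAAA"] * 4, k=5)
        rel = relative_occurrence(occ, restrict(occ, [-1, 1]))
        assert np.allclose(rel.values[0], 1.0)

    def test_direct_division(self):
        occ = scan_kmers(["AAAAAAA"] * 4, k=5)
        occ.values[0] = 0.20
        dist = restrict(occ, [-1, 1])
        dist.values[0] = 0.05
        rel = relative_occurrence(occ, dist)
        assert np.allclose(rel.values[0], 4.0)

    def test_zero_distal_mean_is_floored_finite(self):
        occ = scan_kmers(["AAAAAAA"] * 4, k=5)
        rel = relative_occurrence(occ, restrict(occ, [-1, 1]))
        assert np.all(np.isfinite(rel.values))
        assert np.all(rel.values[1:] == 0.0)  # 0 / floor = 0
        # floor equals the smallest occurrence observable once
        assert rel.distal_mean[1] == pytest.approx(1 / (4 * 2))


class TestBackgroundSampling:
    def test_full_background_single_sample_equals_population(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 11)) for _ in range(30)]
        ids, _ = kmer_id_matrix(seqs, 3)
        dm = np.ones(64)
        idx = draw_sample_indices(np.random.default_rng(0), 30, 1, 30)
        assert sorted(idx[0]) == list(range(30))  # without replacement, full draw
        occ = scan_kmers(seqs, 3)
        samples = sample_background(ids, 3, dm, idx)
        assert np.allclose(samples[0], occ.values)

    def test_reproducible_under_seed(self, rng):
        idx1 = draw_sample_indices(np.random.default_rng(42), 100, 5, 30)
        idx2 = draw_sample_indices(np.random.default_rng(42), 100, 5, 30)
        assert np.array_equal(idx1, idx2)

    def test_small_background_sampled_with_replacement(self):
        idx = draw_sample_indices(np.random.default_rng(0), 5, 3, 12)
        assert idx.shape == (3, 12)
        assert idx.max() < 5

    def test_empty_background_raises(self):
        with pytest.raises(ValueError):
            draw_sample_indices(np.random.default_rng(0), 0, 1, 5)


class TestPositionThresholds:
    def test_extreme_percentiles(self):
        bg = np.arange(24, dtype=float).reshape(2, 4, 3)  # 2 samples, 4 kmers, 3 pos
        assert np.array_equal(
            position_thresholds(bg, 1.0), bg.reshape(-1, 3).max(axis=0)
        )
        assert np.array_equal(
            position_thresholds(bg, 0.0), bg.reshape(-1, 3).min(axis=0)
        )

    def test_nearest_rank_on_small_pool(self):
        assert nearest_rank(np.array([0.5, 1.0, 1.5, 2.0]), 0.5) == 1.0
        assert nearest_rank(np.array([0.5, 1.0, 1.5, 2.0]), 0.0) == 0.5
        assert nearest_rank(np.array([0.5, 1.0, 1.5, 2.0]), 1.0) == 2.0


class TestRelevantPositions:
    def test_fallback_to_all_proximal(self):
        rtxn = np.full((2, 5), 1.0)
        rel = relevant_positions(rtxn, np.full(5, 2.0))
        assert all(np.array_equal(r, np.arange(5)) for r in rel)

    def test_direct_threshold_comparison(self):
        rtxn = np.array([[1.0, 3.0, 3.0, 1.0, 1.0]])
        rel = relevant_positions(rtxn, np.full(5, 2.0))
        assert np.array_equal(rel[0], [1, 2])

    def test_all_proximal_mode(self):
        rtxn = np.array([[1.0, 3.0, 3.0, 1.0, 1.0]])
        rel = relevant_positions(rtxn, np.full(5, 2.0), mode="all-proximal")
        assert np.array_equal(rel[0], np.arange(5))


class TestPekaScore:
    def test_hand_computed_example(self):
        """ARtXn 2.0 against background means {1.0, 1.2, 0.8, 1.0}."""
        rtxn = np.full((1, 1), 2.0)
        bg = np.array([1.0, 1.2, 0.8, 1.0]).reshape(4, 1, 1)
        scores, artxn, mean_a, std_a = peka_score(rtxn, bg, [np.array([0])])
        assert artxn[0] == 2.0
        assert mean_a[0] == pytest.approx(1.0)
        assert std_a[0] == pytest.approx(np.sqrt(0.02))
        assert scores[0] == pytest.approx(1.0 / np.sqrt(0.02))  # ~7.0711

    def test_zero_when_foreground_matches_background(self):
        rtxn = np.full((1, 3), 1.5)
        bg = np.full((5, 1, 3), 1.5)
        bg[0] += 0.1
        bg[1] -= 0.1
        scores, *_ = peka_score(rtxn, bg, [np.arange(3)])
        assert scores[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_flat_background_gives_zero(self):
        rtxn = np.full((1, 2), 1.0)
        bg = np.full((4, 1, 2), 1.0)
        scores, *_ = peka_score(rtxn, bg, [np.arange(2)])
        assert scores[0] == 0.0


class TestScorePvalues:
    def test_symmetry_and_tail(self):
        scores = np.array([0.0, 1.0, 2.0, 3.0, 4.0])  # mean 2, std sqrt(2)
        p = score_pvalues(scores)
        assert p[2] == pytest.approx(0.5)
        scores = np.concatenate([np.zeros(5), np.ones(5)])  # std 0.5
        p = score_pvalues(scores)
        assert p[-1] == pytest.approx(0.158655, abs=1e-5)  # z = +1

    def test_strictly_decreasing_in_score(self, rng):
        scores = np.sort(rng.normal(size=50))
        p = score_pvalues(scores)
        assert np.all(np.diff(p) < 0)

    def test_degenerate_distribution_raises(self):
        with pytest.raises(ValueError):
            score_pvalues(np.ones(10))


def test_rank_ties_break_alphabetically():
    kmers = ["GG", "AA", "CC"]
    ranks = rank_kmers(np.array([1.0, 1.0, 2.0]), kmers)
    assert list(ranks) == [3, 2, 1]  # CC first, then AA before GG


class TestOracleEquivalence:
    """The vectorized pipeline must match an independent loop-based
    re-implementation on small random instances, value for value."""

    @pytest.mark.parametrize("seed,k,n_fg,n_bg", [(0, 2, 20, 60), (1, 3, 50, 100), (2, 1, 10, 25)])
    def test_full_pipeline_matches_brute_force(self, seed, k, n_fg, n_bg):
        rng = np.random.default_rng(seed)
        max_off, w = 8, 3
        distal = ((-8, -5), (5, 8))
        fg = ["".join(rng.choice(list("ACGT"), 2 * max_off + 1)) for _ in range(n_fg)]
        bg = ["".join(rng.choice(list("ACGT"), 2 * w + 1)) for _ in range(n_bg)]
        config = EnrichmentConfig(
            k=k,
            proximal_half_width=w,
            distal_span=distal,
            n_background_samples=5,
            position_percentile=0.7,
            seed=seed,
        )
        indices = draw_sample_indices(np.random.default_rng(seed + 10), n_bg, 5, n_fg)
        core = enrichment_from_sequences(fg, bg, config, sample_indices=indices)
        oracle = brute_enrichment(
            fg, bg, k, w, distal, 0.7, indices, repeat_mode="exclude-repeats"
        )
        kmers = core["kmers"]
        assert kmers == oracle["kmers"]
        positions = list(core["occ"].positions)
        assert positions == oracle["positions"]
        for m, kmer in enumerate(kmers):
            for j, p in enumerate(positions):
                assert core["occ"].values[m, j] == pytest.approx(
                    oracle["occ"][(kmer, p)], abs=1e-9
                )
                assert core["rtxn"].values[m, j] == pytest.approx(
                    oracle["rtxn"][(kmer, p)], abs=1e-9
                )
        bg_positions = list(core["proximal_positions"])
        assert bg_positions == oracle["bg_positions"]
        for j, p in enumerate(bg_positions):
            assert core["thresholds"][j] == pytest.approx(oracle["thresholds"][p], abs=1e-9)
        for m, kmer in enumerate(kmers):
            got = [bg_positions[i] for i in core["relevant"][m]]
            assert got == oracle["relevant"][kmer]
            assert core["scores"][m] == pytest.approx(oracle["scores"][kmer], abs=1e-9)


class TestRunPeka:
    def test_planted_motif_ranks_first(self, default_run):
        assert default_run.results[0].kmer == "UGUGU"
        assert default_run.results[0].rank == 1

    def test_output_size_and_rank_permutation(self, default_run):
        assert len(default_run.results) == 4**5
        assert sorted(r.rank for r in default_run.results) == list(range(1, 4**5 + 1))

    def test_order_invariance(self, default_fixture):
        fx = default_fixture
        config = EnrichmentConfig(seed=5)
        tcfg = ThresholdConfig(seed=5)
        res1 = run_peka(fx.crosslinks, fx.peaks, fx.genome, fx.segmentation, "genome", config, tcfg)
        shuffled = list(fx.crosslinks)
        np.random.default_rng(99).shuffle(shuffled)
        res2 = run_peka(shuffled, fx.peaks, fx.genome, fx.segmentation, "genome", config, tcfg)
        s1 = {r.kmer: r.peka_score for r in res1.results}
        s2 = {r.kmer: r.peka_score for r in res2.results}
        assert s1 == s2

    def test_insufficient_data_names_region(self, default_fixture):
        fx = default_fixture
        with pytest.raises(InsufficientDataError, match="ncRNA"):
            run_peka(
                fx.crosslinks, fx.peaks, fx.genome, fx.segmentation, "ncRNA",
                EnrichmentConfig(seed=1), ThresholdConfig(seed=1),
            )

    def test_region_filtering_reduces_foreground(self, default_fixture, default_run):
        fx = default_fixture
        res = run_peka(
            fx.crosslinks, fx.peaks, fx.genome, fx.segmentation, "intron",
            EnrichmentConfig(seed=1), ThresholdConfig(seed=1),
        )
        assert 0 < res.n_txn < default_run.n_txn
        labels = {
            fx.segmentation.lookup(s.chrom, s.pos, s.strand) for s in res.txn
        }
        assert labels == {"intron"}


def test_planted_motif_rank_monotone_in_planting_probability():
    """More frequent planting can only improve (not worsen) the motif's rank."""
    ranks = []
    for prob in (0.25, 0.5, 1.0):
        fx = generate_fixture(
            FixtureConfig(seed=21, planted_motifs=[("UGUGU", (-2, 2), prob)])
        )
        res = run_peka(
            fx.crosslinks, fx.peaks, fx.genome, fx.segmentation, "genome",
            EnrichmentConfig(seed=21), ThresholdConfig(seed=21),
        )
        ranks.append({r.kmer: r.rank for r in res.results}["UGUGU"])
    assert ranks[0] >= ranks[1] >= ranks[2]
    assert ranks[2] == 1


def test_occurrence_conservation_with_masked_windows(rng):
    """Per-position k-mer occurrence sums to the fraction of sequences whose
    window at that position is valid."""
    seqs = []
    for _ in range(30):
        chars = list(rng.choice(list("ACGT"), 15))
        if rng.random() < 0.5:
            chars[int(rng.integers(0, 15))] = "N"
        if rng.random() < 0.5:
            j = int(rng.integers(0, 15))
            chars[j] = chars[j].lower()
        seqs.append("".join(chars))
    occ = scan_kmers(seqs, k=3, repeat_mode="exclude-repeats")
    ids, _ = kmer_id_matrix(seqs, 3, "exclude-repeats")
    valid_fraction = (ids >= 0).mean(axis=0)
    assert np.allclose(occ.values.sum(axis=0), valid_fraction)
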