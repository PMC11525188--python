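"""Motif enrichment, background sampling and proximity co-occurrence."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from neocistrome import (
    ConsensusMotif,
    EnrichmentResult,
    GenomicInterval,
    MotifHit,
    PeakSet,
    build_profile,
    make_background,
    motif_enrichment,
    proximity_coenrichment,
    rank_profiles,
    scan,
    simulate_genome,
)

from conftest import hypergeom_tail_exact


def forced_peakset(genome_parts, chrom, label, motif, positive_flags, width=40):
    """Lay peaks end to end on an A-only chromosome; positives carry one
    exact motif instance, so per-peak presence is fully controlled."""
    seq = []
    intervals = []
    pos = 0
    for i, positive in enumerate(positive_flags):
        body = "A" * width
        if positive:
            body = body[:10] + motif + body[10 + len(motif):]
        seq.append(body)
        intervals.append(GenomicInterval(chrom, pos, pos + width, name=f"{label}_{i}"))
        pos += width
    genome_parts[chrom] = "".join(seq)
    return PeakSet(intervals, label)


MOTIF = "CGTCGG"  # contains no A: cannot occur on an A-only background
PROFILE = build_profile(ConsensusMotif("probe", MOTIF), 0)


class TestMotifEnrichment:
    def test_counts_fold_and_exact_tail(self):
        """500 targets / 200 positive vs 5000 background / 250 positive:
        fold is exactly 8 and the p-value matches direct tail summation."""
        genome: dict[str, str] = {}
        target = forced_peakset(genome, "chrT", "t", MOTIF,
                                [i < 200 for i in range(500)])
        background = forced_peakset(genome, "chrB", "b", MOTIF,
                                    [i < 250 for i in range(5000)])
        res = motif_enrichment(PROFILE, target, background, genome)
        assert (res.n_target_with, res.n_background_with) == (200, 250)
        assert res.fold_change == pytest.approx(8.0, abs=1e-12)
        exact = float(hypergeom_tail_exact(200, 5500, 450, 500))
        assert res.p_value == pytest.approx(exact, rel=1e-9)

    def test_equal_fractions_give_fold_one(self):
        genome: dict[str, str] = {}
        target = forced_peakset(genome, "chrT", "t", MOTIF,
                                [i < 20 for i in range(100)])
        background = forced_peakset(genome, "chrB", "b", MOTIF,
                                    [i < 40 for i in range(200)])
        res = motif_enrichment(PROFILE, target, background, genome)
        assert res.fold_change == pytest.approx(1.0)

    def test_zero_background_pseudocount_and_single_term_tail(self):
        genome: dict[str, str] = {}
        target = forced_peakset(genome, "chrT", "t", MOTIF, [True] * 5)
        background = forced_peakset(genome, "chrB", "b", MOTIF, [False] * 10)
        res = motif_enrichment(PROFILE, target, background, genome)
        assert np.isfinite(res.fold_change) and res.fold_change > 0
        # all 5 positives drawn into the 5 target slots: one arrangement
        exact = float(hypergeom_tail_exact(5, 15, 5, 5))
        assert res.p_value == pytest.approx(exact, rel=1e-9)

    def test_empty_sets_rejected(self):
        genome: dict[str, str] = {}
        target = forced_peakset(genome, "chrT", "t", MOTIF, [True])
        with pytest.raises(ValueError):
            motif_enrichment(PROFILE, target, PeakSet([], "bg"), genome)

    def test_peak_order_invariance(self):
        genome: dict[str, str] = {}
        target = forced_peakset(genome, "chrT", "t", MOTIF,
                                [i % 3 == 0 for i in range(60)])
        background = forced_peakset(genome, "chrB", "b", MOTIF,
                                    [i % 7 == 0 for i in range(140)])
        res = motif_enrichment(PROFILE, target, background, genome)
        shuffled_t = PeakSet(list(target)[::-1], "t")
        shuffled_b = PeakSet(list(background)[::-1], "b")
        res2 = motif_enrichment(PROFILE, shuffled_t, shuffled_b, genome)
        assert (res.n_target_with, res.p_value) == (res2.n_target_with, res2.p_value)

    def test_tail_matches_permutation_estimate(self):
        """Monte-Carlo label permutation agrees with the analytic tail
        within 3 Monte-Carlo standard errors at 10,000 permutations."""
        rng = np.random.default_rng(11)
        N, K, n, k = 300, 60, 100, 28
        exact = float(hypergeom_tail_exact(k, N, K, n))
        draws = rng.hypergeometric(K, N - K, n, size=10_000)
        estimate = float(np.mean(draws >= k))
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(estimate - exact) <= 3 * se


class TestRankProfiles:
    def _result(self, name, p, fold):
        return EnrichmentResult(name, 100, 10, 100, 10, fold, p)

    def test_single_result(self):
        r = self._result("a", 0.5, 1.0)
        assert rank_profiles([r]) == [r]

    def test_tie_broken_by_fold(self):
        low = self._result("low", 0.01, 2.0)
        high = self._result("high", 0.01, 8.0)
        assert rank_profiles([low, high])[0] is high

    def test_permutation_invariance(self):
        results = [self._result(f"m{i}", p, f)
                   for i, (p, f) in enumerate([(0.5, 1), (0.01, 2), (0.01, 8), (0.2, 3)])]
        ranked = rank_profiles(results)
        assert rank_profiles(results[::-1]) == ranked


class TestMakeBackground:
    def test_n_zero_gives_empty_set(self):
        genome = {"chr1": simulate_genome(50_000, 0.5, 0)}
        target = PeakSet([GenomicInterval("chr1", 0, 200)], "t")
        assert len(make_background(target, genome, 0)) == 0

    def test_gc_matched_and_nonoverlapping(self):
        genome = {"chr1": simulate_genome(2_000_000, 0.5, 3)}
        target = PeakSet(
            [GenomicInterval("chr1", i * 2_000, i * 2_000 + 200) for i in range(200)],
            "t",
        )
        bg = make_background(target, genome, 1000, seed=9)
        assert len(bg) == 1000
        gc = np.mean([
            (genome["chr1"][iv.start:iv.end].count("G")
             + genome["chr1"][iv.start:iv.end].count("C")) / len(iv)
            for iv in bg
        ])
        assert abs(gc - 0.5) < 0.05
        spans = [(iv.start, iv.end) for iv in target]
        for iv in bg:
            assert not any(iv.start < e and s < iv.end for s, e in spans)

    def test_reproducible_from_seed(self):
        genome = {"chr1": simulate_genome(200_000, 0.5, 3)}
        target = PeakSet([GenomicInterval("chr1", i * 5_000, i * 5_000 + 150)
                          for i in range(20)], "t")
        a = make_background(target, genome, 50, seed=4)
        b = make_background(target, genome, 50, seed=4)
        assert [(iv.start, iv.end) for iv in a] == [(iv.start, iv.end) for iv in b]


class TestProximity:
    def _setup(self, partner_at):
        seq = list("A" * 400)
        seq[partner_at:partner_at + 7] = "TGTTTAC"
        genome = {"chr1": "".join(seq)}
        peaks = PeakSet([GenomicInterval("chr1", 0, 400, name="p")], "t")
        anchor = [MotifHit("chr1", 100, 106, "+", 0.0, "anchor", "p")]
        partner = build_profile(ConsensusMotif("fkh", "TGTTTAC"), 0)
        return anchor, partner, peaks, genome

    def test_edge_gap_within_window_counts(self):
        anchor, partner, peaks, genome = self._setup(120)  # gap 14
        res = proximity_coenrichment(anchor, partner, peaks, genome, 25)
        assert (res.n_anchors, res.n_cooccurrent) == (1, 1)

    def test_edge_gap_beyond_window_excluded(self):
        anchor, partner, peaks, genome = self._setup(140)  # gap 34
        res = proximity_coenrichment(anchor, partner, peaks, genome, 25)
        assert res.n_cooccurrent == 0

    def test_overlap_counts_as_distance_zero(self):
        anchor, partner, peaks, genome = self._setup(103)
        res = proximity_coenrichment(anchor, partner, peaks, genome, 0)
        assert res.n_cooccurrent == 1

    def test_no_partner_hits(self):
        anchor, partner, peaks, genome = self._setup(120)
        genome = {"chr1": "A" * 400}
        res = proximity_coenrichment(anchor, partner, peaks, genome, 25)
        assert res.n_cooccurrent == 0 and res.fraction == 0.0
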