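"""Interval merging, overlap classification, annotation and signal matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neocistrome import (
    Coverage,
    GeneModel,
    GenomicInterval,
    PeakSet,
    Transcript,
    annotate_peaks,
    classify_overlap,
    merge_peaks,
    signal_matrix,
)

intervals_strategy = st.lists(
    st.tuples(st.integers(0, 5_000), st.integers(1, 400)).map(
        lambda t: GenomicInterval("chr1", t[0], t[0] + t[1])
    ),
    min_size=0, max_size=30,
)


class TestMergePeaks:
    def test_gap_at_threshold_merges(self):
        peaks = PeakSet([GenomicInterval("chr1", 0, 100),
                         GenomicInterval("chr1", 400, 500)], "a")
        merged = merge_peaks(peaks, 500)
        assert [(iv.start, iv.end) for iv in merged] == [(0, 500)]

    def test_gap_one_past_threshold_keeps_separate(self):
        peaks = PeakSet([GenomicInterval("chr1", 0, 100),
                         GenomicInterval("chr1", 601, 700)], "a")
        assert len(merge_peaks(peaks, 500)) == 2

    def test_empty_input(self):
        assert len(merge_peaks(PeakSet([], "a"), 500)) == 0

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_peaks(PeakSet([], "a"), -1)

    @given(intervals_strategy, st.integers(0, 600))
    @settings(deadline=None, max_examples=60)
    def test_idempotent_order_invariant_and_separated(self, ivs, gap):
        peaks = PeakSet(ivs, "a")
        once = merge_peaks(peaks, gap)
        twice = merge_peaks(once, gap)
        spans = [(iv.start, iv.end) for iv in once]
        assert [(iv.start, iv.end) for iv in twice] == spans
        reversed_spans = [
            (iv.start, iv.end) for iv in merge_peaks(PeakSet(ivs[::-1], "a"), gap)
        ]
        assert reversed_spans == spans
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 - e1 > gap


class TestClassifyOverlap:
    def _peaks(self, spans, label):
        return PeakSet([GenomicInterval("chr1", s, e) for s, e in spans], label)

    def test_identical_sets_fully_shared(self):
        spans = [(i * 10_000, i * 10_000 + 500) for i in range(10)]
        venn = classify_overlap(self._peaks(spans, "a"), self._peaks(spans, "b"))
        assert venn.counts["shared_a"] == venn.counts["shared_b"] == 10
        assert venn.counts["a_only"] == venn.counts["b_only"] == 0

    def test_disjoint_sets(self):
        a = self._peaks([(0, 100), (10_000, 10_100)], "a")
        b = self._peaks([(50_000, 50_100)], "b")
        venn = classify_overlap(a, b)
        assert venn.counts["shared_a"] == venn.counts["shared_b"] == 0
        assert venn.counts["clusters_shared"] == 0

    def test_one_a_spanning_two_b(self):
        a = self._peaks([(0, 1000)], "a")
        b = self._peaks([(100, 200), (800, 900)], "b")
        venn = classify_overlap(a, b, merge_gap=100)
        assert venn.counts["shared_a"] == 1
        assert venn.counts["shared_b"] == 2

    @given(intervals_strategy, intervals_strategy)
    @settings(deadline=None, max_examples=60)
    def test_venn_conservation_and_transposition(self, ivs_a, ivs_b):
        a, b = PeakSet(ivs_a, "a"), PeakSet(ivs_b, "b")
        venn = classify_overlap(a, b, merge_gap=100)
        assert len(venn.a_only) + len(venn.shared_a) == len(merge_peaks(a, 100))
        assert len(venn.b_only) + len(venn.shared_b) == len(merge_peaks(b, 100))
        flipped = classify_overlap(b, a, merge_gap=100)
        assert flipped.counts["shared_a"] == venn.counts["shared_b"]
        assert flipped.counts["a_only"] == venn.counts["b_only"]


class TestAnnotatePeaks:
    @pytest.fixture
    def model(self):
        return GeneModel([
            Transcript("t1", "chr1", 10_000, 30_000, "+",
                       ((10_000, 12_000), (28_000, 30_000))),
        ])

    def test_promoter_within_1kb_of_tss(self, model):
        peaks = PeakSet([GenomicInterval("chr1", 9_300, 9_500)], "p")  # mid 600 bp upstream
        cats, _, _ = annotate_peaks(peaks, model, tss_window=1000)
        assert cats == ["promoter"]

    def test_intron_priority_over_intergenic(self, model):
        peaks = PeakSet([GenomicInterval("chr1", 19_900, 20_100)], "p")
        cats, _, _ = annotate_peaks(peaks, model, tss_window=1000)
        assert cats == ["intron"]

    def test_exon_beats_intron(self, model):
        peaks = PeakSet([GenomicInterval("chr1", 28_900, 29_100)], "p")
        cats, _, _ = annotate_peaks(peaks, model, tss_window=1000)
        assert cats == ["exon"]

    def test_unknown_sequence_is_intergenic_with_warning(self, model):
        peaks = PeakSet([GenomicInterval("chrX", 100, 300)], "p")
        cats, _, warnings = annotate_peaks(peaks, model, tss_window=1000)
        assert cats == ["intergenic"] and warnings == 1

    def test_fractions_partition(self, model):
        peaks = PeakSet([
            GenomicInterval("chr1", 9_300, 9_500),
            GenomicInterval("chr1", 19_900, 20_100),
            GenomicInterval("chr1", 50_000, 50_200),
            GenomicInterval("chr1", 28_900, 29_100),
        ], "p")
        _, fractions, _ = annotate_peaks(peaks, model, tss_window=1000)
        assert sum(fractions.values()) == pytest.approx(1.0)
        assert fractions["promoter"] == fractions["exon"] == 0.25


class TestSignalMatrix:
    def test_constant_coverage_fills_every_cell(self):
        cov = Coverage(pd.DataFrame([dict(chrom="chr1", start=0, end=100_000, value=1.0)]))
        peaks = PeakSet([GenomicInterval("chr1", 10_000, 11_000),
                         GenomicInterval("chr1", 50_000, 51_000)], "p")
        mat, offsets, _ = signal_matrix(peaks, cov, flank=1500, bin_size=50)
        assert mat.shape == (2, 60)
        assert np.allclose(mat, 1.0)

    def test_zero_coverage_all_zero(self):
        cov = Coverage(pd.DataFrame(columns=["chrom", "start", "end", "value"]))
        peaks = PeakSet([GenomicInterval("chr1", 10_000, 11_000)], "p")
        mat, _, _ = signal_matrix(peaks, cov, flank=1500, bin_size=50)
        assert np.all(mat == 0)

    def test_single_bin_signal_lands_in_one_column(self):
        # midpoint 1500; coverage only on the bin [1500, 1550)
        cov = Coverage(pd.DataFrame([dict(chrom="chr1", start=1500, end=1550, value=10.0)]))
        peaks = PeakSet([GenomicInterval("chr1", 1000, 2000)], "p")
        mat, offsets, _ = signal_matrix(peaks, cov, flank=1500, bin_size=50)
        nonzero = np.flatnonzero(mat[0])
        assert list(nonzero) == [30]  # the bin starting at offset 0
        assert mat[0, 30] == pytest.approx(10.0)

    def test_rows_sorted_by_descending_sum(self):
        cov = Coverage(pd.DataFrame([
            dict(chrom="chr1", start=0, end=5_000, value=1.0),
            dict(chrom="chr1", start=50_000, end=55_000, value=7.0),
        ]))
        peaks = PeakSet([GenomicInterval("chr1", 2_000, 3_000),
                         GenomicInterval("chr1", 52_000, 53_000)], "p")
        mat, _, order = signal_matrix(peaks, cov, flank=500, bin_size=50)
        assert list(order) == [1, 0]
        assert mat[0].sum() > mat[1].sum()

    def test_invalid_bin_rejected(self):
        cov = Coverage(pd.DataFrame(columns=["chrom", "start", "end", "value"]))
        peaks = PeakSet([GenomicInterval("chr1", 0, 100)], "p")
        with pytest.raises(ValueError):
            signal_matrix(peaks, cov, flank=1500, bin_size=0)
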