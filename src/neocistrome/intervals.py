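"""Cistrome interval arithmetic: merging, overlap classification, annotation
and reference-point signal matrices.

All coordinates are 0-based half-open (BED convention).  "Within G bp"
means edge-to-edge gap <= G, so touching or overlapping intervals have
gap 0 and a gap of G+1 keeps two peaks separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "OverlapClassification",
    "GeneModel",
    "Transcript",
    "merge_peaks",
    "classify_overlap",
    "annotate_peaks",
    "signal_matrix",
    "coverage_integrals",
]


@dataclass(frozen=True)
class GenomicInterval:
    sequence_id: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.sequence_id}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.sequence_id == other.sequence_id
                and self.start < other.end and other.start < self.end)

    def gap_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge distance; 0 when overlapping or touching."""
        if self.sequence_id != other.sequence_id:
            raise ValueError("intervals on different sequences")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


class PeakSet:
    """An ordered collection of genomic intervals with a label."""

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = ""):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.label = label

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def sorted(self) -> "PeakSet":
        return PeakSet(
            sorted(self.intervals, key=lambda iv: (iv.sequence_id, iv.start, iv.end)),
            self.label,
        )

    def widths(self) -> np.ndarray:
        return np.array([len(iv) for iv in self.intervals], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.sequence_id for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name or "." for iv in self.intervals],
                "score": [0 if iv.score is None else iv.score for iv in self.intervals],
            }
        )


def merge_peaks(peaks: PeakSet, gap: int = 500) -> PeakSet:
    """Union peaks whose edge gap is <= ``gap`` into single spans.

    Mirrors the reduction of nearby ChIP peaks to one representative
    site before overlap analysis.  Idempotent; output sorted with all
    pairwise gaps > ``gap``.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if len(peaks) == 0:
        return PeakSet([], peaks.label)
    merged: list[GenomicInterval] = []
    n_constituents: list[int] = []
    for iv in peaks.sorted():
        if merged and iv.sequence_id == merged[-1].sequence_id \
                and iv.start - merged[-1].end <= gap:
            last = merged[-1]
            merged[-1] = GenomicInterval(
                last.sequence_id, last.start, max(last.end, iv.end), last.name
            )
            n_constituents[-1] += 1
        else:
            merged.append(iv)
            n_constituents.append(1)
    out = [
        GenomicInterval(iv.sequence_id, iv.start, iv.end,
                        name=f"{peaks.label or 'peak'}_{i}", score=n)
        for i, (iv, n) in enumerate(zip(merged, n_constituents))
    ]
    return PeakSet(out, peaks.label)


@dataclass
class OverlapClassification:
    """Cross-cistrome Venn classification after per-set merging.

    Counts are per merged peak in each set (an A-peak spanning several
    B-peaks contributes once to ``shared_a`` but each of those B-peaks
    counts in ``shared_b``); ``n_clusters_shared`` additionally reports
    connected overlap clusters containing peaks from both sets.
    """

    a_only: PeakSet
    b_only: PeakSet
    shared_a: PeakSet
    shared_b: PeakSet
    n_clusters_shared: int

    @property
    def counts(self) -> dict[str, int]:
        return {
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
            "shared_a": len(self.shared_a),
            "shared_b": len(self.shared_b),
            "clusters_shared": self.n_clusters_shared,
        }


def _overlap_counts(query: PeakSet, subject: PeakSet) -> np.ndarray:
    """Number of subject intervals overlapping (>=1 bp) each query interval.

    Subject must be sorted and disjoint per sequence (true after merging).
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv.sequence_id for iv in subject}:
        ivs = [iv for iv in subject if iv.sequence_id == chrom]
        by_chrom[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    counts = np.zeros(len(query), dtype=int)
    for qi, iv in enumerate(query):
        if iv.sequence_id not in by_chrom:
            continue
        starts, ends = by_chrom[iv.sequence_id]
        lo = np.searchsorted(ends, iv.start, side="right")
        hi = np.searchsorted(starts, iv.end, side="left")
        counts[qi] = max(0, hi - lo)
    return counts


def classify_overlap(a: PeakSet, b: PeakSet, merge_gap: int = 500) -> OverlapClassification:
    """Venn-style WT/KO style comparison of two cistromes.

    Both sets are merged at ``merge_gap`` first; a merged peak is shared
    iff it overlaps a merged peak of the other set by >= 1 bp.
    """
    am, bm = merge_peaks(a, merge_gap), merge_peaks(b, merge_gap)
    a_hits = _overlap_counts(am, bm)
    b_hits = _overlap_counts(bm, am)
    a_only = PeakSet([iv for iv, c in zip(am, a_hits) if c == 0], f"{a.label}_only")
    shared_a = PeakSet([iv for iv, c in zip(am, a_hits) if c > 0], f"{a.label}_shared")
    b_only = PeakSet([iv for iv, c in zip(bm, b_hits) if c == 0], f"{b.label}_only")
    shared_b = PeakSet([iv for iv, c in zip(bm, b_hits) if c > 0], f"{b.label}_shared")

    # Connected overlap clusters containing peaks from both sets.
    tagged = sorted(
        [(iv.sequence_id, iv.start, iv.end, 0) for iv in am]
        + [(iv.sequence_id, iv.start, iv.end, 1) for iv in bm]
    )
    n_clusters = 0
    cur_chrom, cur_end, members = None, -1, set()
    for chrom, start, end, tag in tagged:
        if chrom != cur_chrom or start >= cur_end:
            if members == {0, 1}:
                n_clusters += 1
            cur_chrom, cur_end, members = chrom, end, {tag}
        else:
            cur_end = max(cur_end, end)
            members.add(tag)
    if members == {0, 1}:
        n_clusters += 1
    return OverlapClassification(a_only, b_only, shared_a, shared_b, n_clusters)


@dataclass(frozen=True)
class Transcript:
    name: str
    sequence_id: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def tss(self) -> int:
        return self.start if self.strand != "-" else self.end - 1


@dataclass
class GeneModel:
    transcripts: list[Transcript]

    def by_chrom(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            out.setdefault(t.sequence_id, []).append(t)
        return out


def annotate_peaks(peaks: PeakSet, gene_model: GeneModel,
                   tss_window: int = 1000):
    """Classify each peak midpoint as promoter > exon > intron > intergenic.

    Promoter means the midpoint lies within +/- ``tss_window`` of a TSS
    (the +/-1 kb convention for distance-to-gene classification).
    Returns (categories per peak, fraction per category, n_unknown_chrom).
    """
    by_chrom = gene_model.by_chrom()
    categories: list[str] = []
    warnings = 0
    known_chroms = set(by_chrom)
    for iv in peaks:
        mid = iv.midpoint
        if iv.sequence_id not in known_chroms:
            warnings += 1
            categories.append("intergenic")
            continue
        cat = "intergenic"
        for t in by_chrom[iv.sequence_id]:
            if abs(mid - t.tss) <= tss_window:
                cat = "promoter"
                break
            if t.start <= mid < t.end:
                in_exon = any(s <= mid < e for s, e in t.exons)
                nxt = "exon" if in_exon else "intron"
                if cat == "intergenic" or (cat == "intron" and nxt == "exon"):
                    cat = nxt
        categories.append(cat)
    n = max(len(categories), 1)
    fractions = {
        c: categories.count(c) / n
        for c in ("promoter", "exon", "intron", "intergenic")
    }
    return categories, fractions, warnings


# ---------------------------------------------------------------------------
# bedGraph coverage

class Coverage:
    """Sorted non-overlapping bedGraph intervals with prefix integrals."""

    def __init__(self, frame: pd.DataFrame):
        """``frame`` needs columns chrom, start, end, value."""
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in frame.groupby("chrom", sort=True):
            g = grp.sort_values("start")
            starts = g["start"].to_numpy(dtype=float)
            ends = g["end"].to_numpy(dtype=float)
            vals = g["value"].to_numpy(dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping bedGraph intervals on {chrom}")
            cum = np.concatenate([[0.0], np.cumsum(vals * (ends - starts))])
            self._chroms[str(chrom)] = (starts, ends, vals, cum)

    def integral_upto(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of coverage over (-inf, x); missing coverage is 0."""
        x = np.asarray(x, dtype=float)
        if chrom not in self._chroms:
            return np.zeros_like(x)
        starts, ends, vals, cum = self._chroms[chrom]
        idx = np.searchsorted(ends, x, side="left")
        idx_c = np.minimum(idx, len(vals) - 1)
        partial = vals[idx_c] * np.clip(x - starts[idx_c], 0.0, ends[idx_c] - starts[idx_c])
        partial[idx >= len(vals)] = 0.0
        return cum[np.minimum(idx, len(vals))] + partial

    def integral(self, chrom: str, start: float, end: float) -> float:
        a, b = self.integral_upto(chrom, np.array([start, end]))
        return float(b - a)


def coverage_integrals(peaks: PeakSet, coverage: Coverage) -> np.ndarray:
    """Total coverage (tag-count surrogate) over each peak."""
    return np.array([coverage.integral(iv.sequence_id, iv.start, iv.end)
                     for iv in peaks])


def signal_matrix(peaks: PeakSet, coverage: Coverage, flank: int = 1500,
                  bin_size: int = 50, sort_rows: bool = True):
    """Mean coverage in fixed bins around each peak midpoint.

    The reference point is the peak midpoint; the window spans
    +/- ``flank`` (the +/-1.5 kb / +/-2.5 kb heatmap conventions), in
    bins of ``bin_size``.  Rows are sorted by descending row sum unless
    ``sort_rows`` is false.  Returns (matrix, bin offsets, row order).
    """
    if bin_size <= 0:
        raise ValueError("bin size must be > 0")
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin size")
    n_bins = 2 * flank // bin_size
    offsets = np.arange(-flank, flank, bin_size)
    mat = np.zeros((len(peaks), n_bins))
    for i, iv in enumerate(peaks):
        edges = iv.midpoint + np.arange(-flank, flank + bin_size, bin_size, dtype=float)
        integrals = coverage.integral_upto(iv.sequence_id, edges)
        mat[i] = np.diff(integrals) / bin_size
    order = np.arange(len(peaks))
    if sort_rows and len(peaks):
        order = np.argsort(-mat.sum(axis=1), kind="stable")
        mat = mat[order]
    return mat, offsets, order
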