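"""ROSE-style super-enhancer calling.

Peaks are stitched into enhancer domains, ranked by aggregate signal, and
the rank-signal curve is normalized to the unit square (x = rank/n,
y = signal/max).  Scanning from the low-signal end, the first point where
the tangent slope of the normalized curve reaches the slope threshold
(default 1, the diagonal-tangent convention) defines the cutoff; every
domain strictly above it is a super-enhancer.  Calls are invariant to
positive rescaling of the signal track, and a degenerate linear curve
(constant slope) calls none, since no inflection exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .intervals import Coverage, GenomicInterval, PeakSet, coverage_integrals, merge_peaks

__all__ = [
    "StitchedEnhancer",
    "DEFAULT_STITCH_DISTANCE",
    "stitch_peaks",
    "rank_and_call",
    "compare_super_sets",
    "curve_slopes",
    "super_enhancer_frame",
]

#: ROSE's conventional stitching window.
DEFAULT_STITCH_DISTANCE = 12_500


@dataclass(frozen=True)
class StitchedEnhancer:
    interval: GenomicInterval
    n_constituents: int
    signal: float = 0.0
    rank: int = 0            # 1-based from lowest signal
    norm_x: float = 0.0
    norm_y: float = 0.0
    slope_at: float = 0.0
    is_super: bool = False


def stitch_peaks(peaks: PeakSet,
                 stitch_distance: int = DEFAULT_STITCH_DISTANCE) -> list[StitchedEnhancer]:
    """Union peaks with edge gap <= ``stitch_distance`` into domains."""
    if stitch_distance < 0:
        raise ValueError("stitch_distance must be >= 0")
    merged = merge_peaks(peaks, gap=stitch_distance)
    return [
        StitchedEnhancer(interval=iv, n_constituents=int(iv.score or 1))
        for iv in merged
    ]


def curve_slopes(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Tangent slopes of the normalized curve: central differences inside,
    one-sided at the ends."""
    n = len(y)
    if n == 1:
        return np.zeros(1)
    slopes = np.empty(n)
    slopes[0] = (y[1] - y[0]) / (x[1] - x[0])
    slopes[-1] = (y[-1] - y[-2]) / (x[-1] - x[-2])
    if n > 2:
        slopes[1:-1] = (y[2:] - y[:-2]) / (x[2:] - x[:-2])
    return slopes


def rank_and_call(stitched: list[StitchedEnhancer], track: Coverage,
                  slope_threshold: float = 1.0) -> list[StitchedEnhancer]:
    """Rank stitched domains by aggregate signal and flag super-enhancers.

    Signal is the summed coverage over each domain (a tag-count
    surrogate).  Domains are sorted ascending; on the normalized curve
    the cutoff is the first rank whose slope reaches ``slope_threshold``
    and every domain strictly above that rank is called.
    """
    if not stitched:
        raise ValueError("no stitched domains")
    peaks = PeakSet([d.interval for d in stitched])
    signal = coverage_integrals(peaks, track)
    order = np.argsort(signal, kind="stable")
    n = len(stitched)
    x = (np.arange(n) + 1) / n
    max_signal = signal[order[-1]]
    if max_signal <= 0:
        warnings.warn("all-zero signal track: no super-enhancers called")
        y = np.zeros(n)
    else:
        y = signal[order] / max_signal
    slopes = curve_slopes(y, x)

    is_super = np.zeros(n, dtype=bool)
    if max_signal > 0 and not np.allclose(slopes, slopes[0]):
        above = np.flatnonzero(slopes >= slope_threshold)
        if above.size:
            is_super[above[0] + 1:] = True

    out = []
    for pos, idx in enumerate(order):
        out.append(replace(
            stitched[idx],
            signal=float(signal[idx]),
            rank=pos + 1,
            norm_x=float(x[pos]),
            norm_y=float(y[pos]),
            slope_at=float(slopes[pos]),
            is_super=bool(is_super[pos]),
        ))
    return out


def compare_super_sets(se_a: list[StitchedEnhancer], se_b: list[StitchedEnhancer],
                       top_n: int = 100) -> dict:
    """Lost / retained / gained super-enhancer fractions between two calls.

    An A super-enhancer is retained iff its domain overlaps a B
    super-enhancer by >= 1 bp, else lost; gained is symmetric.  Also
    pairs the top ``top_n`` A domains (by signal) with the best-signal
    overlapping B domain for score-shift summaries (NaN when lost).
    """
    supers_a = [d for d in se_a if d.is_super]
    supers_b = [d for d in se_b if d.is_super]

    def _overlapping(d: StitchedEnhancer, others: list[StitchedEnhancer]):
        return [o for o in others if d.interval.overlaps(o.interval)]

    retained = sum(1 for d in supers_a if _overlapping(d, supers_b))
    gained = sum(1 for d in supers_b if not _overlapping(d, supers_a))

    top_a = sorted(se_a, key=lambda d: -d.signal)[:top_n]
    pairs = []
    for d in top_a:
        matches = _overlapping(d, se_b)
        b_signal = max((m.signal for m in matches), default=float("nan"))
        pairs.append((d.signal, b_signal))

    n_a, n_b = len(supers_a), len(supers_b)
    return {
        "n_super_a": n_a,
        "n_super_b": n_b,
        "n_retained": retained,
        "n_lost": n_a - retained,
        "n_gained": gained,
        "lost_fraction": (n_a - retained) / n_a if n_a else 0.0,
        "gained_fraction": gained / n_b if n_b else 0.0,
        "paired_scores": pairs,
    }


def super_enhancer_frame(called: list[StitchedEnhancer]) -> pd.DataFrame:
    """Tabular view (one row per domain, ascending rank) for TSV export."""
    rows = sorted(called, key=lambda d: d.rank)
    return pd.DataFrame({
        "chrom": [d.interval.sequence_id for d in rows],
        "start": [d.interval.start for d in rows],
        "end": [d.interval.end for d in rows],
        "n_constituents": [d.n_constituents for d in rows],
        "signal": [d.signal for d in rows],
        "rank": [d.rank for d in rows],
        "norm_x": [d.norm_x for d in rows],
        "norm_y": [d.norm_y for d in rows],
        "slope": [d.slope_at for d in rows],
        "is_super": [d.is_super for d in rows],
    })
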