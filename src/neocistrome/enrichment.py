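"""Known-motif enrichment in a target cistrome versus a matched background.

A peak is motif-positive when it contains at least one accepted scan
window; enrichment is tested with the upper hypergeometric tail over the
pooled target+background population (the standard known-motif test), and
partner-motif co-occurrence is assessed with an edge-to-edge distance
window around anchor hits (the "within 25 bp of AR half elements" style
of analysis).

Multiple-testing correction across a motif library is deliberately not
applied here; p-values are reported raw.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .intervals import GenomicInterval, PeakSet
from .motifs import MotifHit, MotifProfile, scan

__all__ = [
    "EnrichmentResult",
    "ProximityResult",
    "make_background",
    "motif_enrichment",
    "rank_profiles",
    "proximity_coenrichment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    profile_name: str
    n_target: int
    n_target_with: int
    n_background: int
    n_background_with: int
    fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_target_with <= self.n_target):
            raise ValueError("target counts inconsistent")
        if not (0 <= self.n_background_with <= self.n_background):
            raise ValueError("background counts inconsistent")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


@dataclass(frozen=True)
class ProximityResult:
    anchor_profile: str
    partner_profile: str
    window: int
    n_anchors: int
    n_cooccurrent: int

    @property
    def fraction(self) -> float:
        return self.n_cooccurrent / self.n_anchors if self.n_anchors else 0.0


def _gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    gc = seq.count("G") + seq.count("C")
    return gc / len(seq)


def make_background(target: PeakSet, genome: dict[str, str], n: int,
                    gc_bins: int = 10, seed: int = 0,
                    max_attempts_per_peak: int = 500) -> PeakSet:
    """Sample ``n`` background intervals matched to the target peaks.

    Widths are drawn with replacement from the target width distribution;
    GC content is matched bin-by-bin to the target GC histogram; no
    sampled interval overlaps a target peak or another background
    interval.  Fully reproducible from ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return PeakSet([], "background")
    if len(target) == 0:
        raise ValueError("target peak set is empty")
    rng = np.random.default_rng(seed)

    widths = target.widths()
    target_gc = np.array([
        _gc_fraction(genome[iv.sequence_id][iv.start:iv.end]) for iv in target
    ])
    bin_edges = np.linspace(0.0, 1.0, gc_bins + 1)
    target_bins = np.clip(np.digitize(target_gc, bin_edges) - 1, 0, gc_bins - 1)
    # Per-bin quotas proportional to the target histogram.
    quota = np.zeros(gc_bins, dtype=int)
    frac = np.bincount(target_bins, minlength=gc_bins) / len(target)
    quota[:] = np.floor(frac * n).astype(int)
    shortfall = n - quota.sum()
    order = np.argsort(-frac, kind="stable")
    for i in range(shortfall):
        quota[order[i % gc_bins]] += 1

    chrom_names = sorted(genome)
    chrom_lens = np.array([len(genome[c]) for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()

    # Sorted disjoint occupied spans per chromosome (targets merged first).
    occupied: dict[str, tuple[list[int], list[int]]] = {c: ([], []) for c in chrom_names}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in target:
        by_chrom.setdefault(iv.sequence_id, []).append((iv.start, iv.end))
    for chrom, spans in by_chrom.items():
        starts, ends = occupied.setdefault(chrom, ([], []))
        for s, e in sorted(spans):
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)

    def _clashes(chrom: str, start: int, end: int) -> bool:
        starts, ends = occupied.get(chrom, ([], []))
        i = bisect.bisect_right(starts, start)
        if i > 0 and ends[i - 1] > start:
            return True
        return i < len(starts) and starts[i] < end

    def _occupy(chrom: str, start: int, end: int) -> None:
        starts, ends = occupied[chrom]
        i = bisect.bisect_right(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)

    placed: list[GenomicInterval] = []
    filled = np.zeros(gc_bins, dtype=int)
    attempts = 0
    budget = max_attempts_per_peak * n
    while len(placed) < n and attempts < budget:
        attempts += 1
        width = int(rng.choice(widths))
        chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_p)]
        limit = len(genome[chrom]) - width
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit + 1))
        end = start + width
        if _clashes(chrom, start, end):
            continue
        gc = _gc_fraction(genome[chrom][start:end])
        b = min(gc_bins - 1, max(0, int(np.digitize(gc, bin_edges)) - 1))
        if filled[b] >= quota[b]:
            continue
        _occupy(chrom, start, end)
        placed.append(GenomicInterval(chrom, start, end, name=f"bg_{len(placed)}"))
        filled[b] += 1
    if len(placed) < n:
        raise RuntimeError(
            f"background placement infeasible: placed {len(placed)} of {n} "
            f"intervals after {attempts} attempts"
        )
    return PeakSet(placed, "background")


def _peaks_with_hit(profile: MotifProfile, peaks: PeakSet,
                    genome: dict[str, str]) -> int:
    hits = scan(profile, genome, both_strands=True, peaks=peaks)
    return len({h.peak_name for h in hits})


def motif_enrichment(profile: MotifProfile, target: PeakSet, background: PeakSet,
                     genome: dict[str, str]) -> EnrichmentResult:
    """Per-peak presence/absence enrichment with a hypergeometric tail.

    fold = (t_with/t) / ((b_with + c)/(b + c)) with pseudocount c = 1
    applied only when no background peak is positive; p is the upper
    cumulative tail of drawing >= t_with positive peaks in t draws from
    the pooled population of t + b peaks of which t_with + b_with are
    positive.
    """
    if len(target) == 0 or len(background) == 0:
        raise ValueError("target and background must be non-empty")
    t, b = len(target), len(background)
    t_with = _peaks_with_hit(profile, target, genome)
    b_with = _peaks_with_hit(profile, background, genome)
    if b_with == 0:
        fold = (t_with / t) / (1.0 / (b + 1))
    else:
        fold = (t_with / t) / (b_with / b)
    p = float(hypergeom.sf(t_with - 1, t + b, t_with + b_with, t))
    return EnrichmentResult(profile.name, t, t_with, b, b_with, fold, p)


def rank_profiles(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Ascending p, ties by descending fold then name; deterministic."""
    if not results:
        raise ValueError("no results to rank")
    return sorted(results, key=lambda r: (r.p_value, -r.fold_change, r.profile_name))


def _edge_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge gap; overlap counts as distance 0."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def proximity_coenrichment(anchor_hits: list[MotifHit], partner_profile: MotifProfile,
                           peaks: PeakSet, genome: dict[str, str],
                           window: int = 25) -> ProximityResult:
    """Fraction of anchor hits with a partner hit within ``window`` bp.

    Distances are nearest-edge to nearest-edge, so unequal motif lengths
    are handled symmetrically and overlap counts as 0.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    partner_hits = scan(partner_profile, genome, both_strands=True, peaks=peaks)
    by_seq: dict[str, list[MotifHit]] = {}
    for h in partner_hits:
        by_seq.setdefault(h.sequence_id, []).append(h)
    n_co = 0
    for a in anchor_hits:
        for p in by_seq.get(a.sequence_id, []):
            if _edge_distance(a.start, a.end, p.start, p.end) <= window:
                n_co += 1
                break
    anchor_name = anchor_hits[0].profile_name if anchor_hits else ""
    return ProximityResult(anchor_name, partner_profile.name, window,
                           len(anchor_hits), n_co)
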