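"""Seeded synthetic-data generators with explicit ground truth.

These emulate the statistical structure the analysis modules assume —
peak sets with planted composite-motif instances at a controlled
frequency, signal tracks with clustered high-signal enhancer domains
whose rank curve has the characteristic hockey-stick shape, and
negative-binomial screen count tables with planted coactivator or
repressor genes — so the whole pipeline is testable without any
sequencing data.  Every generator is bit-reproducible from its
parameters and seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet
from .motifs import IUPAC_CODES, ConsensusMotif
from .screen import ScreenCountTable

__all__ = [
    "simulate_genome",
    "plant_peakset",
    "simulate_signal_track",
    "knockout_track",
    "simulate_screen_counts",
]

_BASES = np.array(list("ACGT"))


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random sequence with P(G) + P(C) = ``gc``."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    return codes[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")


def _place_nonoverlapping(rng: np.random.Generator, chrom_len: int, widths,
                          min_gap: int, max_attempts_factor: int = 200) -> list[tuple[int, int]]:
    """Random non-overlapping placements with pairwise edge gaps > min_gap."""
    starts: list[int] = []
    ends: list[int] = []
    placed: list[tuple[int, int]] = []
    budget = max_attempts_factor * len(widths)
    attempts = 0
    for w in widths:
        while True:
            attempts += 1
            if attempts > budget:
                raise RuntimeError(
                    f"placement infeasible: placed {len(placed)} of "
                    f"{len(widths)} intervals in a {chrom_len}-bp sequence"
                )
            s = int(rng.integers(0, chrom_len - w + 1))
            e = s + w
            i = bisect.bisect_right(starts, s)
            ok = (i == 0 or ends[i - 1] + min_gap < s) and \
                 (i == len(starts) or e + min_gap < starts[i])
            if ok:
                starts.insert(i, s)
                ends.insert(i, e)
                placed.append((s, e))
                break
    return placed


def _resolve_iupac(rng: np.random.Generator, consensus: str) -> str:
    """One concrete instance; degenerate codes resolved uniformly."""
    return "".join(
        IUPAC_CODES[c][rng.integers(0, len(IUPAC_CODES[c]))] for c in consensus
    )


def plant_peakset(genome: str, n: int, width: int, motif: ConsensusMotif,
                  fraction: float, seed: int = 0, chrom: str = "chr1",
                  min_gap: int = 600, mutation_rate: float = 0.0,
                  label: str = "peaks"):
    """Place ``n`` peaks and plant one motif instance in round(f*n) of them.

    The planted instance is an exact consensus realisation (degenerate
    codes drawn uniformly) written into the sequence at a uniform offset
    within the peak; ``mutation_rate`` optionally mutates each planted
    base independently.  Returns (modified sequence, PeakSet, truth
    table) where the truth table records, per peak, whether and where an
    instance was planted.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if width < len(motif):
        raise ValueError("peak width smaller than motif length")
    rng = np.random.default_rng(seed)
    placements = _place_nonoverlapping(rng, len(genome), [width] * n, min_gap)
    placements.sort()

    n_planted = round(fraction * n)
    planted_idx = set(rng.permutation(n)[:n_planted].tolist())

    seq = list(genome)
    records = []
    intervals = []
    L = len(motif)
    for i, (s, e) in enumerate(placements):
        name = f"{label}_{i}"
        intervals.append(GenomicInterval(chrom, s, e, name=name))
        planted = i in planted_idx
        offset, instance = -1, ""
        if planted:
            offset = int(rng.integers(0, width - L + 1))
            instance = _resolve_iupac(rng, motif.iupac)
            if mutation_rate > 0:
                chars = list(instance)
                for j in range(L):
                    if rng.random() < mutation_rate:
                        chars[j] = str(rng.choice(_BASES))
                instance = "".join(chars)
            seq[s + offset:s + offset + L] = instance
        records.append(dict(peak=name, chrom=chrom, start=s, end=e,
                            planted=planted, motif=motif.name,
                            offset=offset, instance=instance))
    truth = pd.DataFrame(records)
    return "".join(seq), PeakSet(intervals, label), truth


def simulate_signal_track(chrom_len: int, n_typical: int = 90,
                          n_super_clusters: int = 10, cluster_span: int = 20_000,
                          amplification: float = 20.0, seed: int = 0,
                          chrom: str = "chr1", enhancer_width: int = 1_000,
                          constituents_per_cluster: int = 4,
                          base_level: float = 1.0, noise_sigma: float = 0.25,
                          min_gap: int = 13_500):
    """Signal track with typical enhancers plus amplified clusters.

    Typical enhancers get base-level coverage with lognormal variation;
    super cluster j (j = 0..K-1) gets amplification x (1 + j/4) x base
    total coverage spread equally over closely spaced constituents within
    ``cluster_span``.  The graded ladder keeps the sorted rank curve
    strictly increasing at the top, emulating the heavy upper tail of
    real enhancer rank curves.  Domains are separated by more than
    ``min_gap`` so stitching at the default distance recovers exactly
    the planted domains.

    Returns (constituent PeakSet, bedGraph DataFrame with a domain_id
    column, truth table with one row per planted domain).
    """
    if amplification <= 1:
        raise ValueError("amplification must be > 1")
    if n_typical < 0 or n_super_clusters < 0 or n_typical + n_super_clusters == 0:
        raise ValueError("need at least one domain")
    c = constituents_per_cluster
    if c < 1 or (c > 1 and cluster_span < c * enhancer_width):
        raise ValueError("cluster_span too small for its constituents")
    rng = np.random.default_rng(seed)

    n_domains = n_typical + n_super_clusters
    domain_types = np.array(["typical"] * n_typical + ["super"] * n_super_clusters)
    rng.shuffle(domain_types)
    widths = [enhancer_width if t == "typical" else cluster_span for t in domain_types]
    placements = _place_nonoverlapping(rng, chrom_len, widths, min_gap)
    # keep each type attached to its placement, then order along the sequence
    paired = sorted(zip([s for s, _ in placements], domain_types))

    gap_in_cluster = 0 if c == 1 else (cluster_span - c * enhancer_width) // (c - 1)
    rows, truth_rows, intervals = [], [], []
    cluster_id = 0
    for d, ((start, dtype)) in enumerate(paired):
        domain_id = f"domain_{d}"
        if dtype == "typical":
            end = start + enhancer_width
            value = base_level * rng.lognormal(mean=0.0, sigma=noise_sigma)
            rows.append(dict(chrom=chrom, start=start, end=end,
                             value=value, domain_id=domain_id))
            intervals.append(GenomicInterval(chrom, start, end, name=domain_id))
            expected = value * enhancer_width
            truth_rows.append(dict(domain=domain_id, type="typical",
                                   cluster_id=-1, chrom=chrom, start=start,
                                   end=end, expected_signal=expected))
        else:
            grade = 1.0 + 0.25 * cluster_id
            total = amplification * grade * base_level * enhancer_width
            per_constituent_value = total / (c * enhancer_width)
            end = start
            for k in range(c):
                cs = start + k * (enhancer_width + gap_in_cluster)
                ce = cs + enhancer_width
                end = ce
                rows.append(dict(chrom=chrom, start=cs, end=ce,
                                 value=per_constituent_value,
                                 domain_id=domain_id))
                intervals.append(GenomicInterval(chrom, cs, ce,
                                                 name=f"{domain_id}_c{k}"))
            truth_rows.append(dict(domain=domain_id, type="super",
                                   cluster_id=cluster_id, chrom=chrom,
                                   start=start, end=end,
                                   expected_signal=total))
            cluster_id += 1
    frame = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return PeakSet(intervals, "enhancers"), frame, truth


def knockout_track(frame: pd.DataFrame, truth: pd.DataFrame,
                   lost_fraction: float = 0.75, seed: int = 0,
                   residual_level: float | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Delete the amplified signal from a fraction of planted clusters.

    Selected clusters keep their constituent intervals but drop to
    ``residual_level`` coverage.  The default (base level divided by the
    cluster's constituent count) returns a deleted cluster's total
    signal to that of a single typical enhancer, emulating complete
    off-loading of the amplified binding while ordinary background
    coverage remains.  Returns the modified bedGraph frame and a truth
    table with a ``lost`` column.
    """
    if not 0.0 <= lost_fraction <= 1.0:
        raise ValueError("lost_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    clusters = truth.loc[truth["type"] == "super", "domain"].to_numpy()
    n_lost = round(lost_fraction * len(clusters))
    lost = set(rng.permutation(clusters)[:n_lost].tolist())
    if residual_level is None:
        constituents = frame.groupby("domain_id").size()
        per_cluster = {d: 1.0 / constituents[d] for d in lost}
    else:
        per_cluster = {d: residual_level for d in lost}
    out = frame.copy()
    mask = out["domain_id"].isin(lost)
    out.loc[mask, "value"] = out.loc[mask, "domain_id"].map(per_cluster)
    ko_truth = truth.copy()
    ko_truth["lost"] = ko_truth["domain"].isin(lost)
    return out, ko_truth


def simulate_screen_counts(n_genes: int = 100, guides_per_gene: int = 4,
                           effects: dict[str, float] | None = None,
                           mean_count: float = 500.0, dispersion: float = 0.1,
                           seed: int = 0):
    """Negative-binomial screen counts with per-gene planted log2 effects.

    HIGH-gate counts are NB(mu, alpha) with variance mu + alpha*mu^2;
    LOW-gate counts are NB(mu * 2**delta, alpha) where delta is the
    gene's planted effect (0 for neutral genes).  alpha = 0 degenerates
    to Poisson.  Returns (ScreenCountTable, truth table of deltas).
    """
    if mean_count <= 0:
        raise ValueError("mean_count must be > 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    effects = effects or {}
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    unknown = set(effects) - set(genes)
    if unknown:
        raise ValueError(f"effects refer to unknown genes: {sorted(unknown)}")

    def _nb(mu: float, size: int) -> np.ndarray:
        if dispersion == 0:
            return rng.poisson(mu, size)
        n = 1.0 / dispersion
        return rng.negative_binomial(n, n / (n + mu), size)

    rows = []
    for gene in genes:
        delta = float(effects.get(gene, 0.0))
        high = _nb(mean_count, guides_per_gene)
        low = _nb(mean_count * 2.0 ** delta, guides_per_gene)
        for g in range(guides_per_gene):
            rows.append(dict(guide_id=f"{gene}_g{g}", gene=gene,
                             count_low=int(low[g]), count_high=int(high[g])))
    table = ScreenCountTable(pd.DataFrame(rows))
    truth = pd.DataFrame({
        "gene": genes,
        "delta": [float(effects.get(g, 0.0)) for g in genes],
    })
    return table, truth
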