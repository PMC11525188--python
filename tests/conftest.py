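"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from neocistrome import (
    ConsensusMotif,
    Coverage,
    GenomicInterval,
    PeakSet,
)


def hypergeom_tail_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n) by direct summation."""
    denom = comb(N, n)
    total = sum(comb(K, i) * comb(N - K, n - i)
                for i in range(max(k, 0), min(K, n) + 1))
    return Fraction(total, denom)


def hamming_ball_size(length: int, k: int, alphabet: int = 4) -> int:
    """Number of sequences within Hamming distance k of a fixed L-mer."""
    return sum(comb(length, j) * (alphabet - 1) ** j for j in range(k + 1))


@pytest.fixture
def half_site() -> ConsensusMotif:
    return ConsensusMotif("AR_half", "AGAACA")


@pytest.fixture
def forkhead() -> ConsensusMotif:
    return ConsensusMotif("FKH", "TGTTTAC")


@pytest.fixture
def flat_track():
    """100 well-separated 1-kb domains: 90 at signal 1, 10 at signal 100."""
    rows, intervals = [], []
    pos = 0
    for i, value in enumerate([1.0] * 90 + [100.0] * 10):
        rows.append(dict(chrom="chr1", start=pos, end=pos + 1000,
                         value=value, domain_id=f"d{i}"))
        intervals.append(GenomicInterval("chr1", pos, pos + 1000, name=f"d{i}"))
        pos += 1000 + 13_000
    return PeakSet(intervals, "flat"), Coverage(pd.DataFrame(rows))
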