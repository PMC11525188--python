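"""Consensus-derived motif profiles with exact mismatch thresholds.

The androgen response element (ARE) is a 15-bp palindrome of two inverted
AGAACA half-sites; tumor-specific enhancers instead carry *chimeric*
composite motifs in which a single half-site sits next to a partner
factor's element (e.g. a forkhead motif) at a short, variable spacing.
This module turns IUPAC consensus strings into position-probability /
log-odds profiles whose acceptance threshold is set so that exactly the
sequences within ``k`` mismatches of the consensus pass, assembles
palindromic and chimeric composites over a spacer range, and scans
sequences (optionally restricted to peaks) on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "IUPAC_CODES",
    "ConsensusMotif",
    "MotifProfile",
    "ChimeraSpec",
    "MotifHit",
    "reverse_complement",
    "build_profile",
    "assemble_palindrome",
    "assemble_chimeras",
    "scan",
]

# Degenerate nucleotide alphabet: code -> allowed bases.
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: Probability mass given to the allowed base(s) at each profile position.
MATCH_MASS = 0.85

#: Floating-point slack applied when comparing window scores to thresholds,
#: so sequences at exactly k mismatches are never lost to rounding.
SCORE_EPS = 1e-9


def reverse_complement(seq: str) -> str:
    """Reverse-complement a sequence that may contain IUPAC codes."""
    try:
        return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"cannot complement character {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class ConsensusMotif:
    """A named IUPAC consensus string."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if len(self.iupac) < 1:
            raise ValueError("consensus must have length >= 1")
        for pos, ch in enumerate(self.iupac.upper()):
            if ch not in IUPAC_CODES:
                raise ValueError(
                    f"invalid IUPAC character {ch!r} at position {pos} "
                    f"in motif {self.name!r}"
                )
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def n_informative(self) -> int:
        """Number of non-N positions (positions that can mismatch)."""
        return sum(1 for c in self.iupac if c != "N")

    def reverse_complement(self) -> "ConsensusMotif":
        return ConsensusMotif(f"{self.name}_rc", reverse_complement(self.iupac))


@dataclass
class MotifProfile:
    """Probability/log-odds profile with a k-mismatch acceptance threshold.

    ``threshold`` is the exact minimum log-odds score over all sequences
    within Hamming distance ``mismatch_tolerance`` of the consensus
    (N positions never count as mismatches and score zero).
    """

    name: str
    matrix: np.ndarray          # L x 4 probabilities, rows sum to 1
    log_odds: np.ndarray        # L x 4, base 2, vs uniform 0.25 background
    threshold: float
    mismatch_tolerance: int
    source: ConsensusMotif

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be L x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("probability rows must sum to 1")
        if self.mismatch_tolerance < 0:
            raise ValueError("mismatch tolerance must be >= 0")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus_score(self) -> float:
        """Log-odds score of the consensus itself (max per position)."""
        return float(self.log_odds.max(axis=1).sum())

    def score(self, seq: str) -> float:
        """Log-odds score of one L-mer (non-ACGT bases take the row minimum)."""
        if len(seq) != len(self):
            raise ValueError("sequence length must equal profile length")
        total = 0.0
        for row, ch in zip(self.log_odds, seq.upper()):
            idx = _BASE_INDEX.get(ch)
            total += row[idx] if idx is not None else row.min()
        return float(total)


@dataclass(frozen=True)
class ChimeraSpec:
    """One composite-motif configuration: two elements, spacer, order."""

    element_a: ConsensusMotif
    element_b: ConsensusMotif
    spacer_len: int
    order: str  # "AB" or "BA"

    def __post_init__(self) -> None:
        if self.order not in ("AB", "BA"):
            raise ValueError("order must be 'AB' or 'BA'")
        if self.spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")

    def consensus(self) -> ConsensusMotif:
        first, second = (
            (self.element_a, self.element_b)
            if self.order == "AB"
            else (self.element_b, self.element_a)
        )
        name = f"{first.name}_N{self.spacer_len}_{second.name}"
        return ConsensusMotif(name, first.iupac + "N" * self.spacer_len + second.iupac)


@dataclass(frozen=True)
class MotifHit:
    """One accepted scan window (0-based, half-open, sequence coordinates)."""

    sequence_id: str
    start: int
    end: int
    strand: str
    score: float
    profile_name: str
    peak_name: str | None = None


def build_profile(consensus: ConsensusMotif, k: int = 0,
                  match_mass: float = MATCH_MASS) -> MotifProfile:
    """Convert a consensus into a profile whose threshold admits exactly the
    sequences within ``k`` mismatches.

    Each position gives the allowed base(s) ``match_mass`` split equally,
    and the disallowed bases the remainder split equally; N rows are
    uniform and score zero.  Because the per-position score drop from best
    to worst base is fixed by the allowed-set size, the minimum score of
    any k-mismatch sequence is the consensus score minus the k largest
    drops — that exact value is the threshold.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > consensus.n_informative:
        raise ValueError(
            f"k={k} exceeds the {consensus.n_informative} informative "
            f"(non-N) positions of {consensus.name!r}"
        )
    if not 0.0 < match_mass < 1.0:
        raise ValueError("match_mass must be in (0, 1)")

    L = len(consensus)
    matrix = np.empty((L, 4))
    drops = []
    for i, code in enumerate(consensus.iupac):
        allowed = IUPAC_CODES[code]
        n_allowed = len(allowed)
        if n_allowed == 4:
            matrix[i] = 0.25
            continue
        p_match = match_mass / n_allowed
        p_mis = (1.0 - match_mass) / (4 - n_allowed)
        matrix[i] = p_mis
        for b in allowed:
            matrix[i, _BASE_INDEX[b]] = p_match
        drops.append(np.log2(p_match) - np.log2(p_mis))

    log_odds = np.log2(matrix / 0.25)
    consensus_score = float(log_odds.max(axis=1).sum())
    # N positions contribute no drop; the k largest drops define the floor.
    threshold = consensus_score - float(np.sum(sorted(drops, reverse=True)[:k]))
    return MotifProfile(
        name=consensus.name,
        matrix=matrix,
        log_odds=log_odds,
        threshold=threshold,
        mismatch_tolerance=k,
        source=consensus,
    )


def assemble_palindrome(half: ConsensusMotif, spacer_len: int) -> ConsensusMotif:
    """Half-site + N-spacer + inverted half-site (a full ARE for AGAACA/3N).

    The result is its own reverse complement (N is self-complementary).
    """
    if spacer_len < 0:
        raise ValueError("spacer_len must be >= 0")
    seq = half.iupac + "N" * spacer_len + reverse_complement(half.iupac)
    return ConsensusMotif(f"{half.name}_pal{spacer_len}", seq)


def assemble_chimeras(a: ConsensusMotif, b: ConsensusMotif,
                      spacer_range: tuple[int, int] = (0, 8)) -> list[ConsensusMotif]:
    """Enumerate composite motifs over a spacer range in both orders.

    For spacers 0..8 this yields the 18 configurations scanned when
    pairing a partner element with the AR half-site (9 spacings x 2
    orders).
    """
    lo, hi = spacer_range
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid spacer range [{lo}, {hi}]")
    out = []
    for s in range(lo, hi + 1):
        for order in ("AB", "BA"):
            out.append(ChimeraSpec(a, b, s, order).consensus())
    return out


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to 0..3 for ACGT, 4 for anything else."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _score_table(log_odds: np.ndarray) -> np.ndarray:
    """L x 5 lookup: columns ACGT plus a worst-case column for ambiguity."""
    table = np.empty((log_odds.shape[0], 5))
    table[:, :4] = log_odds
    table[:, 4] = log_odds.min(axis=1)
    return table


def _window_scores(table: np.ndarray, encoded: np.ndarray) -> np.ndarray:
    L = table.shape[0]
    W = len(encoded) - L + 1
    if W <= 0:
        return np.empty(0)
    scores = np.zeros(W)
    for j in range(L):
        scores += table[j, encoded[j:j + W]]
    return scores


def _scan_one(profile: MotifProfile, seq_id: str, seq: str,
              both_strands: bool, offset: int = 0,
              peak_name: str | None = None) -> list[MotifHit]:
    encoded = _encode(seq)
    L = len(profile)
    hits: dict[int, MotifHit] = {}
    fwd = _window_scores(_score_table(profile.log_odds), encoded)
    cut = profile.threshold - SCORE_EPS
    for i in np.flatnonzero(fwd >= cut):
        i = int(i)
        hits[i] = MotifHit(seq_id, offset + i, offset + i + L, "+",
                           float(fwd[i]), profile.name, peak_name)
    if both_strands:
        # Scanning the minus strand == scoring with the reverse-complement
        # profile on the forward sequence at the same window.
        rc = profile.log_odds[::-1, ::-1]
        rev = _window_scores(_score_table(rc), encoded)
        for i in np.flatnonzero(rev >= cut):
            i = int(i)
            if i in hits:  # palindromic position: prefer the + strand call
                continue
            hits[i] = MotifHit(seq_id, offset + i, offset + i + L, "-",
                               float(rev[i]), profile.name, peak_name)
    return [hits[i] for i in sorted(hits)]


def scan(profile: MotifProfile, sequences: Mapping[str, str],
         both_strands: bool = True, peaks=None) -> list[MotifHit]:
    """Report every window scoring at or above the profile threshold.

    ``sequences`` maps sequence id to string.  With ``peaks`` (a
    :class:`~neocistrome.intervals.PeakSet`), only windows fully inside a
    peak are scanned and each hit records its peak.
    """
    if not sequences:
        raise ValueError("no sequences supplied")
    hits: list[MotifHit] = []
    if peaks is None:
        for seq_id in sequences:
            hits.extend(_scan_one(profile, seq_id, sequences[seq_id], both_strands))
        return hits
    for iv in peaks:
        if iv.sequence_id not in sequences:
            raise ValueError(f"peak {iv.name or iv} on unknown sequence "
                             f"{iv.sequence_id!r}")
        seq = sequences[iv.sequence_id]
        if iv.start < 0 or iv.end > len(seq):
            raise ValueError(f"peak {iv.name or iv} outside sequence bounds")
        hits.extend(
            _scan_one(profile, iv.sequence_id, seq[iv.start:iv.end],
                      both_strands, offset=iv.start,
                      peak_name=iv.name or f"{iv.sequence_id}:{iv.start}-{iv.end}")
        )
    return hits
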