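"""Reporter-screen ranking and Bliss synergy.

In a fluorescence-sorted CRISPR reporter screen, guides disabling a
coactivator enrich in the reporter-LOW gate, so the per-guide statistic
is the log2 ratio of counts-per-million in LOW over HIGH (descending
rank puts coactivator candidates on top, repressor candidates at the
bottom).  Gene scores aggregate guide log-ratios by mean (median
optional).  Bliss independence for two inhibitions a and b expects
a + b - a*b; positive excess of the observed combination indicates
synergy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScreenCountTable",
    "guide_ratios",
    "gene_scores",
    "bliss_synergy",
]

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class ScreenCountTable:
    """Per-guide LOW/HIGH counts with gene mapping."""

    frame: pd.DataFrame  # columns guide_id, gene, count_low, count_high

    def __post_init__(self) -> None:
        required = {"guide_id", "gene", "count_low", "count_high"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if self.frame["guide_id"].duplicated().any():
            raise ValueError("guide_ids must be unique")
        if (self.frame[["count_low", "count_high"]] < 0).any().any():
            raise ValueError("counts must be non-negative")

    @property
    def library_size_low(self) -> int:
        return int(self.frame["count_low"].sum())

    @property
    def library_size_high(self) -> int:
        return int(self.frame["count_high"].sum())

    def __len__(self) -> int:
        return len(self.frame)


def guide_ratios(table: ScreenCountTable,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-guide log2 LOW/HIGH CPM ratio, ranked descending.

    Counts are normalized to counts-per-million within each sorted arm;
    the symmetric pseudocount keeps dropout guides (0/0) at log-ratio 0.
    """
    lib_low, lib_high = table.library_size_low, table.library_size_high
    if lib_low <= 0 or lib_high <= 0:
        raise ValueError("both arms need positive library size")
    out = table.frame[["guide_id", "gene"]].copy()
    cpm_low = table.frame["count_low"] / lib_low * 1e6
    cpm_high = table.frame["count_high"] / lib_high * 1e6
    out["cpm_low"] = cpm_low
    out["cpm_high"] = cpm_high
    out["log2_ratio"] = np.log2((cpm_low + pseudocount) / (cpm_high + pseudocount))
    out = out.sort_values("log2_ratio", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def gene_scores(ratios: pd.DataFrame, method: str = "mean") -> pd.DataFrame:
    """Aggregate guide log2 ratios per gene, ranked descending.

    Reports the guide count and the second-highest guide log-ratio
    (equal to the only guide's ratio for single-guide genes) as a
    robustness readout.
    """
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    if ratios["gene"].isna().any():
        raise ValueError("every guide must map to a gene")

    def _second_best(vals: pd.Series) -> float:
        s = np.sort(vals.to_numpy())[::-1]
        return float(s[1] if len(s) > 1 else s[0])

    agg = ratios.groupby("gene")["log2_ratio"].agg(
        score=method, n_guides="size", second_best=_second_best
    ).reset_index()
    agg = agg.sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg


def bliss_synergy(inhibition_a, inhibition_b, inhibition_combo) -> np.ndarray:
    """Excess of the observed combination over Bliss independence.

    All inputs are inhibition fractions in [0, 1] (scalars or arrays of a
    common shape, e.g. a dose-pair matrix); the excess is bounded in
    [-1, 1] and positive values indicate synergy.
    """
    a = np.asarray(inhibition_a, dtype=float)
    b = np.asarray(inhibition_b, dtype=float)
    combo = np.asarray(inhibition_combo, dtype=float)
    for name, v in (("a", a), ("b", b), ("combo", combo)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"inhibition_{name} outside [0, 1]")
    expected = a + b - a * b
    return combo - expected
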