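"""Abundance-rank sextile concordance between proteome contexts.

Proteins are ranked by mean abundance within a context (a compartment x
stage combination) and split into k equal bins from high to low — E1..E6
for epithelium, S1..S6 for stroma.  A 6x6 transition table between two
contexts then shows how well the abundance order is preserved: identical
orderings put all mass on the diagonal, unrelated orderings spread each
row uniformly (diagonal fraction 1/k).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["BinAssignment", "ConcordanceTable", "rank_bins", "concordance_table", "context_means"]


@dataclasses.dataclass
class BinAssignment:
    """Protein -> rank-bin index (1 = highest abundance)."""

    bins: pd.Series
    k: int
    context: str = ""
    bin_sizes: tuple[int, ...] = ()

    def proteins_in(self, b: int) -> list[str]:
        return list(self.bins.index[self.bins == b])


@dataclasses.dataclass
class ConcordanceTable:
    """k x k bin-transition counts between two rank-bin assignments."""

    counts: pd.DataFrame
    row_fractions: pd.DataFrame
    diagonal_fraction: pd.Series
    middle_band_retention: float
    n_shared: int
    tolerance: int = 0


def context_means(data: pd.DataFrame | "pd.Series", samples: Sequence[str] | None = None,
                  min_obs: int = 3) -> pd.Series:
    """Per-protein mean over observed values in the given samples.

    Proteins observed in fewer than ``min_obs`` samples get ``NaN`` so
    they drop out of the ranking.
    """
    df = data if samples is None else data[list(samples)]
    n_obs = df.notna().sum(axis=1)
    means = df.mean(axis=1, skipna=True)
    means[n_obs < min_obs] = np.nan
    return means


def rank_bins(means: pd.Series, k: int = 6, context: str = "") -> BinAssignment:
    """Split proteins into k contiguous rank bins by descending mean.

    Ties are broken by protein ID (lexicographic) so the assignment is
    deterministic.  When len(means) is not divisible by k the remainder
    is distributed to the earliest (highest-abundance) bins, so bin sizes
    differ by at most one.
    """
    usable = means.dropna()
    n = len(usable)
    if n < k:
        raise ValueError(f"need at least k={k} proteins with defined means, got {n}")
    order = (
        usable.rename("mean")
        .rename_axis("protein")
        .reset_index()
        .sort_values(["mean", "protein"], ascending=[False, True], kind="mergesort")
    )
    base, rem = divmod(n, k)
    sizes = tuple(base + (1 if i < rem else 0) for i in range(k))
    labels = np.repeat(np.arange(1, k + 1), sizes)
    bins = pd.Series(labels, index=order["protein"].to_numpy(), name="bin")
    return BinAssignment(bins=bins, k=k, context=context, bin_sizes=sizes)


def concordance_table(
    bins_a: BinAssignment, bins_b: BinAssignment, tolerance: int = 0
) -> ConcordanceTable:
    """Tabulate bin transitions for proteins shared by both assignments.

    ``tolerance`` widens the notion of "staying in the same bin": with
    tolerance 1 a protein landing in an adjacent bin still counts toward
    the diagonal fraction and the middle-band (bins 2..k-1) retention.
    """
    if bins_a.k != bins_b.k:
        raise ValueError("bin assignments use different k")
    k = bins_a.k
    shared = bins_a.bins.index.intersection(bins_b.bins.index)
    if len(shared) == 0:
        raise ValueError("no shared proteins between the two assignments")
    a = bins_a.bins.loc[shared].to_numpy()
    b = bins_b.bins.loc[shared].to_numpy()
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (a - 1, b - 1), 1)
    idx = pd.RangeIndex(1, k + 1)
    counts_df = pd.DataFrame(counts, index=idx, columns=idx)
    row_tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = counts / row_tot[:, None]
    row_fracs = pd.DataFrame(fracs, index=idx, columns=idx)

    near = np.abs(a - b) <= tolerance
    diag = np.zeros(k)
    for i in range(1, k + 1):
        in_bin = a == i
        diag[i - 1] = near[in_bin].mean() if in_bin.any() else np.nan
    mid = (a >= 2) & (a <= k - 1)
    retention = float(near[mid].mean()) if mid.any() else float("nan")
    return ConcordanceTable(
        counts=counts_df,
        row_fractions=row_fracs,
        diagonal_fraction=pd.Series(diag, index=idx),
        middle_band_retention=retention,
        n_shared=int(len(shared)),
        tolerance=tolerance,
    )
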