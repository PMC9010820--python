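"""Cohort-level QC and global structure: counts, correlations, PCA.

Identification depth (observed proteins per sample), within-group
pairwise Spearman correlation distributions (a homogeneity read-out),
and an unsupervised PCA embedding of samples.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quant import QuantTable, SampleSheet

__all__ = [
    "CorrelationSummary",
    "EmbeddingResult",
    "identification_counts",
    "pairwise_spearman",
    "pca_embedding",
]


def identification_counts(
    table: QuantTable,
    sheet: SampleSheet,
    group_by: Sequence[str] = ("compartment", "stage"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed-protein counts per sample and summarized per group.

    Returns ``(per_sample, per_group)``: the former one row per sample
    with its annotation columns and ``n_detected``; the latter group
    mean/median/min/max counts.
    """
    sheet.validate_against(table)
    counts = table.detected().sum(axis=0)
    per_sample = sheet.table.loc[table.sample_ids].copy()
    per_sample["n_detected"] = counts
    per_group = (
        per_sample.groupby(list(group_by))["n_detected"]
        .agg(["count", "mean", "median", "min", "max"])
        .rename(columns={"count": "n_samples"})
    )
    return per_sample, per_group


@dataclasses.dataclass
class CorrelationSummary:
    """Pairwise-complete Spearman correlations within one sample group."""

    group: str
    pairs: pd.DataFrame  # sample_a, sample_b, rho, n_overlap
    median_rho: float
    n_pairs: int
    n_excluded: int
    min_overlap: int

    @property
    def rhos(self) -> list[float]:
        return list(self.pairs["rho"])


def pairwise_spearman(
    table: QuantTable,
    samples: Sequence[str],
    min_overlap: int = 50,
    group: str = "",
) -> CorrelationSummary:
    """Spearman rho for every sample pair, on jointly-observed proteins.

    Pairs with fewer than ``min_overlap`` co-observed proteins are
    excluded (and counted).  Average ranks resolve ties.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least two samples for pairwise correlation")
    data = table.data[samples]
    rows = []
    n_excluded = 0
    for a, b in combinations(samples, 2):
        both = data[a].notna() & data[b].notna()
        n = int(both.sum())
        if n < min_overlap:
            n_excluded += 1
            continue
        rho = stats.spearmanr(data.loc[both, a], data.loc[both, b]).statistic
        rows.append((a, b, float(rho), n))
    if not rows:
        raise ValueError(
            f"all {n_excluded} sample pairs fell below min_overlap={min_overlap}"
        )
    pairs = pd.DataFrame(rows, columns=["sample_a", "sample_b", "rho", "n_overlap"])
    return CorrelationSummary(
        group=group,
        pairs=pairs,
        median_rho=float(pairs["rho"].median()),
        n_pairs=len(pairs),
        n_excluded=n_excluded,
        min_overlap=min_overlap,
    )


@dataclasses.dataclass
class EmbeddingResult:
    """Sample coordinates on the top-k principal components."""

    coordinates: pd.DataFrame  # samples x PC1..PCk
    explained_variance_ratio: np.ndarray


def pca_embedding(table: QuantTable, k: int = 2) -> EmbeddingResult:
    """Unsupervised PCA of samples (proteins centered, not scaled).

    Requires a complete (imputed) matrix.  The sign of each component is
    fixed so that its largest-magnitude protein loading is positive,
    making coordinates reproducible across runs and platforms.
    """
    if table.data.isna().any().any():
        raise ValueError("pca_embedding requires a complete matrix; impute first")
    X = table.data.to_numpy(dtype=float)
    n_p, n_s = X.shape
    k = min(k, n_s, n_p)
    centered = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    for i in range(len(s)):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            Vt[i, :] = -Vt[i, :]
    total = float((s**2).sum())
    evr = (s**2) / total if total > 0 else np.zeros_like(s)
    coords = pd.DataFrame(
        (s[:k, None] * Vt[:k, :]).T,
        index=table.data.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return EmbeddingResult(coordinates=coords, explained_variance_ratio=evr[:k])
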