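"""Differential protein abundance, overlap, comparability, and modules.

DEP (differentially expressed protein) calling uses a per-protein Welch
two-sample t-test on log2 abundances with Benjamini-Hochberg FDR control,
under the three threshold regimes used for stage contrasts (|FC| > 4,
q < 0.05), compartment contrasts (|FC| > 2, q < 0.05) and single-patient
paired tissues (|FC| >= 2, no replicate test).  Paired-contrast
comparability ("how close do two log-ratio vectors sit to the diagonal")
is quantified by Lin's concordance correlation coefficient plus the RMS
perpendicular distance from the identity line.  A light-weight
correlation-module classification (hierarchical clustering on
1 - Pearson distance with an eigenprotein summary per module) stands in
for a full weighted co-expression network analysis.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import cluster, stats

from .quant import QuantTable, SampleSheet

__all__ = [
    "ContrastResult",
    "ComparabilityResult",
    "ModuleAssignment",
    "IndividualDeps",
    "OverlapResult",
    "bh_adjust",
    "call_deps",
    "individual_deps",
    "overlap_analysis",
    "ratio_comparability",
    "classify_modules",
]

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"
STATUS_UNTESTED = "untested"


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped at
    1, returned in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = q_sorted
    return out


@dataclasses.dataclass
class ContrastResult:
    """Per-protein differential result for one named contrast.

    ``table`` has columns ``log2fc`` (mean_A - mean_B on log2 scale),
    ``p``, ``q``, ``n_obs_a``, ``n_obs_b`` and ``status`` in
    {up, down, ns, untested}.  Proteins with too few observations are
    reported as ``untested``, never dropped.
    """

    label: str
    table: pd.DataFrame
    fc_threshold: float
    q_threshold: float
    min_obs: int

    @property
    def up(self) -> set[str]:
        return set(self.table.index[self.table["status"] == STATUS_UP])

    @property
    def down(self) -> set[str]:
        return set(self.table.index[self.table["status"] == STATUS_DOWN])

    @property
    def deps(self) -> set[str]:
        return self.up | self.down

    @property
    def n_dep(self) -> int:
        return len(self.deps)

    def log2fc(self, tested_only: bool = True) -> pd.Series:
        s = self.table["log2fc"]
        if tested_only:
            s = s[self.table["status"] != STATUS_UNTESTED]
        return s


def _group_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.sum(np.isfinite(X), axis=1).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=1)
        var = np.nanvar(X, axis=1, ddof=1)
    return n, mean, var


def call_deps(
    table: QuantTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    label: str = "",
    fc_threshold: float = 4.0,
    q_threshold: float = 0.05,
    min_obs: int = 3,
) -> ContrastResult:
    """Call DEPs between two sample groups (Welch t + BH-FDR + FC cut).

    ``fc_threshold`` is in fold units; a protein is up/down iff
    q < q_threshold and |log2FC| > log2(fc_threshold) (strict, matching
    "greater than a four-fold change").  Proteins with fewer than
    ``min_obs`` observed values in either group are ``untested``.
    """
    if table.scale != "log2":
        raise ValueError("call_deps expects log2-scale abundances")
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1 (fold units)")
    if min_obs < 2:
        raise ValueError("min_obs must be at least 2")
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError(f"groups overlap: {sorted(set_a & set_b)}")
    A = table.data[list(group_a)].to_numpy()
    B = table.data[list(group_b)].to_numpy()
    n_a, mean_a, var_a = _group_stats(A)
    n_b, mean_b, var_b = _group_stats(B)

    log2fc = mean_a - mean_b
    tested = (n_a >= min_obs) & (n_b >= min_obs)

    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = var_a / n_a + var_b / n_b
        t = log2fc / np.sqrt(se2)
        df = se2**2 / (
            (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
        )
    p = np.full(A.shape[0], np.nan)
    ok = tested & (se2 > 0)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    degenerate = tested & (se2 == 0)  # both groups constant
    p[degenerate] = np.where(log2fc[degenerate] == 0, 1.0, 0.0)

    q = np.full_like(p, np.nan)
    q[tested] = bh_adjust(p[tested])

    status = np.full(A.shape[0], STATUS_NS, dtype=object)
    status[~tested] = STATUS_UNTESTED
    cut = np.log2(fc_threshold)
    sig = tested & (q < q_threshold) & (np.abs(log2fc) > cut)
    status[sig & (log2fc > 0)] = STATUS_UP
    status[sig & (log2fc < 0)] = STATUS_DOWN

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "n_obs_a": n_a.astype(int),
            "n_obs_b": n_b.astype(int),
            "status": status,
        },
        index=table.data.index,
    )
    out.loc[~tested, ["log2fc", "p", "q"]] = np.nan
    return ContrastResult(label, out, fc_threshold, q_threshold, min_obs)


@dataclasses.dataclass
class IndividualDeps:
    """Single-patient paired-tissue DEPs (|log2 ratio| >= log2 threshold)."""

    patient: str
    label: str
    ratios: pd.Series
    up: set[str]
    down: set[str]

    @property
    def deps(self) -> set[str]:
        return self.up | self.down


def individual_deps(
    table: QuantTable,
    sheet: SampleSheet,
    patient: str,
    compartment: str,
    stage_a: str,
    stage_b: str,
    fc_threshold: float = 2.0,
) -> IndividualDeps:
    """Paired-tissue DEPs for one patient (inclusive |FC| >= threshold).

    With a single sample per tissue no replicate test is possible; the
    call is a pure fold-change cut on proteins observed in both samples.
    """
    ids = {}
    for stage in (stage_a, stage_b):
        hits = sheet.samples_where(patient_id=patient, compartment=compartment, stage=stage)
        hits = [s for s in hits if s in table.sample_ids]
        if len(hits) == 0:
            raise ValueError(f"patient {patient} lacks a {compartment} {stage} sample")
        if len(hits) > 1:
            raise ValueError(
                f"patient {patient} has multiple {compartment} {stage} samples: {hits}"
            )
        ids[stage] = hits[0]
    a = table.data[ids[stage_a]]
    b = table.data[ids[stage_b]]
    if table.scale == "log2":
        ratios = (a - b).dropna()
    else:
        ratios = np.log2(a / b).dropna()
    cut = np.log2(fc_threshold)
    up = set(ratios.index[ratios >= cut])
    down = set(ratios.index[ratios <= -cut])
    return IndividualDeps(
        patient=patient,
        label=f"{compartment}:{stage_a}/{stage_b}",
        ratios=ratios,
        up=up,
        down=down,
    )


@dataclasses.dataclass
class OverlapResult:
    """Membership table and pairwise overlap fractions of named sets."""

    membership: pd.DataFrame
    fractions: pd.DataFrame  # fractions.loc[A, B] = |A & B| / |A|
    sizes: pd.Series


def overlap_analysis(sets: Mapping[str, set[str]]) -> OverlapResult:
    """Exact set algebra over >= 2 named protein sets.

    fraction(A in B) = |A & B| / |A|; undefined (NaN) for empty A.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = list(sets)
    universe = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {name: [p in sets[name] for p in universe] for name in names}, index=universe
    )
    sizes = pd.Series({name: len(sets[name]) for name in names})
    frac = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            if len(sets[a]) == 0:
                frac.loc[a, b] = np.nan
            else:
                frac.loc[a, b] = len(sets[a] & sets[b]) / len(sets[a])
    return OverlapResult(membership=membership, fractions=frac, sizes=sizes)


@dataclasses.dataclass
class ComparabilityResult:
    """Agreement of two paired log-ratio vectors with the diagonal."""

    labels: tuple[str, str]
    ccc: float
    rms_from_diagonal: float
    n_shared: int
    ratios: pd.DataFrame


def ratio_comparability(
    ratios_a: pd.Series,
    ratios_b: pd.Series,
    labels: tuple[str, str] = ("A", "B"),
    min_shared: int = 10,
) -> ComparabilityResult:
    """Lin's concordance correlation + RMS distance from the diagonal.

    rho_c = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2), with
    n-denominator moments (Lin's estimator); the RMS uses the
    perpendicular distance |x - y| / sqrt(2) to the identity line.
    """
    shared = ratios_a.dropna().index.intersection(ratios_b.dropna().index)
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared proteins with both ratios defined (< {min_shared})"
        )
    x = ratios_a.loc[shared].to_numpy(dtype=float)
    y = ratios_b.loc[shared].to_numpy(dtype=float)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    ccc = float(2.0 * cov / denom) if denom > 0 else 1.0
    rms = float(np.sqrt(np.mean((x - y) ** 2) / 2.0))
    df = pd.DataFrame({labels[0]: x, labels[1]: y}, index=shared)
    return ComparabilityResult(
        labels=labels, ccc=ccc, rms_from_diagonal=rms, n_shared=len(shared), ratios=df
    )


@dataclasses.dataclass
class ModuleAssignment:
    """Correlation modules of proteins with eigenprotein-trait labels."""

    modules: pd.Series  # protein -> module id (1..k)
    eigenproteins: pd.DataFrame  # samples x modules (first-PC scores)
    trait_correlation: pd.DataFrame  # modules x traits
    trait_labels: dict[int, str]
    excluded: list[str]


def classify_modules(
    data: pd.DataFrame,
    traits: pd.DataFrame,
    k: int = 3,
) -> ModuleAssignment:
    """Cluster protein profiles into k correlation modules and label them.

    Distance is 1 - Pearson correlation between protein profiles;
    average-linkage hierarchical clustering with a static cut at ``k``.
    Each module is summarized by its eigenprotein (first principal
    component of the standardized member profiles, sign-aligned with the
    module's mean profile) and labeled with the trait whose indicator
    correlates most strongly (in absolute value) with the eigenprotein.

    Parameters
    ----------
    data:
        DEP abundance sub-matrix (proteins x samples), no missing values.
    traits:
        Samples x trait indicator columns (0/1 or numeric).
    """
    if data.isna().any().any():
        raise ValueError("module classification requires a complete matrix")
    if data.shape[0] < 3 or data.shape[1] < 4:
        raise ValueError("need at least 3 proteins and 4 samples")
    if not set(data.columns) <= set(traits.index):
        raise ValueError("traits must cover every sample column")

    sd = data.std(axis=1, ddof=0)
    excluded = list(data.index[sd == 0])
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} constant-profile protein(s)", RuntimeWarning
        )
        data = data.loc[sd > 0]
        if data.shape[0] < max(3, k):
            raise ValueError("too few variable proteins after exclusion")

    X = data.to_numpy(dtype=float)
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True, ddof=0)
    corr = np.clip((Z @ Z.T) / X.shape[1], -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = cluster.hierarchy.distance.squareform(dist, checks=False)
    linkage = cluster.hierarchy.average(condensed)
    if k == 1:
        labels = np.ones(X.shape[0], dtype=int)
    else:
        labels = cluster.hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    modules = pd.Series(labels, index=data.index, name="module")

    trait_mat = traits.loc[data.columns].astype(float)
    eig = {}
    corr_rows = {}
    trait_labels = {}
    for m in sorted(set(labels)):
        Zm = Z[labels == m]
        U, s, Vt = np.linalg.svd(Zm, full_matrices=False)
        pc = Vt[0]
        mean_profile = Zm.mean(axis=0)
        if np.dot(pc, mean_profile) < 0:
            pc = -pc
        eig[m] = pc
        cors = {}
        for trait in trait_mat.columns:
            tvec = trait_mat[trait].to_numpy()
            if tvec.std() == 0 or pc.std() == 0:
                cors[trait] = np.nan
            else:
                cors[trait] = float(np.corrcoef(pc, tvec)[0, 1])
        corr_rows[m] = cors
        finite = {t: c for t, c in cors.items() if np.isfinite(c)}
        trait_labels[m] = (
            max(finite, key=lambda t: abs(finite[t])) if finite else ""
        )
    eigen_df = pd.DataFrame(eig, index=data.columns)
    corr_df = pd.DataFrame(corr_rows).T
    return ModuleAssignment(
        modules=modules,
        eigenproteins=eigen_df,
        trait_correlation=corr_df,
        trait_labels=trait_labels,
        excluded=excluded,
    )
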