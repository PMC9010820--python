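"""Signature-based stromal characterization.

Three tools: a rank-based single-sample enrichment score (ssGSEA-style
running sum) for stromal signatures, constrained linear deconvolution of
immune-cell fractions against a reference signature matrix
(non-negative least squares with sum-to-one renormalization), and a
ligand-receptor screen intersecting stroma- and epithelium-side DEPs
with a curated pair list.

The stromal signature and the ligand-receptor pair list are inputs, not
code: small editable files ship with the package as placeholders and can
be replaced by any GMT / two-column TSV.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .differential import ContrastResult, bh_adjust
from .quant import QuantTable, SampleSheet

__all__ = [
    "SignatureSet",
    "SignatureMatrix",
    "DeconvolutionResult",
    "CohortScores",
    "LigandReceptorResult",
    "ssgsea_score",
    "score_cohort",
    "deconvolve",
    "ligand_receptor_screen",
    "read_gmt",
    "write_gmt",
    "load_stromal_signature",
    "load_lr_pairs",
]


@dataclasses.dataclass
class SignatureSet:
    """Named protein sets (e.g., a stromal marker signature)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"signature set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate IDs in signature set {name!r}")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> SignatureSet:
    """Read GMT: one set per line, tab-separated name, description, members."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = [f for f in fields[2:] if f]
    return SignatureSet(sets)


def write_gmt(signature: SignatureSet, path: str | Path, description: str = "") -> None:
    lines = [
        "\t".join([name, description, *members])
        for name, members in signature.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclasses.dataclass
class SignatureMatrix:
    """Reference cell-type profiles: proteins x cell types, non-negative."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        if self.profiles.columns.duplicated().any():
            raise ValueError("duplicate cell-type labels")
        vals = self.profiles.to_numpy(dtype=float)
        if (vals < 0).any() or np.isnan(vals).any():
            raise ValueError("signature profiles must be non-negative and complete")
        if (vals.sum(axis=0) == 0).any():
            raise ValueError("signature matrix has an all-zero cell-type column")
        self.profiles = self.profiles.astype(float)

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def n_cell_types(self) -> int:
        return self.profiles.shape[1]


# ---------------------------------------------------------------------------
# Single-sample enrichment


def ssgsea_score(
    values: pd.Series, gene_set: Iterable[str], alpha: float = 0.25
) -> float:
    """Rank-based single-sample enrichment score of a protein set.

    Observed proteins are ranked by descending abundance (ties broken by
    protein ID).  A running sum takes in-set increments proportional to
    rank^alpha (normalized to total 1; the top rank has value N) and
    out-of-set decrements 1/(N - N_set); the score is the integrated
    deviation of the running sum (its mean over positions, so samples
    with different identification depth N are comparable).  It depends
    only on ranks, never on the abundance scale.
    """
    obs = values.dropna()
    n = len(obs)
    if n == 0:
        raise ValueError("no observed proteins in sample")
    members = set(gene_set) & set(obs.index)
    if not members:
        raise ValueError("no signature member observed in sample")
    if len(members) == n:
        return 0.0  # degenerate: no out-of-set mass
    order = (
        obs.rename("value")
        .rename_axis("protein")
        .reset_index()
        .sort_values(["value", "protein"], ascending=[False, True], kind="mergesort")
    )
    in_set = order["protein"].isin(members).to_numpy()
    rank_value = np.arange(n, 0, -1, dtype=float)  # top of the list gets N
    weights = np.where(in_set, rank_value**alpha, 0.0)
    weights /= weights[in_set].sum()
    misses = np.where(in_set, 0.0, 1.0 / (n - len(members)))
    running = np.cumsum(weights - misses)
    return float(running.sum() / n)


@dataclasses.dataclass
class CohortScores:
    """Per-sample enrichment scores plus pairwise group comparisons."""

    scores: pd.Series
    set_name: str
    alpha: float
    group_tests: pd.DataFrame  # group_a, group_b, n_a, n_b, p, q


def score_cohort(
    table: QuantTable,
    signature: SignatureSet | Iterable[str],
    sheet: SampleSheet,
    set_name: str | None = None,
    group_col: str = "compartment",
    alpha: float = 0.25,
    min_group_size: int = 3,
) -> CohortScores:
    """Score every sample and compare groups by Wilcoxon rank-sum.

    Pairwise two-sided Mann-Whitney tests between all groups (of the
    chosen annotation column) with at least ``min_group_size`` samples,
    BH-adjusted.
    """
    if isinstance(signature, SignatureSet):
        if set_name is None:
            if len(signature.names) != 1:
                raise ValueError("set_name required when signature has several sets")
            set_name = signature.names[0]
        members = signature[set_name]
    else:
        members = list(signature)
        set_name = set_name or "signature"
    sheet.validate_against(table)
    scores = pd.Series(
        {s: ssgsea_score(table.data[s], members, alpha=alpha) for s in table.sample_ids},
        name="score",
    )
    groups = sheet.table.loc[table.sample_ids, group_col]
    usable = [
        g for g, cnt in groups.value_counts().items() if cnt >= min_group_size
    ]
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 groups with >= {min_group_size} samples, got {usable}"
        )
    rows = []
    for a, b in combinations(sorted(usable), 2):
        xa = scores[groups[groups == a].index]
        xb = scores[groups[groups == b].index]
        p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        rows.append((a, b, len(xa), len(xb), p))
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "p"])
    tests["q"] = bh_adjust(tests["p"].to_numpy())
    return CohortScores(scores=scores, set_name=set_name, alpha=alpha, group_tests=tests)


# ---------------------------------------------------------------------------
# Deconvolution


@dataclasses.dataclass
class DeconvolutionResult:
    """Estimated per-sample cell-type fractions (non-negative, sum to 1)."""

    fractions: pd.DataFrame  # samples x cell types
    residual_norm: pd.Series
    n_proteins_used: pd.Series


def deconvolve(
    table: QuantTable,
    signature: SignatureMatrix,
    min_protein_ratio: float = 2.0,
) -> DeconvolutionResult:
    """Estimate cell-type fractions by row-scaled non-negative least squares.

    Per sample: restrict to signature proteins observed in the sample,
    scale each protein row of the signature (and the matching abundance)
    by the row's standard deviation across cell types so no single
    high-abundance protein dominates the fit, solve
    min ||S f - x|| s.t. f >= 0 on linear-scale abundances, and
    renormalize f to sum to one.  Requires at least
    ``min_protein_ratio`` x n_cell_types observed signature proteins.
    """
    if table.scale != "linear":
        raise ValueError("deconvolution mixes additively on the linear scale")
    S_full = signature.profiles
    k = signature.n_cell_types
    frac_rows = {}
    resid = {}
    n_used = {}
    for sample in table.sample_ids:
        x = table.data[sample].dropna()
        shared = S_full.index.intersection(x.index)
        if len(shared) < min_protein_ratio * k:
            raise ValueError(
                f"sample {sample}: only {len(shared)} observed signature proteins for "
                f"{k} cell types (underdetermined)"
            )
        S = S_full.loc[shared].to_numpy(dtype=float)
        v = x.loc[shared].to_numpy(dtype=float)
        scale = S.std(axis=1, ddof=0)
        scale[scale == 0] = np.maximum(S[scale == 0].mean(axis=1), 1.0)
        Sw = S / scale[:, None]
        vw = v / scale
        f, rnorm = optimize.nnls(Sw, vw)
        total = f.sum()
        if total <= 0:
            f = np.full(k, 1.0 / k)
        else:
            f = f / total
        frac_rows[sample] = f
        resid[sample] = float(rnorm)
        n_used[sample] = int(len(shared))
    fractions = pd.DataFrame(frac_rows, index=signature.cell_types).T
    return DeconvolutionResult(
        fractions=fractions,
        residual_norm=pd.Series(resid),
        n_proteins_used=pd.Series(n_used),
    )


# ---------------------------------------------------------------------------
# Ligand-receptor screen


@dataclasses.dataclass
class LigandReceptorResult:
    """DEP x DEP ligand-receptor hits between stroma and epithelium."""

    table: pd.DataFrame
    n_pairs_screened: int
    n_malformed: int


def ligand_receptor_screen(
    stroma: ContrastResult,
    epithelium: ContrastResult,
    pairs: pd.DataFrame | str | Path | None = None,
) -> LigandReceptorResult:
    """Report pairs whose partners are DEPs on the two sides.

    For each (ligand, receptor) pair both orientations are tried: the
    pair is a hit when one partner is a DEP (either direction) in the
    stroma contrast and the other in the epithelium contrast.  Hits are
    deduplicated by unordered pair; malformed pair-list rows are skipped
    and counted.
    """
    if pairs is None:
        pairs = load_lr_pairs()
    elif not isinstance(pairs, pd.DataFrame):
        pairs = pd.read_csv(Path(pairs), sep="\t")
    if not {"ligand", "receptor"} <= set(pairs.columns):
        raise ValueError("pair list needs 'ligand' and 'receptor' columns")

    s_status = stroma.table["status"]
    e_status = epithelium.table["status"]
    s_fc = stroma.table["log2fc"]
    e_fc = epithelium.table["log2fc"]

    def is_dep(status: pd.Series, protein: str) -> bool:
        return protein in status.index and status.loc[protein] in ("up", "down")

    rows = []
    seen: set[frozenset[str]] = set()
    n_malformed = 0
    n_screened = 0
    for ligand, receptor in pairs[["ligand", "receptor"]].itertuples(index=False):
        if (
            not isinstance(ligand, str)
            or not isinstance(receptor, str)
            or not ligand
            or not receptor
        ):
            n_malformed += 1
            continue
        n_screened += 1
        key = frozenset((ligand, receptor))
        if key in seen:
            continue
        for s_side, e_side in ((ligand, receptor), (receptor, ligand)):
            if is_dep(s_status, s_side) and is_dep(e_status, e_side):
                rows.append(
                    {
                        "ligand": ligand,
                        "receptor": receptor,
                        "stroma_partner": s_side,
                        "epithelium_partner": e_side,
                        "stroma_log2fc": float(s_fc.loc[s_side]),
                        "stroma_direction": s_status.loc[s_side],
                        "epithelium_log2fc": float(e_fc.loc[e_side]),
                        "epithelium_direction": e_status.loc[e_side],
                    }
                )
                seen.add(key)
                break
    cols = [
        "ligand",
        "receptor",
        "stroma_partner",
        "epithelium_partner",
        "stroma_log2fc",
        "stroma_direction",
        "epithelium_log2fc",
        "epithelium_direction",
    ]
    out = pd.DataFrame(rows, columns=cols)
    return LigandReceptorResult(
        table=out, n_pairs_screened=n_screened, n_malformed=n_malformed
    )


# ---------------------------------------------------------------------------
# Bundled placeholder resources


def load_stromal_signature() -> SignatureSet:
    """Bundled placeholder stromal marker signature (editable GMT).

    A compact list of canonical stromal/matrix proteins; replace with
    any externally curated signature via :func:`read_gmt`.
    """
    with resources.as_file(
        resources.files("stromacomp.data").joinpath("stromal_signature.gmt")
    ) as path:
        return read_gmt(path)


def load_lr_pairs() -> pd.DataFrame:
    """Bundled placeholder ligand-receptor pair list (editable TSV)."""
    with resources.as_file(
        resources.files("stromacomp.data").joinpath("lr_pairs.tsv")
    ) as path:
        return pd.read_csv(path, sep="\t")
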