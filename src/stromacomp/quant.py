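"""Protein quantification tables, sample annotations, and preprocessing.

The central container is :class:`QuantTable`, a wide protein x sample
abundance matrix with explicit missing values (``NaN``), carrying a scale
flag (``linear`` instrument-style intensities or ``log2``).  Sample
metadata live in a :class:`SampleSheet` (patient, preparation, compartment,
disease stage).

Preprocessing follows the standard label-free workflow: log2 transform,
equalize-medians global normalization, a missing-frequency filter, and
EM-style iterative PCA imputation of the remaining missing cells.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QuantTable",
    "SampleSheet",
    "ImputationResult",
    "read_quant",
    "read_quant_table",
    "read_sample_sheet",
    "write_quant",
    "write_sample_sheet",
    "log2_transform",
    "median_normalize",
    "filter_by_missingness",
    "impute_pca",
    "preprocess_groups",
]

VALID_SCALES = ("linear", "log2")
PREPARATIONS = ("bulk", "LCM")
COMPARTMENTS = ("epithelium", "stroma", "mixed")
STAGES = ("adjacent", "adenoma", "carcinoma")

#: strings parsed as missing cells in TSV/CSV input (never zero-filled)
MISSING_TOKENS = ("", "NA", "NaN", "nan")


@dataclasses.dataclass
class QuantTable:
    """Protein x sample abundance matrix with explicit missingness.

    Parameters
    ----------
    data:
        DataFrame indexed by protein ID with sample IDs as columns.
        ``NaN`` marks a protein not detected in a sample.
    scale:
        ``"linear"`` (positive intensities) or ``"log2"``.
    peptide_counts:
        Optional per-protein count of supporting peptides.
    """

    data: pd.DataFrame
    scale: str = "linear"
    peptide_counts: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein IDs: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        self.data = self.data.astype(float)
        self.data.index.name = "protein"
        self.data.columns.name = None
        if self.scale == "linear":
            vals = self.data.to_numpy()
            observed = vals[np.isfinite(vals)]
            if observed.size and observed.min() <= 0:
                raise ValueError("linear-scale abundances must be strictly positive")
        if self.peptide_counts is not None:
            self.peptide_counts = self.peptide_counts.reindex(self.data.index)

    # -- basic views -------------------------------------------------------

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def detected(self) -> pd.DataFrame:
        """Boolean mask of observed (non-missing) cells."""
        return self.data.notna()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    def subset(
        self,
        samples: Sequence[str] | None = None,
        proteins: Sequence[str] | None = None,
    ) -> "QuantTable":
        data = self.data
        if proteins is not None:
            missing = set(proteins) - set(data.index)
            if missing:
                raise KeyError(f"unknown proteins: {sorted(missing)}")
            data = data.loc[list(proteins)]
        if samples is not None:
            missing = set(samples) - set(data.columns)
            if missing:
                raise KeyError(f"unknown samples: {sorted(missing)}")
            data = data[list(samples)]
        return QuantTable(data.copy(), scale=self.scale, peptide_counts=self.peptide_counts)


@dataclasses.dataclass
class SampleSheet:
    """Per-sample annotations: patient, preparation, compartment, stage.

    The table is indexed by sample ID.  Bulk preparations carry
    compartment ``mixed`` (a bulk section contains both epithelium and
    stroma); LCM samples are ``epithelium`` or ``stroma``.
    """

    table: pd.DataFrame

    REQUIRED = ("patient_id", "preparation", "compartment", "stage")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs in sheet: {dups}")
        for col, allowed in (
            ("preparation", PREPARATIONS),
            ("compartment", COMPARTMENTS),
            ("stage", STAGES),
        ):
            bad = set(self.table[col]) - set(allowed)
            if bad:
                raise ValueError(f"invalid {col} values: {sorted(bad)}")
        bulk = self.table["preparation"] == "bulk"
        if (self.table.loc[bulk, "compartment"] != "mixed").any():
            raise ValueError("bulk samples must have compartment 'mixed'")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def patients(self) -> list[str]:
        return sorted(self.table["patient_id"].unique())

    def samples_where(self, **conditions: str | Sequence[str]) -> list[str]:
        """Sample IDs matching every given column==value (or value-in-list)."""
        mask = pd.Series(True, index=self.table.index)
        for col, value in conditions.items():
            if col not in self.table.columns:
                raise KeyError(f"unknown sample-sheet column {col!r}")
            if isinstance(value, str):
                mask &= self.table[col] == value
            else:
                mask &= self.table[col].isin(list(value))
        return list(self.table.index[mask])

    def validate_against(self, table: QuantTable) -> None:
        unknown = [s for s in table.sample_ids if s not in self.table.index]
        if unknown:
            raise ValueError(
                f"samples in quantification matrix absent from sample sheet: {unknown}"
            )


# ---------------------------------------------------------------------------
# I/O


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_quant_table(path: str | Path, scale: str = "linear") -> QuantTable:
    """Read a wide protein x sample matrix (first column = protein ID).

    Empty cells and ``NA`` parse as missing; values are never zero-filled.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
    )
    return QuantTable(df, scale=scale)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    return SampleSheet(df)


def read_quant(
    path: str | Path, sheet_path: str | Path, scale: str = "linear"
) -> tuple[QuantTable, SampleSheet]:
    """Read a quantification matrix together with its sample sheet.

    Every matrix column must be annotated in the sheet; offenders are
    named in the error.
    """
    table = read_quant_table(path, scale=scale)
    sheet = read_sample_sheet(sheet_path)
    sheet.validate_against(table)
    return table, sheet


def write_quant(table: QuantTable, path: str | Path) -> None:
    path = Path(path)
    table.data.to_csv(path, sep=_sep_for(path), index_label="protein", na_rep="")


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    path = Path(path)
    sheet.table.to_csv(path, sep=_sep_for(path), index_label="sample_id")


# ---------------------------------------------------------------------------
# Preprocessing


def log2_transform(table: QuantTable) -> QuantTable:
    """Log2-transform a linear-scale table; missing cells stay missing."""
    if table.scale != "linear":
        raise ValueError("log2_transform requires a linear-scale table")
    vals = table.data.to_numpy()
    observed = vals[np.isfinite(vals)]
    if observed.size and observed.min() <= 0:
        raise ValueError("cannot log-transform non-positive abundances")
    return QuantTable(
        np.log2(table.data), scale="log2", peptide_counts=table.peptide_counts
    )


def median_normalize(table: QuantTable) -> QuantTable:
    """Equalize sample medians on the log2 scale.

    Each sample is shifted so that its median over observed values equals
    the global median of the pre-shift sample medians.  Within-sample
    differences are untouched, making the operation idempotent.
    """
    if table.scale != "log2":
        raise ValueError("median_normalize operates on log2-scale tables")
    medians = table.data.median(axis=0, skipna=True)
    if medians.isna().any():
        empty = medians.index[medians.isna()].tolist()
        raise ValueError(f"samples with no observed values: {empty}")
    target = float(medians.median())
    shifted = table.data.sub(medians - target, axis=1)
    return QuantTable(shifted, scale="log2", peptide_counts=table.peptide_counts)


def filter_by_missingness(
    table: QuantTable,
    max_missing_frac: float = 0.5,
    within: Sequence[str] | None = None,
) -> QuantTable:
    """Keep proteins whose missing fraction is strictly below the threshold.

    The fraction is evaluated over ``within`` (default: all samples).  The
    comparison is strict — a protein missing in exactly half the samples is
    removed at the default 0.5 threshold.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    cols = list(within) if within is not None else table.sample_ids
    if not cols:
        raise ValueError("empty sample subset for missingness filter")
    unknown = set(cols) - set(table.sample_ids)
    if unknown:
        raise KeyError(f"unknown samples in subset: {sorted(unknown)}")
    frac = table.data[cols].isna().mean(axis=1)
    keep = frac < max_missing_frac
    return QuantTable(
        table.data.loc[keep].copy(), scale=table.scale, peptide_counts=table.peptide_counts
    )


@dataclasses.dataclass
class ImputationResult:
    """Imputed table plus convergence diagnostics."""

    table: QuantTable
    converged: bool
    n_iter: int


def impute_pca(
    table: QuantTable,
    n_components: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ImputationResult:
    """Impute missing cells by iterative truncated-SVD reconstruction.

    EM-style loop: fill missing cells with current estimates (initialized
    at protein means), reconstruct the protein-centered matrix at rank
    ``n_components``, and update only the originally-missing cells, until
    the relative change of the imputed cells drops below ``tol``.
    Observed cells are returned bit-identical.  Non-convergence sets a
    flag (and warns) rather than raising.
    """
    if table.scale != "log2":
        raise ValueError("impute_pca expects a log2-scale table")
    n_p, n_s = table.shape
    if n_components >= min(n_p, n_s):
        raise ValueError(
            f"n_components={n_components} must be < min(n_proteins, n_samples)={min(n_p, n_s)}"
        )
    X = table.data.to_numpy().copy()
    mask = np.isnan(X)
    if not mask.any():
        return ImputationResult(table, True, 0)
    if mask.all(axis=1).any():
        raise ValueError("protein with no observed values; filter before imputing")

    row_means = np.nanmean(X, axis=1)
    filled = X.copy()
    filled[mask] = np.broadcast_to(row_means[:, None], X.shape)[mask]

    converged = False
    it = 0
    prev = filled[mask].copy()
    for it in range(1, max_iter + 1):
        mu = filled.mean(axis=1, keepdims=True)
        centered = filled - mu
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        recon = mu + (U[:, :n_components] * s[:n_components]) @ Vt[:n_components]
        new = recon[mask]
        denom = max(float(np.linalg.norm(prev)), 1e-12)
        delta = float(np.linalg.norm(new - prev)) / denom
        filled[mask] = new
        prev = new.copy()
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"PCA imputation did not converge in {max_iter} iterations", RuntimeWarning
        )
    out = X.copy()
    out[mask] = filled[mask]  # observed entries untouched by construction
    imputed = QuantTable(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        scale="log2",
        peptide_counts=table.peptide_counts,
    )
    return ImputationResult(imputed, converged, it)


def preprocess_groups(
    table: QuantTable,
    sheet: SampleSheet,
    group_by: Sequence[str] = ("compartment", "preparation"),
    max_missing_frac: float = 0.5,
    impute: bool = True,
    n_components: int = 5,
    joint_normalize: bool = False,
) -> dict[tuple[str, ...], QuantTable]:
    """Log2 + normalize + filter (+ optionally impute) per analysis group.

    The missing-frequency filter is applied within each group (default:
    each compartment x preparation combination) so that, e.g., stroma-only
    analyses are not constrained by epithelium coverage.  With
    ``joint_normalize`` the median shift is computed once across all
    samples instead of per group.
    """
    sheet.validate_against(table)
    logged = log2_transform(table) if table.scale == "linear" else table
    if joint_normalize:
        logged = median_normalize(logged)
    meta = sheet.table.loc[table.sample_ids]
    out: dict[tuple[str, ...], QuantTable] = {}
    for key, sub in meta.groupby(list(group_by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        samples = list(sub.index)
        group_table = logged.subset(samples=samples)
        if not joint_normalize:
            group_table = median_normalize(group_table)
        group_table = filter_by_missingness(group_table, max_missing_frac)
        if impute and group_table.n_missing and min(group_table.shape) > n_components:
            group_table = impute_pca(group_table, n_components=n_components).table
        out[key] = group_table
    return out
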