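"""Four-criterion stromal biomarker panel selection.

A candidate stromal biomarker must (1) never be observed in any
epithelium sample of any stage, (2) be co-identified in more than 80% of
the patients contributing stroma samples (strict "over 80%"), (3) be an
up-called DEP of tumor stroma versus adjacent stroma in adenoma and/or
carcinoma, and (4) sit in the top 80% of stroma proteins by median
abundance while being supported by at least two peptides.  Every
criterion is audited separately so the final verdict is a transparent
conjunction.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import ContrastResult
from .quant import QuantTable, SampleSheet

__all__ = ["BiomarkerCriteria", "PanelResult", "select_biomarkers"]


@dataclasses.dataclass(frozen=True)
class BiomarkerCriteria:
    """Tunable thresholds of the four-way stromal biomarker filter.

    ``rank_mode`` resolves the ambiguity in "abundance ranked within 80%
    of total proteins": ``"top"`` (default) keeps proteins in the top
    ``max_rank_frac`` of the abundance ranking (dropping the
    lowest-abundance tail), while ``"bottom"`` keeps the complementary
    reading (rank at or above the ``1 - max_rank_frac`` quantile from
    the bottom).  ``strict_peptides`` switches the peptide gate from
    >= to > ``min_peptides``.
    """

    require_stroma_unique: bool = True
    min_patient_frac: float = 0.8
    require_dep_in: tuple[str, ...] = ("adenoma", "carcinoma")
    max_rank_frac: float = 0.8
    min_peptides: int = 2
    strict_peptides: bool = False
    rank_mode: str = "top"

    def __post_init__(self) -> None:
        if not 0 < self.min_patient_frac <= 1:
            raise ValueError("min_patient_frac must lie in (0, 1]")
        if not 0 < self.max_rank_frac <= 1:
            raise ValueError("max_rank_frac must lie in (0, 1]")
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")
        if self.rank_mode not in ("top", "bottom"):
            raise ValueError("rank_mode must be 'top' or 'bottom'")


@dataclasses.dataclass
class PanelResult:
    """Per-candidate criterion audit plus the passing panel."""

    audit: pd.DataFrame
    panel: set[str]
    criteria: BiomarkerCriteria


def select_biomarkers(
    stroma_table: QuantTable,
    epithelium_table: QuantTable,
    sheet: SampleSheet,
    contrasts: Mapping[str, ContrastResult],
    peptide_counts: pd.Series | None = None,
    criteria: BiomarkerCriteria = BiomarkerCriteria(),
) -> PanelResult:
    """Evaluate every stroma-observed protein against the four criteria.

    Parameters
    ----------
    stroma_table, epithelium_table:
        Quantification restricted to stroma / epithelium samples.
    contrasts:
        Stage -> tumor-stroma-vs-adjacent-stroma :class:`ContrastResult`;
        must cover every stage named in ``criteria.require_dep_in``.
    peptide_counts:
        Per-protein supporting-peptide counts; falls back to
        ``stroma_table.peptide_counts``.
    """
    for stage in criteria.require_dep_in:
        if stage not in contrasts:
            raise ValueError(f"criteria require a contrast for stage {stage!r}")
    if peptide_counts is None:
        peptide_counts = stroma_table.peptide_counts
    if peptide_counts is None:
        raise ValueError("peptide counts are required for the abundance/peptide gate")

    observed_stroma = stroma_table.detected()
    candidates = list(observed_stroma.index[observed_stroma.any(axis=1)])
    if not candidates:
        raise ValueError("no proteins observed in stroma")
    missing_pep = [p for p in candidates if p not in peptide_counts.index or pd.isna(peptide_counts[p])]
    if missing_pep:
        raise ValueError(f"peptide counts missing for candidates: {missing_pep[:5]}")

    # criterion 1: stroma-unique across every epithelium sample of any stage
    epi_detected = epithelium_table.detected()
    seen_in_epi = epi_detected.reindex(candidates).fillna(False).any(axis=1)
    c1 = ~seen_in_epi

    # criterion 2: patient prevalence over patients with >= 1 stroma sample
    stroma_patients = sheet.table.loc[stroma_table.sample_ids, "patient_id"]
    n_patients = stroma_patients.nunique()
    per_patient = observed_stroma.loc[candidates].T.groupby(stroma_patients).any()
    prevalence = per_patient.sum(axis=0) / n_patients
    c2 = prevalence > criteria.min_patient_frac  # strict "over 80%"

    # criterion 3: up-called DEP in the designated stroma contrast(s), OR semantics
    up_any = pd.Series(False, index=candidates)
    for stage in criteria.require_dep_in:
        status = contrasts[stage].table["status"].reindex(candidates)
        up_any |= status.eq("up").fillna(False)
    c3 = up_any

    # criterion 4: abundance rank window AND peptide support
    medians = stroma_table.data.loc[candidates].median(axis=1, skipna=True)
    order = (
        medians.rename("median")
        .rename_axis("protein")
        .reset_index()
        .sort_values(["median", "protein"], ascending=[False, True], kind="mergesort")
    )
    position = pd.Series(
        np.arange(1, len(order) + 1), index=order["protein"].to_numpy()
    )
    rank_frac = position / len(candidates)
    if criteria.rank_mode == "top":
        rank_ok = rank_frac <= criteria.max_rank_frac
    else:
        rank_ok = rank_frac >= 1.0 - criteria.max_rank_frac
    peps = peptide_counts.reindex(candidates)
    pep_ok = peps > criteria.min_peptides if criteria.strict_peptides else peps >= criteria.min_peptides
    c4 = rank_ok.reindex(candidates) & pep_ok

    audit = pd.DataFrame(
        {
            "stroma_unique": c1,
            "patient_prevalence": c2,
            "dep_up": c3,
            "abundance_rank": c4,
            "prevalence_frac": prevalence,
            "rank_frac": rank_frac.reindex(candidates),
            "n_peptides": peps,
        },
        index=pd.Index(candidates, name="protein"),
    )
    conjuncts = ["patient_prevalence", "dep_up", "abundance_rank"]
    if criteria.require_stroma_unique:
        conjuncts = ["stroma_unique"] + conjuncts
    audit["selected"] = audit[conjuncts].all(axis=1)
    panel = set(audit.index[audit["selected"]])
    return PanelResult(audit=audit, panel=panel, criteria=criteria)
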