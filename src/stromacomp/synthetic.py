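"""Synthetic LCM-DIA cohort generator with planted ground truth.

Emulates the structure of a laser-capture-microdissection DIA proteomics
cohort: per-protein baseline log2 intensities, patient-level random
effects shared across all tissues of a patient (supporting paired
analyses), stage x compartment abundance effects for planted protein
sets, stroma-unique marker proteins, abundance-dependent (MNAR)
detection with a compartment depth offset (stroma identifies fewer
proteins), and stage-dependent noise inflation in tumor tissue.  The
matrix is simulated on the log2 scale and exported as linear
intensities with explicit missing cells, since the pipeline's first
step is its own log transform.

The default configuration plants the study's headline structure:
adenoma and carcinoma stroma receive *identical* stage effects (one
shared tumor-microenvironment shift), while epithelium effects are
stage-specific — so downstream analyses should find almost no
adenoma-vs-carcinoma DEPs in stroma but many in epithelium.

A companion generator builds immune-cell mixtures from a reference
signature matrix for testing fraction deconvolution.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concordance import rank_bins
from .differential import ContrastResult
from .quant import QuantTable, SampleSheet
from .signatures import SignatureMatrix

__all__ = [
    "PlantedEffect",
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "default_cohort_config",
    "planted_recovery_config",
    "simulate_signature_matrix",
    "generate_mixtures",
    "biomarker_audit_fixture",
    "random_biomarker_fixture",
]

STAGE_CONTRASTS = {
    "AN": ("adenoma", "adjacent"),
    "CN": ("carcinoma", "adjacent"),
    "CA": ("carcinoma", "adenoma"),
}


@dataclasses.dataclass(frozen=True)
class PlantedEffect:
    """A log2 abundance shift applied to a protein set in one context."""

    proteins: tuple[str, ...]
    stage: str
    compartment: str
    log2_effect: float


def _default_noise_scale() -> dict[str, float]:
    # tumor tissue is noisier than adjacent (heterogeneity of the lesion)
    return {"adjacent": 1.0, "adenoma": 1.4, "carcinoma": 1.6}


def _default_depth_offsets() -> dict[str, float]:
    # stroma yields fewer identifications at equal abundance
    return {"epithelium": 0.0, "stroma": -2.0}


@dataclasses.dataclass
class CohortConfig:
    """Generative parameters of a synthetic LCM-DIA cohort.

    Log2-intensity model per protein p and sample s:

        x[p, s] = mu_p + compartment_shift + gamma(stage, compartment, p)
                  + u_patient + eps,   eps ~ N(0, (noise_sd * stage_scale)^2)

    followed by logistic MNAR censoring
    P(detect) = 1 / (1 + exp(-k (x - m0 + depth_offset))).
    """

    n_patients: int = 22
    n_proteins: int = 5500
    stages: tuple[str, ...] = ("adjacent", "adenoma", "carcinoma")
    compartments: tuple[str, ...] = ("epithelium", "stroma")
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    patient_sd: float = 0.5
    noise_sd: float = 0.3
    noise_scale_by_stage: dict[str, float] = dataclasses.field(
        default_factory=_default_noise_scale
    )
    compartment_shift: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"epithelium": 0.0, "stroma": 0.0}
    )
    planted_effects: tuple[PlantedEffect, ...] = ()
    stroma_unique: tuple[str, ...] = ()
    detect_midpoint: float | None = None  # default baseline_mean - 2
    detect_steepness: float = 1.0
    depth_offsets: dict[str, float] = dataclasses.field(
        default_factory=_default_depth_offsets
    )
    n_celltypes: int = 9
    seed: int = 0

    @property
    def protein_ids(self) -> list[str]:
        return [f"PROT{i:05d}" for i in range(self.n_proteins)]

    @property
    def midpoint(self) -> float:
        return (
            self.baseline_mean - 2.0
            if self.detect_midpoint is None
            else self.detect_midpoint
        )

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_proteins <= 0:
            raise ValueError("n_patients and n_proteins must be positive")
        if self.n_celltypes < 2:
            raise ValueError("n_celltypes must be >= 2")
        for name in ("baseline_sd", "patient_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        known = set(self.protein_ids)
        unique = set(self.stroma_unique)
        if unique - known:
            raise ValueError(
                f"stroma_unique references unknown proteins: {sorted(unique - known)[:5]}"
            )
        for eff in self.planted_effects:
            members = set(eff.proteins)
            if members - known:
                raise ValueError(
                    f"effect references unknown proteins: {sorted(members - known)[:5]}"
                )
            if members & unique:
                raise ValueError("effect sets must be disjoint from stroma_unique")
            if eff.stage not in self.stages or eff.compartment not in self.compartments:
                raise ValueError(
                    f"effect context ({eff.stage}, {eff.compartment}) not in cohort"
                )


@dataclasses.dataclass
class GroundTruth:
    """Planted truth of a generated cohort (plain containers, JSON-safe).

    ``true_dep_sets`` maps contrast labels like ``"stroma:AN"`` to
    {protein: signed log2 effect}; ``true_bins`` maps context labels like
    ``"adenoma:stroma"`` to sextile indices of the noiseless expected
    abundances; ``stromal_signature`` lists proteins enriched in stroma
    at every stage (including the stroma-unique markers) — a planted
    analogue of a stromal marker signature; ``true_fractions`` (mixture
    cohorts only) maps sample -> cell-type proportion list.
    """

    seed: int
    true_dep_sets: dict[str, dict[str, float]]
    true_bins: dict[str, dict[str, int]]
    stroma_unique: list[str]
    stromal_signature: list[str] = dataclasses.field(default_factory=list)
    true_fractions: dict[str, list[float]] | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruth":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(**payload)


def _sample_frame(config: CohortConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_patients):
        patient = f"PT{i + 1:02d}"
        for stage in config.stages:
            for comp in config.compartments:
                sid = f"{patient}-{stage}-{comp}"
                rows.append((sid, patient, "LCM", comp, stage))
    df = pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "preparation", "compartment", "stage"]
    ).set_index("sample_id")
    return df


def generate_cohort(
    config: CohortConfig,
) -> tuple[QuantTable, SampleSheet, GroundTruth]:
    """Simulate a cohort; identical config + seed gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    proteins = config.protein_ids
    p_index = {p: i for i, p in enumerate(proteins)}
    meta = _sample_frame(config)
    n_p, n_s = config.n_proteins, len(meta)

    mu = rng.normal(config.baseline_mean, config.baseline_sd, n_p)
    patients = sorted(meta["patient_id"].unique())
    u = dict(zip(patients, rng.normal(0.0, config.patient_sd, len(patients))))

    # per-(stage, compartment) planted effect vectors
    gamma: dict[tuple[str, str], np.ndarray] = {
        (st, co): np.zeros(n_p) for st in config.stages for co in config.compartments
    }
    for eff in config.planted_effects:
        idx = [p_index[p] for p in eff.proteins]
        gamma[(eff.stage, eff.compartment)][idx] += eff.log2_effect

    X = np.empty((n_p, n_s))
    noise_sds = np.empty(n_s)
    for j, (sid, row) in enumerate(meta.iterrows()):
        stage, comp = row["stage"], row["compartment"]
        scale = config.noise_scale_by_stage.get(stage, 1.0)
        noise_sds[j] = config.noise_sd * scale
        X[:, j] = (
            mu
            + config.compartment_shift.get(comp, 0.0)
            + gamma[(stage, comp)]
            + u[row["patient_id"]]
        )
    X += rng.normal(0.0, 1.0, (n_p, n_s)) * noise_sds[None, :]

    # logistic MNAR detection with compartment depth offsets
    offsets = np.array(
        [config.depth_offsets.get(c, 0.0) for c in meta["compartment"]]
    )
    logit = config.detect_steepness * (X - config.midpoint + offsets[None, :])
    p_detect = 1.0 / (1.0 + np.exp(-logit))
    detected = rng.random((n_p, n_s)) < p_detect

    # stroma-unique markers never appear outside stroma
    if config.stroma_unique:
        unique_idx = [p_index[p] for p in config.stroma_unique]
        not_stroma = (meta["compartment"] != "stroma").to_numpy()
        detected[np.ix_(unique_idx, np.flatnonzero(not_stroma))] = False

    linear = np.power(2.0, X)
    linear[~detected] = np.nan
    data = pd.DataFrame(linear, index=proteins, columns=meta.index)

    # supporting-peptide counts scale loosely with baseline abundance
    lam = np.clip(2.0 + (mu - config.baseline_mean) / 2.0, 0.3, 12.0)
    peptide_counts = pd.Series(1 + rng.poisson(lam), index=proteins, name="n_peptides")

    table = QuantTable(data, scale="linear", peptide_counts=peptide_counts)
    sheet = SampleSheet(meta)

    truth = _build_truth(config, mu, gamma)
    return table, sheet, truth


def _build_truth(
    config: CohortConfig,
    mu: np.ndarray,
    gamma: Mapping[tuple[str, str], np.ndarray],
) -> GroundTruth:
    proteins = config.protein_ids
    dep_sets: dict[str, dict[str, float]] = {}
    for comp in config.compartments:
        for code, (hi, lo) in STAGE_CONTRASTS.items():
            if hi not in config.stages or lo not in config.stages:
                continue
            diff = gamma[(hi, comp)] - gamma[(lo, comp)]
            nz = np.flatnonzero(diff != 0.0)
            dep_sets[f"{comp}:{code}"] = {proteins[i]: float(diff[i]) for i in nz}
    bins: dict[str, dict[str, int]] = {}
    unique = set(config.stroma_unique)
    for stage in config.stages:
        for comp in config.compartments:
            expected = mu + config.compartment_shift.get(comp, 0.0) + gamma[(stage, comp)]
            means = pd.Series(expected, index=proteins)
            if comp != "stroma" and unique:
                means = means.drop(labels=list(unique))
            if len(means) >= 6:
                assignment = rank_bins(means, k=6, context=f"{stage}:{comp}")
                bins[f"{stage}:{comp}"] = {
                    p: int(b) for p, b in assignment.bins.items()
                }
    # stroma-enriched at every stage (and absent/never higher in epithelium)
    signature = set(unique)
    if "stroma" in config.compartments:
        g_stroma = np.min(
            [gamma[(st, "stroma")] for st in config.stages], axis=0
        )
        if "epithelium" in config.compartments:
            g_epi = np.max(
                [gamma[(st, "epithelium")] for st in config.stages], axis=0
            )
        else:
            g_epi = np.zeros_like(g_stroma)
        shift = config.compartment_shift.get("stroma", 0.0) - config.compartment_shift.get(
            "epithelium", 0.0
        )
        enriched = np.flatnonzero(g_stroma + shift >= 1.0)
        signature |= {proteins[i] for i in enriched if g_epi[i] <= 0.0}
    return GroundTruth(
        seed=config.seed,
        true_dep_sets=dep_sets,
        true_bins=bins,
        stroma_unique=sorted(unique),
        stromal_signature=sorted(signature),
    )


# ---------------------------------------------------------------------------
# Canned configurations


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """Paper-scale default cohort with the headline planted structure.

    22 patients with epithelium + stroma at each of the three stages;
    5,500 simulated proteins so that logistic MNAR censoring leaves
    roughly 3,500-4,000 identified per epithelium sample and 2,500-3,000
    per stroma sample.  Stroma stage effects are identical for adenoma
    and carcinoma (one shared tumor-microenvironment shift); epithelium
    effects are stage-specific and disjoint.
    """
    base = CohortConfig(seed=seed)
    n = overrides.get("n_proteins", base.n_proteins)
    ids = [f"PROT{i:05d}" for i in range(n)]
    rng = np.random.default_rng(seed + 7_654_321)
    # planted set sizes scale with cohort size (reference: 5,500 proteins)
    sizes = [max(5, round(s * n / 5500)) for s in (250, 120, 250, 150, 120)]
    bounds = np.cumsum([0] + sizes)
    picked = rng.choice(n, size=int(bounds[-1]), replace=False)
    stroma_set = [ids[i] for i in picked[bounds[0] : bounds[1]]]
    epi_adenoma = [ids[i] for i in picked[bounds[1] : bounds[2]]]
    epi_carcinoma = [ids[i] for i in picked[bounds[2] : bounds[3]]]
    stroma_unique = tuple(ids[i] for i in picked[bounds[3] : bounds[4]])
    stroma_enriched = tuple(ids[i] for i in picked[bounds[4] : bounds[5]])

    def split(members: list[str], frac_up: float) -> tuple[tuple[str, ...], tuple[str, ...]]:
        n_up = int(round(frac_up * len(members)))
        return tuple(members[:n_up]), tuple(members[n_up:])

    s_up, s_down = split(stroma_set, 0.6)
    ea_up, ea_down = split(epi_adenoma, 0.65)
    ec_up, ec_down = split(epi_carcinoma, 0.65)

    effects: list[PlantedEffect] = []
    for stage in ("adenoma", "carcinoma"):  # identical stroma shift in both
        effects.append(PlantedEffect(s_up, stage, "stroma", +3.0))
        effects.append(PlantedEffect(s_down, stage, "stroma", -3.0))
    effects.append(PlantedEffect(ea_up, "adenoma", "epithelium", +3.0))
    effects.append(PlantedEffect(ea_down, "adenoma", "epithelium", -3.0))
    effects.append(PlantedEffect(ec_up, "carcinoma", "epithelium", +3.0))
    effects.append(PlantedEffect(ec_down, "carcinoma", "epithelium", -3.0))
    # stroma-enriched signature proteins: the same shift at every stage,
    # so they separate compartments but cancel in stroma stage contrasts
    for stage in ("adjacent", "adenoma", "carcinoma"):
        effects.append(PlantedEffect(stroma_enriched, stage, "stroma", +2.0))

    params = dict(
        planted_effects=tuple(effects),
        stroma_unique=stroma_unique,
        seed=seed,
    )
    params.update(overrides)
    return dataclasses.replace(base, **params)


def planted_recovery_config(
    seed: int = 0,
    n_proteins: int = 3000,
    n_patients: int = 15,
    n_dep: int = 300,
    effect: float = 3.0,
    frac_up: float = 0.6,
    noise_sd: float = 0.3,
) -> CohortConfig:
    """Two-group stroma cohort with a planted DEP set, for recovery studies.

    One compartment (stroma), stages adjacent vs adenoma, ``n_patients``
    paired samples per group.  The planted effects sit clearly above the
    four-fold calling threshold so that recovery failures indicate
    pipeline defects rather than borderline effect sizes.  Censoring is
    mild (midpoint four log2 units below baseline) so planted proteins
    stay testable.
    """
    ids = [f"PROT{i:05d}" for i in range(n_proteins)]
    rng = np.random.default_rng(seed + 1_234_567)
    picked = rng.choice(n_proteins, size=n_dep, replace=False)
    n_up = int(round(frac_up * n_dep))
    up = tuple(ids[i] for i in picked[:n_up])
    down = tuple(ids[i] for i in picked[n_up:])
    return CohortConfig(
        n_patients=n_patients,
        n_proteins=n_proteins,
        stages=("adjacent", "adenoma"),
        compartments=("stroma",),
        patient_sd=0.3,
        noise_sd=noise_sd,
        noise_scale_by_stage={"adjacent": 1.0, "adenoma": 1.0},
        planted_effects=(
            PlantedEffect(up, "adenoma", "stroma", +effect),
            PlantedEffect(down, "adenoma", "stroma", -effect),
        ),
        detect_midpoint=16.0,
        depth_offsets={"stroma": 0.0},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Immune mixtures


def simulate_signature_matrix(
    n_celltypes: int = 9,
    markers_per_type: int = 20,
    seed: int = 0,
    marker_fold: float = 30.0,
) -> SignatureMatrix:
    """Reference profiles with distinct markers per cell type.

    Every cell type expresses a shared positive background plus a block
    of strongly elevated marker proteins, giving a well-conditioned,
    identifiable mixing basis.
    """
    rng = np.random.default_rng(seed)
    n_prot = n_celltypes * markers_per_type
    base = rng.uniform(20.0, 100.0, size=(n_prot, n_celltypes))
    for t in range(n_celltypes):
        rows = slice(t * markers_per_type, (t + 1) * markers_per_type)
        base[rows, t] *= marker_fold
    proteins = [f"SIG{i:04d}" for i in range(n_prot)]
    types = [f"celltype_{t + 1}" for t in range(n_celltypes)]
    return SignatureMatrix(pd.DataFrame(base, index=proteins, columns=types))


def generate_mixtures(
    signature: SignatureMatrix,
    fractions: pd.DataFrame,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[QuantTable, GroundTruth]:
    """Linear mixtures of signature columns with multiplicative noise.

    Each sample equals ``signature @ fraction_vector`` times i.i.d.
    lognormal noise with the stated coefficient of variation (mean 1).
    Zero mixture intensities (possible when the signature contains exact
    zeros) are exported as missing.
    """
    if list(fractions.columns) != signature.cell_types:
        raise ValueError("fraction columns must match signature cell types")
    F = fractions.to_numpy(dtype=float)
    if (F < 0).any():
        raise ValueError("fractions must be non-negative")
    sums = F.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("fraction rows must sum to 1")
    S = signature.profiles.to_numpy(dtype=float)
    M = S @ F.T
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=M.shape)
        M = M * noise
    M = M.copy()
    M[M <= 0] = np.nan
    data = pd.DataFrame(M, index=signature.profiles.index, columns=fractions.index)
    truth = GroundTruth(
        seed=seed,
        true_dep_sets={},
        true_bins={},
        stroma_unique=[],
        true_fractions={s: [float(v) for v in row] for s, row in fractions.iterrows()},
    )
    return QuantTable(data, scale="linear"), truth


# ---------------------------------------------------------------------------
# Engineered fixtures for auditing the biomarker filter


def _contrast_from_status(
    label: str, status: Mapping[str, str], fc: float = 4.0
) -> ContrastResult:
    idx = list(status)
    up = {p: s == "up" for p, s in status.items()}
    table = pd.DataFrame(
        {
            "log2fc": [3.0 if up[p] else 0.1 for p in idx],
            "p": [1e-6 if up[p] else 0.5 for p in idx],
            "q": [1e-5 if up[p] else 0.6 for p in idx],
            "n_obs_a": 5,
            "n_obs_b": 5,
            "status": [status[p] for p in idx],
        },
        index=idx,
    )
    return ContrastResult(label, table, fc, 0.05, 3)


def biomarker_audit_fixture():
    """Eight engineered proteins, exactly three of which pass all criteria.

    Returns ``(stroma_table, epithelium_table, sheet, contrasts,
    expected_audit)``: B1-B3 satisfy every criterion; F1 is seen once in
    epithelium, F2 reaches a patient prevalence of exactly 0.8 (not
    *over* 80%), F3 is no DEP, F4 ranks in the lowest-abundance tail,
    F5 has a single supporting peptide (and also ranks low).
    """
    proteins = ["B1", "B2", "B3", "F1", "F2", "F3", "F5", "F4"]
    stroma_samples = [f"ST{i}" for i in range(1, 6)]
    epi_samples = [f"EP{i}" for i in range(1, 6)]
    medians = dict(zip(proteins, [10.0, 9.5, 9.0, 8.5, 8.0, 7.5, 7.0, 6.5]))

    stroma = pd.DataFrame(
        {s: [medians[p] for p in proteins] for s in stroma_samples}, index=proteins
    )
    stroma.loc["F2", "ST5"] = np.nan  # observed in 4 of 5 patients -> 0.8 exactly
    epi = pd.DataFrame(np.nan, index=proteins, columns=epi_samples)
    epi.loc["F1", "EP3"] = 8.5  # a single epithelium sighting vetoes criterion 1

    peptides = pd.Series(3, index=proteins)
    peptides.loc["F5"] = 1
    stroma_table = QuantTable(stroma, scale="log2", peptide_counts=peptides)
    epi_table = QuantTable(epi, scale="log2", peptide_counts=peptides)

    meta = pd.DataFrame(
        {
            "patient_id": [f"PT{i}" for i in range(1, 6)] * 2,
            "preparation": "LCM",
            "compartment": ["stroma"] * 5 + ["epithelium"] * 5,
            "stage": "carcinoma",
        },
        index=pd.Index(stroma_samples + epi_samples, name="sample_id"),
    )
    sheet = SampleSheet(meta)

    status_adenoma = {p: ("ns" if p == "F3" else "up") for p in proteins}
    status_carcinoma = {p: "ns" for p in proteins}
    contrasts = {
        "adenoma": _contrast_from_status("stroma:AN", status_adenoma),
        "carcinoma": _contrast_from_status("stroma:CN", status_carcinoma),
    }

    expected_audit = pd.DataFrame(
        {
            "stroma_unique": {p: p != "F1" for p in proteins},
            "patient_prevalence": {p: p != "F2" for p in proteins},
            "dep_up": {p: p != "F3" for p in proteins},
            "abundance_rank": {p: p not in ("F4", "F5") for p in proteins},
            "selected": {p: p in ("B1", "B2", "B3") for p in proteins},
        }
    )
    return stroma_table, epi_table, sheet, contrasts, expected_audit


def random_biomarker_fixture(seed: int, n_proteins: int = 12, n_patients: int = 4):
    """Random small stroma/epithelium fixture for panel property tests."""
    rng = np.random.default_rng(seed)
    proteins = [f"R{i:02d}" for i in range(n_proteins)]
    stroma_samples = [f"ST{i}" for i in range(n_patients)]
    epi_samples = [f"EP{i}" for i in range(n_patients)]
    stroma = pd.DataFrame(
        rng.normal(10, 2, (n_proteins, n_patients)),
        index=proteins,
        columns=stroma_samples,
    )
    stroma[rng.random(stroma.shape) < 0.3] = np.nan
    stroma.iloc[:, 0] = stroma.iloc[:, 0].fillna(9.0)  # keep every candidate observed
    epi = pd.DataFrame(
        rng.normal(10, 2, (n_proteins, n_patients)), index=proteins, columns=epi_samples
    )
    epi[rng.random(epi.shape) < 0.7] = np.nan
    peptides = pd.Series(rng.integers(1, 5, n_proteins), index=proteins)
    stroma_table = QuantTable(stroma, scale="log2", peptide_counts=peptides)
    epi_table = QuantTable(epi, scale="log2", peptide_counts=peptides)
    meta = pd.DataFrame(
        {
            "patient_id": [f"PT{i}" for i in range(n_patients)] * 2,
            "preparation": "LCM",
            "compartment": ["stroma"] * n_patients + ["epithelium"] * n_patients,
            "stage": "carcinoma",
        },
        index=pd.Index(stroma_samples + epi_samples, name="sample_id"),
    )
    sheet = SampleSheet(meta)
    contrasts = {}
    for stage in ("adenoma", "carcinoma"):
        status = {
            p: rng.choice(["up", "down", "ns"], p=[0.4, 0.2, 0.4]) for p in proteins
        }
        contrasts[stage] = _contrast_from_status(f"stroma:{stage}", status)
    return stroma_table, epi_table, sheet, contrasts
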