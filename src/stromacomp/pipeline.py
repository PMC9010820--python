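"""End-to-end orchestration: simulate/read -> preprocess -> analyses -> report.

A :class:`RunConfig` (buildable from TOML) names either an input
quantification matrix + sample sheet or a simulation block, plus the
threshold set: stage contrasts at |FC| > 4 / q < 0.05, compartment
contrasts at |FC| > 2 / q < 0.05, individual paired tissues at
|FC| >= 2.  :func:`run_pipeline` executes the stages in dependency
order, writes every intermediate table as TSV plus a versioned JSON
summary and a log recording each resolved threshold, and is
deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import biomarkers as bm
from . import concordance as cc
from . import differential as dd
from . import quant as q
from . import signatures as sg
from . import structure as st
from . import synthetic as syn

__all__ = ["RunConfig", "PipelineError", "ConfigError", "run_pipeline"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclasses.dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    # exactly one of (input_quant+input_sheet) or simulate
    input_quant: Path | None = None
    input_sheet: Path | None = None
    simulate: dict[str, Any] | None = None
    # thresholds (fold units / q / inclusive individual fold cut)
    stage_fc: float = 4.0
    stage_q: float = 0.05
    compartment_fc: float = 2.0
    compartment_q: float = 0.05
    individual_fc: float = 2.0
    min_obs: int = 3
    # preprocessing
    max_missing: float = 0.5
    n_components: int = 5
    impute_tol: float = 1e-4
    # modules
    n_modules: int = 3
    # optional signature inputs
    stromal_signature_gmt: Path | None = None
    lr_pairs_path: Path | None = None
    deconvolution_samples: int = 40

    def validate(self) -> None:
        has_input = self.input_quant is not None or self.input_sheet is not None
        if has_input and (self.input_quant is None or self.input_sheet is None):
            raise ConfigError("input mode needs both input_quant and input_sheet")
        if has_input == (self.simulate is not None):
            raise ConfigError(
                "exactly one of input paths or a simulate block must be given"
            )
        for name in ("stage_fc", "compartment_fc", "individual_fc"):
            if getattr(self, name) <= 1:
                raise ConfigError(f"{name} must exceed 1 (fold units)")
        for name in ("stage_q", "compartment_q", "max_missing"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must lie in (0, 1]")

    @classmethod
    def from_toml(cls, path: str | Path, seed: int | None = None,
                  outdir: str | Path | None = None) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        thresholds = raw.pop("thresholds", {})
        preprocess = raw.pop("preprocess", {})
        inputs = raw.pop("input", {})
        kwargs: dict[str, Any] = {}
        kwargs["outdir"] = Path(outdir if outdir is not None else raw.pop("outdir", "stromacomp_run"))
        kwargs["seed"] = int(seed if seed is not None else raw.pop("seed", 0))
        if inputs:
            kwargs["input_quant"] = Path(inputs["quant"])
            kwargs["input_sheet"] = Path(inputs["sheet"])
        if "simulate" in raw:
            kwargs["simulate"] = dict(raw.pop("simulate"))
        for key in ("stage_fc", "stage_q", "compartment_fc", "compartment_q",
                    "individual_fc", "min_obs"):
            if key in thresholds:
                kwargs[key] = thresholds[key]
        for key in ("max_missing", "n_components"):
            if key in preprocess:
                kwargs[key] = preprocess[key]
        for key in ("n_modules", "stromal_signature_gmt", "lr_pairs_path",
                    "deconvolution_samples"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        config = cls(**kwargs)
        config.validate()
        return config


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def write(self, msg: str) -> None:
        self.lines.append(msg)
        self.path.write_text("\n".join(self.lines) + "\n")


def _round(x: float, nd: int = 6) -> float:
    return float(round(float(x), nd))


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run all stages; returns (and writes) the JSON summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Log(outdir / "run.log")
    summary: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "thresholds": {
            "stage_fc": config.stage_fc,
            "stage_q": config.stage_q,
            "compartment_fc": config.compartment_fc,
            "compartment_q": config.compartment_q,
            "individual_fc": config.individual_fc,
            "min_obs": config.min_obs,
            "max_missing": config.max_missing,
        },
    }
    log.write(f"resolved thresholds: {json.dumps(summary['thresholds'], sort_keys=True)}")

    # -- stage: data -------------------------------------------------------
    stage = "data"
    try:
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            cohort_cfg = syn.default_cohort_config(seed=config.seed, **sim_kwargs)
            table, sheet, truth = syn.generate_cohort(cohort_cfg)
            q.write_quant(table, outdir / "quant.tsv")
            q.write_sample_sheet(sheet, outdir / "samples.tsv")
            truth.to_json(outdir / "ground_truth.json")
            log.write(
                f"simulated cohort: {table.shape[0]} proteins x {table.shape[1]} samples"
            )
        else:
            table, sheet = q.read_quant(config.input_quant, config.input_sheet)
            truth = None
            log.write(f"read cohort: {table.shape[0]} proteins x {table.shape[1]} samples")
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001
        log.write(f"ERROR in stage {stage}: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    compartments = [c for c in ("epithelium", "stroma")
                    if sheet.samples_where(compartment=c)]
    stages_present = sorted(
        sheet.table["stage"].unique(), key=list(q.STAGES).index
    )

    # -- stage: preprocess -------------------------------------------------
    stage = "preprocess"
    try:
        logged = q.log2_transform(table) if table.scale == "linear" else table
        joint = q.median_normalize(logged)
        norm: dict[str, q.QuantTable] = {}
        filtered: dict[str, q.QuantTable] = {}
        imputed: dict[str, q.QuantTable] = {}
        for comp in compartments:
            samples = sheet.samples_where(compartment=comp)
            comp_table = q.median_normalize(logged.subset(samples=samples))
            norm[comp] = comp_table
            filt = q.filter_by_missingness(comp_table, config.max_missing)
            filtered[comp] = filt
            if filt.n_missing and min(filt.shape) > config.n_components:
                filt = q.impute_pca(
                    filt, n_components=config.n_components, tol=config.impute_tol
                ).table
            imputed[comp] = filt
            log.write(
                f"preprocess[{comp}]: {norm[comp].shape[0]} proteins, "
                f"{filtered[comp].shape[0]} pass missingness filter"
            )
    except Exception as exc:  # noqa: BLE001
        log.write(f"ERROR in stage {stage}: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: qc ---------------------------------------------------------
    stage = "qc"
    try:
        per_sample, per_group = st.identification_counts(table, sheet)
        per_sample.to_csv(outdir / "identification_counts.tsv", sep="\t")
        summary["identification"] = {
            " x ".join(map(str, k)): _round(v)
            for k, v in per_group["mean"].items()
        }
        rho_summaries = {}
        for comp in compartments:
            for stg in stages_present:
                samples = sheet.samples_where(compartment=comp, stage=stg)
                if len(samples) < 2:
                    continue
                cs = st.pairwise_spearman(
                    norm[comp], samples, min_overlap=50, group=f"{comp}:{stg}"
                )
                rho_summaries[f"{comp}:{stg}"] = _round(cs.median_rho, 4)
        summary["median_spearman"] = rho_summaries
        embeddings = {}
        for comp in compartments:
            emb = st.pca_embedding(imputed[comp], k=2)
            emb.coordinates.to_csv(outdir / f"pca_{comp}.tsv", sep="\t")
            embeddings[comp] = [_round(v, 4) for v in emb.explained_variance_ratio]
        summary["pca_explained_variance"] = embeddings
        log.write(f"qc: correlations for {len(rho_summaries)} groups")
    except Exception as exc:  # noqa: BLE001
        log.write(f"ERROR in stage {stage}: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: dep --------------------------------------------------------
    stage = "dep"
    contrast_results: dict[str, dd.ContrastResult] = {}
    try:
        for comp in compartments:
            for code, (hi, lo) in syn.STAGE_CONTRASTS.items():
                if hi not in stages_present or lo not in stages_present:
                    continue
                ga = sheet.samples_where(compartment=comp, stage=hi)
                gb = sheet.samples_where(compartment=comp, stage=lo)
                res = dd.call_deps(
                    filtered[comp], ga, gb, label=f"{comp}:{code}",
                    fc_threshold=config.stage_fc, q_threshold=config.stage_q,
                    min_obs=config.min_obs,
                )
                contrast_results[res.label] = res
        if len(compartments) == 2:
            for stg in stages_present:
                ga = sheet.samples_where(compartment="stroma", stage=stg)
                gb = sheet.samples_where(compartment="epithelium", stage=stg)
                if not ga or not gb:
                    continue
                res = dd.call_deps(
                    joint, ga, gb, label=f"SvE:{stg}",
                    fc_threshold=config.compartment_fc,
                    q_threshold=config.compartment_q, min_obs=config.min_obs,
                )
                contrast_results[res.label] = res
        for label, res in contrast_results.items():
            res.table.to_csv(outdir / f"dep_{label.replace(':', '_')}.tsv", sep="\t")
        summary["dep_counts"] = {
            label: {"up": len(res.up), "down": len(res.down)}
            for label, res in sorted(contrast_results.items())
        }
        log.write(f"dep: {len(contrast_results)} contrasts")
    except Exception as exc:  # noqa: BLE001
        log.write(f"ERROR in stage {stage}: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: concordance ------------------------------------------------
    stage = "concordance"
    try:
        if len(compartments) == 2:
            conc = {}
            for stg in stages_present:
                bins = {}
                for comp in compartments:
                    samples = sheet.samples_where(compartment=comp, stage=stg)
                    means = cc.context_means(norm[comp].data, samples)
                    bins[comp] = cc.rank_bins(means, k=6, context=f"{stg}:{comp}")
                ct = cc.concordance_table(bins["epithelium"], bins["stroma"])
                ct.counts.to_csv(outdir / f"concordance_{stg}.tsv", sep="\t")
                conc[stg] = {
                    "diagonal_fraction": [
                        _round(v, 4) for v in ct.diagonal_fraction
                    ],
                    "middle_band_retention": _round(ct.middle_band_retention, 4),
                    "n_shared": ct.n_shared,
                }
            summary["concordance"] = conc
            log.write(f"concordance: {len(conc)} stages")
    except Exception as exc:  # noqa: BLE001
        log.write(f"ERROR in stage {stage}: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: comparability ----------------------------------------------
    stage = "comparability"
    try:
        comparability = {}
        for comp in compartments:
            pairs = [("AN", "CN"), ("AN", "CA"), ("CN", "CA")]
            for a, b in pairs:
                la, lb = f"{comp}:{a}", f"{comp}:{b}"
                if la not in contrast_results or lb not in contrast_results:
                    continue
                try:
                    res = dd.ratio_comparability(
                        contrast_results[la].log2fc(),
                        contrast_results[lb].log2fc(),
                        labels=(a, b),
                    )
                except ValueError:
                    continue
                comparability[f"{comp}:{a}-vs-{b}"] = {
                    "ccc": _round(res.ccc, 4),
                    "rms_from_diagonal": _round(res.rms_from_diagonal, 4),
                    "n_shared": res.n_shared,
                }
        summary["comparability"] = comparability
        log.write(f"comparability: {len(comparability)} contrast pairs")
    except Exception as exc:  # noqa: BLE001
        log.write(f"ERROR in stage {stage}: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: modules ----------------------------------------------------
    stage = "modules"
    try:
        summary["modules"] = None
        if "epithelium" in compartments:
            dep_union: set[str] = set()
            for code in ("AN", "CN", "CA"):
                label = f"epithelium:{code}"
                if label in contrast_results:
                    dep_union |= contrast_results[label].deps
            imp = imputed["epithelium"]
            members = sorted(dep_union & set(imp.protein_ids))
            if len(members) >= max(3, config.n_modules):
                meta = sheet.table.loc[imp.sample_ids]
                traits = pd.DataFrame(
                    {
                        "adenoma": (meta["stage"] == "adenoma").astype(float),
                        "carcinoma": (meta["stage"] == "carcinoma").astype(float),
                        "carcinoma/adenoma": meta["stage"].isin(
                            ["adenoma", "carcinoma"]
                        ).astype(float),
                    },
                    index=imp.sample_ids,
                )
                ma = dd.classify_modules(
                    imp.data.loc[members], traits, k=config.n_modules
                )
                ma.modules.to_csv(outdir / "modules.tsv", sep="\t")
                summary["modules"] = {
                    str(m): {
                        "size": int((ma.modules == m).sum()),
                        "trait": ma.trait_labels[m],
                    }
                    for m in sorted(ma.trait_labels)
                }
                log.write(f"modules: {len(members)} consensus DEPs into "
                          f"{config.n_modules} modules")
            else:
                log.write("modules: skipped (too few consensus DEPs)")
    except Exception as exc:  # noqa: BLE001
        log.write(f"ERROR in stage {stage}: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: biomarkers --------------------------------------------------
    stage = "biomarkers"
    try:
        summary["biomarker_panel"] = None
        if len(compartments) == 2:
            stroma_raw = logged.subset(samples=sheet.samples_where(compartment="stroma"))
            epi_raw = logged.subset(samples=sheet.samples_where(compartment="epithelium"))
            stage_contrasts = {
                stg: contrast_results[f"stroma:{code}"]
                for code, (stg, _lo) in (("AN", ("adenoma", "adjacent")),
                                         ("CN", ("carcinoma", "adjacent")))
                if f"stroma:{code}" in contrast_results
            }
            if stage_contrasts and table.peptide_counts is not None:
                crit = bm.BiomarkerCriteria(
                    require_dep_in=tuple(sorted(stage_contrasts))
                )
                panel = bm.select_biomarkers(
                    stroma_raw, epi_raw, sheet, stage_contrasts,
                    peptide_counts=table.peptide_counts, criteria=crit,
                )
                panel.audit.to_csv(outdir / "biomarker_audit.tsv", sep="\t")
                summary["biomarker_panel"] = sorted(panel.panel)
                log.write(f"biomarkers: panel of {len(panel.panel)}")
            else:
                log.write("biomarkers: skipped (missing contrasts or peptide counts)")
    except Exception as exc:  # noqa: BLE001
        log.write(f"ERROR in stage {stage}: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: score --------------------------------------------------------
    stage = "score"
    try:
        summary["stromal_score"] = None
        members: list[str] | None = None
        if config.stromal_signature_gmt is not None:
            sig = sg.read_gmt(config.stromal_signature_gmt)
            members = sig[sig.names[0]]
        elif truth is not None and truth.stromal_signature:
            members = list(truth.stromal_signature)
        if members and len(compartments) == 2:
            scores = sg.score_cohort(
                joint, members, sheet, set_name="stromal", group_col="compartment"
            )
            scores.scores.to_csv(outdir / "stromal_scores.tsv", sep="\t")
            by_group = scores.scores.groupby(
                sheet.table.loc[scores.scores.index, "compartment"]
            ).median()
            summary["stromal_score"] = {
                "median_by_compartment": {k: _round(v, 2) for k, v in by_group.items()},
                "tests": [
                    {
                        "groups": f"{r.group_a}-vs-{r.group_b}",
                        "p": float(r.p),
                        "q": float(r.q),
                    }
                    for r in scores.group_tests.itertuples()
                ],
            }
            log.write("score: stromal enrichment per sample")
        else:
            log.write("score: skipped (no signature available)")
    except Exception as exc:  # noqa: BLE001
        log.write(f"ERROR in stage {stage}: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: deconvolve ---------------------------------------------------
    stage = "deconvolve"
    try:
        summary["deconvolution"] = None
        if config.simulate is not None:
            rng = np.random.default_rng(config.seed + 101)
            sig_mat = syn.simulate_signature_matrix(seed=config.seed + 202)
            n_mix = config.deconvolution_samples
            F = rng.dirichlet(np.ones(sig_mat.n_cell_types), size=n_mix)
            fractions = pd.DataFrame(
                F,
                index=[f"MIX{i:03d}" for i in range(n_mix)],
                columns=sig_mat.cell_types,
            )
            mix_table, mix_truth = syn.generate_mixtures(
                sig_mat, fractions, noise_cv=0.1, seed=config.seed + 303
            )
            result = sg.deconvolve(mix_table, sig_mat)
            result.fractions.to_csv(outdir / "immune_fractions.tsv", sep="\t")
            mae = float(np.abs(result.fractions.to_numpy() - F).mean())
            summary["deconvolution"] = {
                "n_samples": n_mix,
                "mean_fraction": {
                    k: _round(v, 4) for k, v in result.fractions.mean().items()
                },
                "mean_abs_error_vs_truth": _round(mae, 4),
            }
            log.write(f"deconvolve: MAE vs planted fractions {mae:.4f}")
        else:
            log.write("deconvolve: skipped (no signature matrix input)")
    except Exception as exc:  # noqa: BLE001
        log.write(f"ERROR in stage {stage}: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: lrpairs -------------------------------------------------------
    stage = "lrpairs"
    try:
        summary["ligand_receptor"] = None
        if "stroma:CN" in contrast_results and "epithelium:CN" in contrast_results:
            pairs = (
                pd.read_csv(config.lr_pairs_path, sep="\t")
                if config.lr_pairs_path is not None
                else None
            )
            lr = sg.ligand_receptor_screen(
                contrast_results["stroma:CN"], contrast_results["epithelium:CN"], pairs
            )
            lr.table.to_csv(outdir / "lr_pairs.tsv", sep="\t", index=False)
            summary["ligand_receptor"] = {
                "n_hits": int(len(lr.table)),
                "n_screened": lr.n_pairs_screened,
                "n_malformed": lr.n_malformed,
            }
            log.write(f"lrpairs: {len(lr.table)} hits")
    except Exception as exc:  # noqa: BLE001
        log.write(f"ERROR in stage {stage}: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    log.write("pipeline complete")
    return summary
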