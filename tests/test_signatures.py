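"""Enrichment scoring, immune deconvolution, ligand-receptor screening."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stromacomp import (
    QuantTable,
    SampleSheet,
    SignatureMatrix,
    SignatureSet,
    deconvolve,
    generate_mixtures,
    ligand_receptor_screen,
    load_lr_pairs,
    load_stromal_signature,
    read_gmt,
    score_cohort,
    simulate_signature_matrix,
    ssgsea_score,
    write_gmt,
)
from stromacomp.synthetic import _contrast_from_status


def _values(n, seed=0, prefix="P"):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(1, 100, n)
    return pd.Series(vals, index=[f"{prefix}{i:03d}" for i in range(n)])


class TestSsgseaScore:
    def test_top_placement_maximal_small_enumeration(self):
        # every placement of 2 members among 8 ranks; contiguous top block wins
        values = pd.Series(
            np.arange(8, 0, -1, dtype=float), index=[f"P{i}" for i in range(8)]
        )
        ranked = list(values.sort_values(ascending=False).index)
        scores = {
            members: ssgsea_score(values, list(members))
            for members in combinations(ranked, 2)
        }
        top = tuple(ranked[:2])
        assert max(scores, key=scores.get) == top

    def test_all_proteins_degenerate_zero(self):
        values = _values(10)
        assert ssgsea_score(values, list(values.index)) == 0.0

    def test_rank_invariance_under_squaring(self):
        values = _values(50, seed=1)
        members = list(values.index[:7])
        assert ssgsea_score(values, members) == pytest.approx(
            ssgsea_score(values**2, members), abs=1e-12
        )

    def test_moving_member_from_bottom_to_top_increases_score(self):
        values = _values(30, seed=2).sort_values(ascending=False)
        members = [values.index[5], values.index[-1]]  # one near top, one at bottom
        before = ssgsea_score(values, members)
        promoted = values.copy()
        promoted[values.index[-1]] = values.iloc[0] + 1.0
        after = ssgsea_score(promoted, members)
        assert after > before

    def test_missing_members_excluded_before_ranking(self):
        values = _values(20, seed=3)
        values.iloc[:3] = np.nan
        score_a = ssgsea_score(values, list(values.index[3:8]))
        score_b = ssgsea_score(values.dropna(), list(values.index[3:8]))
        assert score_a == score_b

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="member"):
            ssgsea_score(_values(10), ["NOPE"])


def _scored_cohort(shift: float, seed: int = 0, n_prot=200, n_per_group=15):
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:03d}" for i in range(n_prot)]
    members = proteins[:30]
    stroma = rng.normal(20, 1, (n_prot, n_per_group))
    epi = rng.normal(20, 1, (n_prot, n_per_group))
    stroma[:30] += shift
    cols = [f"ST{i}" for i in range(n_per_group)] + [f"EP{i}" for i in range(n_per_group)]
    table = QuantTable(
        pd.DataFrame(np.hstack([stroma, epi]), index=proteins, columns=cols),
        scale="log2",
    )
    meta = pd.DataFrame(
        {
            "patient_id": [f"PT{i}" for i in range(n_per_group)] * 2,
            "preparation": "LCM",
            "compartment": ["stroma"] * n_per_group + ["epithelium"] * n_per_group,
            "stage": "carcinoma",
        },
        index=pd.Index(cols, name="sample_id"),
    )
    return table, SampleSheet(meta), members


class TestScoreCohort:
    def test_planted_enrichment_separates_compartments(self):
        table, sheet, members = _scored_cohort(shift=2.0)
        res = score_cohort(table, members, sheet)
        assert res.group_tests["p"].iloc[0] < 0.01
        groups = sheet.table["compartment"]
        assert (
            res.scores[groups[groups == "stroma"].index].median()
            > res.scores[groups[groups == "epithelium"].index].median()
        )

    def test_no_enrichment_gives_large_p(self):
        table, sheet, members = _scored_cohort(shift=0.0, seed=1)
        res = score_cohort(table, members, sheet)
        assert res.group_tests["p"].iloc[0] > 0.05

    def test_label_permutation_gives_uniform_p(self):
        # permuting compartment labels over real (null) scores: Wilcoxon p uniform
        table, sheet, members = _scored_cohort(shift=0.0, seed=2)
        scores = np.array(
            [ssgsea_score(table.data[s], members) for s in table.sample_ids]
        )
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(200):
            perm = rng.permutation(len(scores))
            a, b = scores[perm[:15]], scores[perm[15:]]
            pvals.append(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_small_groups_rejected(self):
        table, sheet, members = _scored_cohort(shift=1.0)
        tiny = table.subset(samples=table.sample_ids[:4])
        with pytest.raises(ValueError, match="groups"):
            score_cohort(tiny, members, sheet)


class TestDeconvolve:
    def test_exact_mixture_recovered(self):
        sig = simulate_signature_matrix(seed=5)
        rng = np.random.default_rng(6)
        F = rng.dirichlet(np.ones(9), size=5)
        fractions = pd.DataFrame(
            F, index=[f"M{i}" for i in range(5)], columns=sig.cell_types
        )
        table, _ = generate_mixtures(sig, fractions, noise_cv=0.0)
        res = deconvolve(table, sig)
        np.testing.assert_allclose(res.fractions.to_numpy(), F, atol=1e-6)
        assert (res.residual_norm < 1e-6).all()

    def test_pure_column_gives_unit_vector(self):
        sig = simulate_signature_matrix(n_celltypes=4, markers_per_type=10, seed=7)
        fractions = pd.DataFrame(
            np.eye(4)[[2]], index=["M0"], columns=sig.cell_types
        )
        table, _ = generate_mixtures(sig, fractions, noise_cv=0.0)
        res = deconvolve(table, sig)
        np.testing.assert_allclose(res.fractions.loc["M0"], np.eye(4)[2], atol=1e-9)

    def test_fractions_normalized_and_nonnegative(self):
        sig = simulate_signature_matrix(seed=8)
        rng = np.random.default_rng(9)
        F = rng.dirichlet(np.ones(9), size=10)
        fractions = pd.DataFrame(
            F, index=[f"M{i}" for i in range(10)], columns=sig.cell_types
        )
        table, _ = generate_mixtures(sig, fractions, noise_cv=0.3, seed=10)
        res = deconvolve(table, sig)
        vals = res.fractions.to_numpy()
        assert (vals >= 0).all()
        np.testing.assert_allclose(vals.sum(axis=1), 1.0, atol=1e-9)

    def test_error_monotone_in_noise(self):
        sig = simulate_signature_matrix(seed=11)
        rng = np.random.default_rng(12)
        F = rng.dirichlet(np.ones(9), size=30)
        fractions = pd.DataFrame(
            F, index=[f"M{i}" for i in range(30)], columns=sig.cell_types
        )
        maes = []
        for cv in (0.0, 0.1, 0.4):
            table, _ = generate_mixtures(sig, fractions, noise_cv=cv, seed=13)
            res = deconvolve(table, sig)
            maes.append(float(np.abs(res.fractions.to_numpy() - F).mean()))
        assert maes[0] <= maes[1] <= maes[2]

    def test_row_order_invariance(self):
        sig = simulate_signature_matrix(n_celltypes=5, markers_per_type=8, seed=14)
        rng = np.random.default_rng(15)
        F = rng.dirichlet(np.ones(5), size=3)
        fractions = pd.DataFrame(
            F, index=[f"M{i}" for i in range(3)], columns=sig.cell_types
        )
        table, _ = generate_mixtures(sig, fractions, noise_cv=0.05, seed=16)
        res_a = deconvolve(table, sig)
        perm = rng.permutation(table.protein_ids)
        table_perm = QuantTable(table.data.loc[perm], scale="linear")
        res_b = deconvolve(table_perm, sig)
        np.testing.assert_allclose(
            res_a.fractions.to_numpy(), res_b.fractions.to_numpy(), atol=1e-9
        )

    def test_underdetermined_rejected(self):
        sig = simulate_signature_matrix(n_celltypes=9, markers_per_type=20, seed=17)
        fractions = pd.DataFrame(
            np.full((1, 9), 1 / 9), index=["M0"], columns=sig.cell_types
        )
        table, _ = generate_mixtures(sig, fractions, noise_cv=0.0)
        sparse = table.data.copy()
        sparse.iloc[15:] = np.nan  # only 15 observed proteins for 9 cell types
        with pytest.raises(ValueError, match="underdetermined"):
            deconvolve(QuantTable(sparse, scale="linear"), sig)


class TestLigandReceptorScreen:
    def _contrasts(self, stroma_status, epi_status):
        return (
            _contrast_from_status("stroma:CN", stroma_status),
            _contrast_from_status("epithelium:CN", epi_status),
        )

    def test_constructed_hit_reported_with_directions(self):
        stroma, epi = self._contrasts({"L1": "up", "R1": "ns"}, {"L1": "ns", "R1": "up"})
        pairs = pd.DataFrame({"ligand": ["L1"], "receptor": ["R1"]})
        res = ligand_receptor_screen(stroma, epi, pairs)
        assert len(res.table) == 1
        row = res.table.iloc[0]
        assert row["stroma_partner"] == "L1" and row["epithelium_partner"] == "R1"
        assert row["stroma_direction"] == "up" and row["epithelium_direction"] == "up"

    def test_no_deps_empty_table(self):
        stroma, epi = self._contrasts({"L1": "ns", "R1": "ns"}, {"L1": "ns", "R1": "ns"})
        pairs = pd.DataFrame({"ligand": ["L1"], "receptor": ["R1"]})
        res = ligand_receptor_screen(stroma, epi, pairs)
        assert res.table.empty

    def test_planted_pairs_recovered_exactly(self):
        ligands = [f"L{i}" for i in range(10)]
        receptors = [f"R{i}" for i in range(10)]
        decoys = [f"D{i}" for i in range(5)]
        stroma_status = {p: "up" for p in ligands}
        stroma_status.update({p: "ns" for p in receptors + decoys})
        epi_status = {p: "down" for p in receptors}
        epi_status.update({p: "ns" for p in ligands + decoys})
        stroma, epi = self._contrasts(stroma_status, epi_status)
        pairs = pd.DataFrame(
            {
                "ligand": ligands + decoys,
                "receptor": receptors + decoys[::-1],
            }
        )
        res = ligand_receptor_screen(stroma, epi, pairs)
        assert set(zip(res.table["ligand"], res.table["receptor"])) == set(
            zip(ligands, receptors)
        )

    def test_malformed_rows_skipped_and_counted(self):
        stroma, epi = self._contrasts({"L1": "up"}, {"R1": "up"})
        pairs = pd.DataFrame(
            {"ligand": ["L1", None, ""], "receptor": ["R1", "R1", "R1"]}
        )
        res = ligand_receptor_screen(stroma, epi, pairs)
        assert res.n_malformed == 2 and len(res.table) == 1


class TestResources:
    def test_gmt_round_trip(self, tmp_path):
        sig = SignatureSet({"SET_A": ["P1", "P2"], "SET_B": ["P3"]})
        path = tmp_path / "sets.gmt"
        write_gmt(sig, path)
        assert read_gmt(path).sets == sig.sets

    def test_bundled_resources_load(self):
        sig = load_stromal_signature()
        assert len(sig[sig.names[0]]) > 20
        pairs = load_lr_pairs()
        assert {"ligand", "receptor"} <= set(pairs.columns)

    def test_signature_matrix_validation(self):
        df = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 0.0]}, index=["P1", "P2"])
        with pytest.raises(ValueError, match="all-zero"):
            SignatureMatrix(df)
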