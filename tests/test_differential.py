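"""Differential calling, BH-FDR, overlap, comparability, module classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st_
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from stromacomp import (
    CohortConfig,
    PlantedEffect,
    QuantTable,
    bh_adjust,
    call_deps,
    classify_modules,
    generate_cohort,
    individual_deps,
    log2_transform,
    overlap_analysis,
    ratio_comparability,
)


def bh_oracle(p):
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, capped."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBHAdjust:
    def test_hand_computed_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-15)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    @given(st_.lists(st_.floats(0, 1), min_size=1, max_size=30))
    def test_matches_oracle_and_statsmodels(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
        sm_q = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, sm_q, atol=1e-12)

    @given(st_.lists(st_.floats(0, 1), min_size=2, max_size=30))
    def test_contract_bounds_and_monotonicity(self, p):
        q = bh_adjust(p)
        assert q.max() <= 1.0
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _two_group_table(n_prot=60, n=6, delta=0.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(20, 0.5, (n_prot, n))
    b = rng.normal(20, 0.5, (n_prot, n)) + delta
    cols = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
    df = pd.DataFrame(np.hstack([a, b]), columns=cols)
    groups = cols[:n], cols[n:]
    return QuantTable(df, scale="log2"), groups


class TestCallDeps:
    def test_swap_symmetry(self):
        table, (ga, gb) = _two_group_table(delta=1.0, seed=1)
        r1 = call_deps(table, ga, gb, fc_threshold=2.0)
        r2 = call_deps(table, gb, ga, fc_threshold=2.0)
        np.testing.assert_allclose(r1.table["log2fc"], -r2.table["log2fc"])
        np.testing.assert_allclose(r1.table["q"], r2.table["q"], atol=1e-12)
        assert r1.up == r2.down and r1.down == r2.up

    def test_welch_p_matches_scipy(self):
        table, (ga, gb) = _two_group_table(seed=2)
        res = call_deps(table, ga, gb)
        A = table.data[ga].to_numpy()
        B = table.data[gb].to_numpy()
        oracle = stats.ttest_ind(A, B, axis=1, equal_var=False).pvalue
        np.testing.assert_allclose(res.table["p"], oracle, atol=1e-12)

    def test_null_data_yields_no_calls(self):
        table, (ga, gb) = _two_group_table(n_prot=500, seed=3)
        res = call_deps(table, ga, gb, fc_threshold=2.0, q_threshold=0.05)
        assert res.n_dep == 0  # BH control on pure-null data

    def test_fc4_calls_subset_of_fc2_calls(self):
        table, (ga, gb) = _two_group_table(n_prot=300, delta=2.5, seed=4)
        r4 = call_deps(table, ga, gb, fc_threshold=4.0)
        r2 = call_deps(table, ga, gb, fc_threshold=2.0)
        assert r4.deps <= r2.deps

    def test_untested_proteins_reported_not_dropped(self):
        table, (ga, gb) = _two_group_table(n_prot=5, seed=5)
        data = table.data.copy()
        data.iloc[0, :5] = np.nan  # only 1 observation left in group A
        res = call_deps(QuantTable(data, scale="log2"), ga, gb, min_obs=3)
        assert res.table["status"].iloc[0] == "untested"
        assert len(res.table) == 5
        assert np.isnan(res.table["q"].iloc[0])

    def test_overlapping_groups_rejected(self):
        table, (ga, gb) = _two_group_table()
        with pytest.raises(ValueError, match="overlap"):
            call_deps(table, ga, ga[:3] + gb)

    def test_min_obs_floor(self):
        table, (ga, gb) = _two_group_table()
        with pytest.raises(ValueError, match="min_obs"):
            call_deps(table, ga, gb, min_obs=1)


class TestIndividualDeps:
    def _cohort(self):
        cfg = CohortConfig(
            n_patients=2,
            n_proteins=40,
            stages=("adenoma", "carcinoma"),
            compartments=("stroma",),
            noise_sd=0.2,
            noise_scale_by_stage={},
            depth_offsets={"stroma": 0.0},
            detect_midpoint=-1e6,
            seed=0,
        )
        return generate_cohort(cfg)

    def test_threshold_is_inclusive_at_exactly_twofold(self):
        table, sheet, _ = self._cohort()
        data = table.data.copy()
        sa = sheet.samples_where(patient_id="PT01", stage="carcinoma")[0]
        sb = sheet.samples_where(patient_id="PT01", stage="adenoma")[0]
        data.loc["PROT00000", [sa, sb]] = [200.0, 100.0]  # ratio exactly 2.0
        data.loc["PROT00001", [sa, sb]] = [190.0, 100.0]  # ratio 1.9
        res = individual_deps(
            QuantTable(data, scale="linear"), sheet, "PT01", "stroma",
            "carcinoma", "adenoma", fc_threshold=2.0,
        )
        assert "PROT00000" in res.up  # fold change >= 2 counts
        assert "PROT00001" not in res.deps

    def test_identical_samples_give_empty_set(self):
        table, sheet, _ = self._cohort()
        data = table.data.copy()
        sa = sheet.samples_where(patient_id="PT01", stage="carcinoma")[0]
        sb = sheet.samples_where(patient_id="PT01", stage="adenoma")[0]
        data[sa] = data[sb]
        res = individual_deps(
            QuantTable(data, scale="linear"), sheet, "PT01", "stroma",
            "carcinoma", "adenoma",
        )
        assert res.deps == set()

    def test_missing_tissue_rejected(self):
        table, sheet, _ = self._cohort()
        kept = [s for s in table.sample_ids
                if s != sheet.samples_where(patient_id="PT01", stage="adenoma")[0]]
        sub = table.subset(samples=kept)
        with pytest.raises(ValueError, match="lacks"):
            individual_deps(sub, sheet, "PT01", "stroma", "carcinoma", "adenoma")


class TestOverlapAnalysis:
    def test_exact_fractions(self):
        res = overlap_analysis({"A": {"1", "2", "3"}, "B": {"2", "3", "4"}})
        assert res.fractions.loc["A", "B"] == pytest.approx(2 / 3)
        assert res.fractions.loc["A", "A"] == 1.0

    def test_subset_gives_fraction_one(self):
        res = overlap_analysis({"A": {"1", "2"}, "B": {"1", "2", "3"}})
        assert res.fractions.loc["A", "B"] == 1.0

    def test_membership_covers_union(self):
        sets = {"A": {"1", "2"}, "B": {"2", "3"}, "C": {"4"}}
        res = overlap_analysis(sets)
        assert len(res.membership) == len(set().union(*sets.values()))
        assert res.membership.any(axis=1).all()

    def test_empty_set_fraction_is_missing(self):
        res = overlap_analysis({"A": set(), "B": {"1"}})
        assert np.isnan(res.fractions.loc["A", "B"])

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            overlap_analysis({"A": {"1"}})


class TestRatioComparability:
    def test_identical_vectors_on_diagonal(self):
        x = pd.Series(np.linspace(-2, 2, 15))
        res = ratio_comparability(x, x.copy())
        assert res.ccc == pytest.approx(1.0)
        assert res.rms_from_diagonal == 0.0

    def test_anti_diagonal_negative_ccc(self):
        x = pd.Series(np.linspace(-2, 2, 15))
        res = ratio_comparability(x, -x)
        assert res.ccc < 0

    def test_hand_computed_value(self):
        # x=[1,2,3], y=[1,2,4]: rho_c = 2*cov / (vx + vy + dmean^2) = 6/7
        x = pd.Series([1.0, 2.0, 3.0])
        y = pd.Series([1.0, 2.0, 4.0])
        res = ratio_comparability(x, y, min_shared=3)
        assert res.ccc == pytest.approx(6 / 7, abs=1e-12)

    def test_invariant_to_protein_order(self):
        rng = np.random.default_rng(6)
        idx = [f"P{i}" for i in range(30)]
        x = pd.Series(rng.normal(size=30), index=idx)
        y = pd.Series(rng.normal(size=30), index=idx)
        perm = rng.permutation(idx)
        a = ratio_comparability(x, y)
        b = ratio_comparability(x.loc[perm], y.loc[perm])
        assert a.ccc == pytest.approx(b.ccc, abs=1e-12)
        assert a.rms_from_diagonal == pytest.approx(b.rms_from_diagonal, abs=1e-12)

    def test_too_few_shared_rejected(self):
        x = pd.Series([1.0, 2.0])
        with pytest.raises(ValueError, match="shared"):
            ratio_comparability(x, x)


class TestClassifyModules:
    @staticmethod
    def _planted_blocks(noise_sd=0.1, seed=0):
        rng = np.random.default_rng(seed)
        n_samples = 24
        stage = np.array(["adjacent"] * 8 + ["adenoma"] * 8 + ["carcinoma"] * 8)
        traits = pd.DataFrame(
            {
                "adenoma": (stage == "adenoma").astype(float),
                "carcinoma": (stage == "carcinoma").astype(float),
                "carcinoma/adenoma": np.isin(stage, ["adenoma", "carcinoma"]).astype(float),
            },
            index=[f"S{i}" for i in range(n_samples)],
        )
        blocks, labels = [], []
        drivers = {
            "carcinoma": (stage == "carcinoma").astype(float),
            "adenoma": (stage == "adenoma").astype(float),
            "carcinoma/adenoma": np.isin(stage, ["adenoma", "carcinoma"]).astype(float),
        }
        for b, (name, drv) in enumerate(drivers.items()):
            for i in range(10):
                blocks.append(drv * 3.0 + rng.normal(0, noise_sd, n_samples))
                labels.append(b)
        data = pd.DataFrame(
            blocks, index=[f"P{i}" for i in range(30)], columns=traits.index
        )
        return data, traits, np.array(labels)

    def test_planted_blocks_recovered_with_matching_traits(self):
        data, traits, truth = self._planted_blocks()
        res = classify_modules(data, traits, k=3)
        assert adjusted_rand_score(truth, res.modules.to_numpy()) == 1.0
        recovered_traits = set(res.trait_labels.values())
        assert recovered_traits == {"carcinoma", "adenoma", "carcinoma/adenoma"}
        assert (res.trait_correlation.abs().max(axis=1) > 0.9).all()

    def test_k_one_single_module(self):
        data, traits, _ = self._planted_blocks(seed=1)
        res = classify_modules(data, traits, k=1)
        assert set(res.modules) == {1}

    def test_duplicated_rows_share_module(self):
        data, traits, _ = self._planted_blocks(seed=2)
        data = pd.concat([data, data.iloc[[0]].rename(index={"P0": "P0dup"})])
        res = classify_modules(data, traits, k=3)
        assert res.modules["P0"] == res.modules["P0dup"]

    def test_constant_protein_excluded_with_warning(self):
        data, traits, _ = self._planted_blocks(seed=3)
        data.loc["PFLAT"] = 1.0
        with pytest.warns(RuntimeWarning, match="constant"):
            res = classify_modules(data, traits, k=3)
        assert "PFLAT" in res.excluded
        assert "PFLAT" not in res.modules.index
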