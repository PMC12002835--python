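"""Tests for the Perseus-style proteomics post-processing stages."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vascage.errors import ValidationError
from vascage.proteomics import (ProteomicsMatrix, filter_valid, hcluster,
                                impute_downshift, log2_transform, pca_scores,
                                ttest_permutation_fdr, zscore_rows)


def _matrix(values, groups=None, scale="log2", proteins=None):
    values = np.asarray(values, dtype=float)
    n_p, n_s = values.shape
    proteins = proteins or [f"P{i}" for i in range(n_p)]
    samples = [f"S{j}" for j in range(n_s)]
    if groups is None:
        half = n_s // 2
        groups = ["A"] * half + ["B"] * (n_s - half)
    return ProteomicsMatrix(
        values=pd.DataFrame(values, index=proteins, columns=samples),
        groups=pd.Series(groups, index=samples),
        scale=scale,
    )


class TestLog2Transform:
    def test_values_and_missing_cells(self):
        m = _matrix([[8.0, np.nan], [2.0, 4.0]], groups=["A", "A"],
                    scale="raw")
        out = log2_transform(m)
        assert out.values.iloc[0, 0] == 3.0
        assert np.isnan(out.values.iloc[0, 1])
        assert out.scale == "log2"

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 1e6, (10, 4))
        m = _matrix(vals, scale="raw")
        back = 2.0 ** log2_transform(m).values.to_numpy()
        assert np.allclose(back, vals, rtol=1e-12)

    def test_non_positive_cell_rejected_at_construction(self):
        with pytest.raises(ValidationError, match="non-positive"):
            _matrix([[1.0, 0.0]], groups=["A", "B"], scale="raw")

    def test_double_transform_rejected(self):
        m = _matrix([[1.0, 2.0]], groups=["A", "B"])
        with pytest.raises(ValidationError):
            log2_transform(m)


class TestFilterValid:
    def _with_missing(self):
        vals = np.ones((3, 12)) * 20
        vals[0, [0, 1, 2]] = np.nan       # 3 of 6 valid in group A -> kept
        vals[1, [6, 7, 8, 9]] = np.nan    # 2 of 6 valid in group B -> removed
        vals[2, :] = 20
        return _matrix(vals, groups=["A"] * 6 + ["B"] * 6)

    def test_boundary_and_removal(self):
        out = filter_valid(self._with_missing(), min_valid=3)
        assert list(out.values.index) == ["P0", "P2"]

    def test_min_valid_zero_is_identity(self):
        m = self._with_missing()
        out = filter_valid(m, min_valid=0)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_idempotent_and_never_grows(self):
        m = self._with_missing()
        once = filter_valid(m)
        twice = filter_valid(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert len(once.values) <= len(m.values)


class TestPermutationFDR:
    def test_identical_groups_yield_empty_set(self):
        rng = np.random.default_rng(2)
        half = rng.normal(20, 1, (50, 6))
        m = _matrix(np.hstack([half, half]))
        de = ttest_permutation_fdr(m, seed=0)
        assert (de.table["log2fc"] == 0).all()
        assert not de.table["significant"].any()

    def test_t_and_p_match_textbook_student_t(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(20, 1, (20, 12))
        vals[:5, 6:] += 2.0
        m = _matrix(vals)
        de = ttest_permutation_fdr(m, seed=1)
        for i in range(20):
            t_ref, p_ref = sps.ttest_ind(vals[i, :6], vals[i, 6:],
                                         equal_var=True)
            row = de.table.iloc[i]
            assert row["t"] == pytest.approx(t_ref, rel=1e-10)
            assert row["p"] == pytest.approx(p_ref, rel=1e-10)
            assert row["log2fc"] == pytest.approx(
                vals[i, :6].mean() - vals[i, 6:].mean(), rel=1e-12)

    def test_estimated_fdr_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(20, 1, (200, 12))
        vals[:20, 6:] += 1.5
        de = ttest_permutation_fdr(_matrix(vals), seed=2)
        assert (np.diff(de.fdr_curve["fdr_monotone"]) <= 1e-12).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(20, 1, (100, 12))
        m = _matrix(vals)
        d1 = ttest_permutation_fdr(m, seed=7)
        d2 = ttest_permutation_fdr(m, seed=7)
        pd.testing.assert_frame_equal(d1.table, d2.table)

    def test_all_distinct_permutations_seed_invariant(self):
        """With every balanced assignment enumerated, the seed is irrelevant."""
        rng = np.random.default_rng(6)
        vals = rng.normal(20, 1, (40, 8))
        vals[:5, 4:] += 3.0
        m = _matrix(vals)  # 4 vs 4: C(8,4)-1 = 69 distinct non-identity
        d1 = ttest_permutation_fdr(m, n_perm=1000, seed=1)
        d2 = ttest_permutation_fdr(m, n_perm=1000, seed=99)
        assert d1.n_perm_used == 69 == d2.n_perm_used
        pd.testing.assert_frame_equal(d1.table, d2.table)

    def test_protein_with_too_few_valid_values_untested(self):
        vals = np.full((2, 12), 20.0)
        vals[0, 1:6] = np.nan  # 1 valid in group A
        vals[1] = np.linspace(19, 21, 12)
        de = ttest_permutation_fdr(_matrix(vals), seed=0)
        assert not de.table.iloc[0]["tested"]
        assert de.table.iloc[1]["tested"]

    def test_strong_effects_flagged(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(25, 0.3, (500, 12))
        vals[:50, 6:] += 2.0
        de = ttest_permutation_fdr(_matrix(vals), seed=3)
        sig = de.table["significant"].to_numpy()
        assert sig[:50].mean() > 0.9
        assert sig[50:].mean() < 0.02


class TestImputeDownshift:
    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(9)
        m = _matrix(rng.normal(20, 1, (30, 6)))
        out = impute_downshift(m, seed=0)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_observed_cells_bitwise_untouched(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(20, 1, (50, 6))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        m = _matrix(vals)
        out = impute_downshift(m, seed=1)
        obs = ~np.isnan(vals)
        assert np.array_equal(out.values.to_numpy()[obs], vals[obs])
        assert not np.isnan(out.values.to_numpy()).any()

    def test_moments_of_imputed_cells(self):
        from vascage.evaluation import imputation_moments

        res = imputation_moments(n_cells=10_000, mu=20.0, sigma=1.0)
        assert res["mean"] == pytest.approx(18.2, abs=0.02)
        assert res["sd"] == pytest.approx(0.4, abs=0.02)

    def test_same_seed_same_imputation(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(20, 1, (40, 4))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        m = _matrix(vals, groups=["A", "A", "B", "B"])
        o1 = impute_downshift(m, seed=5)
        o2 = impute_downshift(m, seed=5)
        pd.testing.assert_frame_equal(o1.values, o2.values)

    def test_column_with_one_observed_value_is_an_error(self):
        vals = np.full((3, 2), np.nan)
        vals[0, 0] = 20.0
        vals[:, 1] = 20.0
        m = _matrix(vals, groups=["A", "B"])
        with pytest.raises(ValidationError, match="S0"):
            impute_downshift(m, seed=0)


class TestZScore:
    def test_hand_example_sample_sd(self):
        m = _matrix([[1.0, 2.0, 3.0]], groups=["A", "A", "B"])
        out = zscore_rows(m)
        assert np.allclose(out.values.to_numpy()[0], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(12)
        m = _matrix(rng.normal(20, 2, (20, 8)))
        once = zscore_rows(m)
        twice = zscore_rows(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy())

    def test_constant_row_error_names_protein(self):
        m = _matrix([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                    groups=["A", "A", "B"])
        with pytest.raises(ValidationError, match="P0"):
            zscore_rows(m)


class TestHCluster:
    def test_duplicate_samples_merge_at_zero(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(0, 1, (20, 4))
        vals[:, 3] = vals[:, 2]  # duplicate sample
        m = _matrix(vals, groups=["A", "A", "B", "B"])
        res = hcluster(m)
        assert res.col_linkage[0, 2] == pytest.approx(0.0)

    def test_two_block_design_top_split_separates_groups(self):
        rng = np.random.default_rng(14)
        vals = rng.normal(0, 0.2, (50, 12))
        vals[:, 6:] += 5.0
        m = _matrix(vals)
        res = hcluster(m)
        order = res.col_order
        first_half = {str(s) for s in order[:6]}
        assert first_half in ({f"S{j}" for j in range(6)},
                              {f"S{j}" for j in range(6, 12)})

    def test_kmeans_preprocessing_reduces_to_centroids(self):
        rng = np.random.default_rng(15)
        vals = np.vstack([rng.normal(-2, 0.1, (30, 6)),
                          rng.normal(2, 0.1, (30, 6))])
        m = _matrix(vals)
        res = hcluster(m, kmeans_pre=2, seed=0)
        assert res.row_cluster_of.nunique() == 2
        assert len(res.row_order) == 60
        assert res.row_newick.count("cluster_") == 2

    def test_newick_has_all_leaves(self):
        rng = np.random.default_rng(16)
        m = _matrix(rng.normal(0, 1, (5, 4)), groups=["A", "A", "B", "B"])
        res = hcluster(m)
        for p in ["P0", "P1", "P2", "P3", "P4"]:
            assert p in res.row_newick
        assert res.col_newick.endswith(";")


class TestPCA:
    def test_rank_one_matrix_explained_by_pc1(self):
        u = np.linspace(-1, 1, 30)
        v = np.linspace(2, 5, 8)
        m = _matrix(np.outer(u, v))
        res = pca_scores(m, n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(17)
        m = _matrix(rng.normal(0, 1, (40, 10)))
        r1 = pca_scores(m, 3)
        r2 = pca_scores(m, 3)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)
        for c in r1.loadings.columns:
            assert r1.loadings[c].iloc[r1.loadings[c].abs().argmax()] > 0

    def test_two_group_separation_on_pc1(self):
        rng = np.random.default_rng(18)
        vals = rng.normal(20, 0.3, (200, 12))
        vals[:40, 6:] += 2.0
        res = pca_scores(_matrix(vals), 2)
        pc1 = res.scores["PC1"].to_numpy()
        assert (np.sign(pc1[:6]) == np.sign(pc1[0])).all()
        assert (np.sign(pc1[6:]) == -np.sign(pc1[0])).all()

    def test_too_many_components_rejected(self):
        m = _matrix(np.random.default_rng(19).normal(0, 1, (5, 4)),
                    groups=["A", "A", "B", "B"])
        with pytest.raises(ValidationError):
            pca_scores(m, 5)
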