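"""Unit and property tests for the statistical kernels."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from vascage.errors import CollinearityError, PValueError, ValidationError
from vascage.stats_core import (Contingency2x2, bh_adjust, chi_square_2x2,
                                fisher_exact_2x2, kruskal_wallis, ols_fit,
                                pearson_age_corr, wilcoxon_one_sample)

from oracles import (bh_stepup_bruteforce, chi2_2x2_closed_form,
                     fisher_2x2_enumeration, kruskal_bruteforce,
                     ols_normal_equations, pearson_closed_form,
                     wilcoxon_exact_bruteforce)


class TestBHAdjust:
    @pytest.mark.parametrize("p, expected", [
        ([0.05], [0.05]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ])
    def test_worked_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(PValueError):
            bh_adjust([0.1, 1.5])
        with pytest.raises(PValueError):
            bh_adjust([-0.1])
        with pytest.raises(PValueError):
            bh_adjust([np.nan, 0.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    def test_matches_stepup_definition_and_bounds(self, p):
        q = bh_adjust(p)
        assert np.allclose(q, bh_stepup_bruteforce(p), atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), q_sm)


class TestPearson:
    def test_exact_linearity(self):
        res = pearson_age_corr([20, 40, 60, 80], 10 + 0.1 * np.array([20, 40, 60, 80]))
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.1)
        assert res.mean_y == pytest.approx(15.0)

    def test_constant_y_is_degenerate(self):
        res = pearson_age_corr([20, 40, 60], [5.0, 5.0, 5.0])
        assert res.degenerate
        assert np.isnan(res.r)

    def test_constant_x_is_an_error(self):
        with pytest.raises(ValidationError):
            pearson_age_corr([50, 50, 50], [1.0, 2.0, 3.0])

    def test_matches_closed_form(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        res = pearson_age_corr(x, y)
        r, p = pearson_closed_form(x, y)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_never_reports_zero_p(self):
        res = pearson_age_corr([20, 40, 60, 80], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value > 0
        assert res.p_floored


class TestWilcoxon:
    def test_perfect_symmetry(self):
        assert wilcoxon_one_sample([-1, 1], mu0=0).p_value == pytest.approx(1.0)

    def test_all_positive_small_n(self):
        res = wilcoxon_one_sample([1, 2, 3, 4, 5, 6], mu0=0)
        assert res.p_value == pytest.approx(0.03125)

    def test_all_above_mu0_n10_is_significant(self):
        res = wilcoxon_one_sample(np.arange(1, 11, dtype=float), mu0=0)
        assert res.p_value < 0.01
        assert res.p_value == pytest.approx(2 / 2**10)

    def test_all_equal_mu0_is_degenerate(self):
        res = wilcoxon_one_sample([3.0, 3.0, 3.0], mu0=3.0)
        assert res.degenerate and res.p_value == 1.0

    @given(st.lists(st.integers(-8, 8), min_size=2, max_size=12))
    def test_exact_matches_sign_flip_enumeration(self, values):
        values = [float(v) for v in values]
        res = wilcoxon_one_sample(values, mu0=0.0, mode="exact")
        expected = wilcoxon_exact_bruteforce(values)
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_approx_mode_close_to_exact_for_moderate_n(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0.3, 1.0, 24)
        pe = wilcoxon_one_sample(v, mode="exact").p_value
        pa = wilcoxon_one_sample(v, mode="approx").p_value
        assert pa == pytest.approx(pe, rel=0.25)

    def test_type_one_error_at_most_nominal(self):
        """Exact signed-rank p is conservative under the null by discreteness."""
        rng = np.random.default_rng(42)
        alpha = 0.05
        n_sim = 10_000
        rejections = 0
        for _ in range(n_sim):
            v = rng.normal(0.0, 1.0, 10)
            if wilcoxon_one_sample(v, mode="exact").p_value <= alpha:
                rejections += 1
        rate = rejections / n_sim
        mc = np.sqrt(alpha * (1 - alpha) / n_sim)
        assert rate <= alpha + 2 * mc


class TestChi2AndFisher:
    def test_aortopathy_table(self):
        res = chi_square_2x2(Contingency2x2(4, 3, 0, 7), correction="none")
        assert res.statistic == pytest.approx(5.6)
        assert res.p_value == pytest.approx(0.0180, abs=5e-4)
        assert res.p_value < 0.05

    def test_identical_proportions(self):
        res = chi_square_2x2(Contingency2x2(5, 5, 5, 5))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_small_table_closed_form(self):
        res = chi_square_2x2(Contingency2x2(3, 3, 2, 3), correction="none")
        assert res.statistic == pytest.approx(0.110, abs=5e-3)
        assert res.p_value == pytest.approx(0.740, abs=5e-3)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_2x2(Contingency2x2(0, 0, 3, 4))
        with pytest.raises(ValidationError):
            fisher_exact_2x2(Contingency2x2(0, 3, 0, 4))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            Contingency2x2(-1, 2, 3, 4)

    @pytest.mark.parametrize("cells", [(4, 3, 0, 7), (5, 5, 5, 5), (10, 0, 0, 10),
                                       (7, 2, 3, 9), (1, 8, 6, 2)])
    def test_invariant_under_row_and_column_swap(self, cells):
        a, b, c, d = cells
        for test in (chi_square_2x2, fisher_exact_2x2):
            p0 = test(Contingency2x2(a, b, c, d)).p_value
            p_swapped = test(Contingency2x2(d, c, b, a)).p_value
            assert p_swapped == pytest.approx(p0, rel=1e-12)

    def test_fisher_worked_examples(self):
        assert fisher_exact_2x2(Contingency2x2(4, 3, 0, 7)).p_value == \
            pytest.approx(0.0699, abs=5e-4)
        assert fisher_exact_2x2(Contingency2x2(5, 5, 5, 5)).p_value == \
            pytest.approx(1.0)
        assert fisher_exact_2x2(Contingency2x2(10, 0, 0, 10)).p_value < 1e-4

    def test_fisher_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, 4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            p = fisher_exact_2x2(Contingency2x2(a, b, c, d)).p_value
            assert p == pytest.approx(fisher_2x2_enumeration(a, b, c, d),
                                      rel=1e-9)

    def test_yates_floors_at_zero(self):
        res = chi_square_2x2(Contingency2x2(3, 3, 3, 4), correction="yates")
        assert res.statistic >= 0.0


class TestKruskal:
    def test_identical_groups_degenerate(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert res.degenerate and res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_rank_formula(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        res = kruskal_wallis(groups)
        h, p = kruskal_bruteforce(groups)
        assert res.statistic == pytest.approx(h)
        assert res.p_value == pytest.approx(p)

    def test_two_groups_consistent_with_rank_ordering(self):
        low = kruskal_wallis([[1, 2, 3, 4], [5, 6, 7, 8]])
        near = kruskal_wallis([[1, 3, 5, 7], [2, 4, 6, 8]])
        assert low.statistic > near.statistic
        assert low.p_value < near.p_value

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1.0], []])


class TestOLS:
    def test_exact_linear_fit(self):
        x = np.arange(10.0)
        res = ols_fit(2.0 + 3.0 * x, x[:, None], names=["x"])
        assert res.r2 == pytest.approx(1.0)
        assert res.coefficients == pytest.approx([2.0, 3.0], abs=1e-10)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = rng.integers(8, 30)
            X = rng.normal(size=(n, 3))
            y = rng.normal(size=n)
            res = ols_fit(y, X)
            r2, beta, p = ols_normal_equations(y, X)
            assert res.r2 == pytest.approx(r2, abs=1e-10)
            assert np.allclose(res.coefficients, beta, atol=1e-10)
            assert np.allclose(res.coef_p, p, atol=1e-10)

    def test_noise_free_recovery_to_ten_digits(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 4))
        beta = np.array([1.5, -2.0, 0.0, 3.25])
        res = ols_fit(0.7 + X @ beta, X)
        assert np.allclose(res.coefficients, [0.7, *beta], rtol=1e-10)

    def test_collinear_design_names_columns(self):
        x = np.arange(10.0)
        X = np.column_stack([x, 2.0 * x])
        with pytest.raises(CollinearityError) as err:
            ols_fit(np.random.default_rng(0).normal(size=10), X,
                    names=["a", "b"])
        assert {"a", "b"} <= set(err.value.columns)

    def test_null_r2_near_zero(self):
        rng = np.random.default_rng(10)
        res = ols_fit(rng.normal(size=500), rng.normal(size=(500, 2)))
        assert res.r2 < 0.05
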