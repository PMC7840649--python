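"""Constrained-means ML fitting, fit indices, and Wald machinery."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import norm

from meanbands.design import GROUPS
from meanbands.effects import printed_grid
from meanbands.mean_structure import (
    ConstraintScheme,
    MeanModelFit,
    chisq_diff,
    chisq_pvalue,
    d1_constraint_test,
    fit_constrained,
    pool_fits,
    profile_loglik,
    rmsea,
    srmr,
    wald_separation,
)
from meanbands.outcome_prep import OutcomeGrid
from meanbands.trial_synth import synthesize_outcome_grid


def _random_grid(rng, G=2, T=6, n=40):
    data = tuple(rng.normal(size=(n, T)) @ (np.eye(T) + 0.2 * rng.normal(size=(T, T)))
                 + rng.normal(0, 1, T) for _ in range(G))
    return OutcomeGrid("sim", tuple(range(G)), data)


class TestConstraintScheme:
    def test_labels_canonicalized_and_df(self):
        s = ConstraintScheme(np.array([[7, 7, 2], [2, 9, 9]]))
        assert s.n_ranks == 3
        assert s.ranks.max() == 3 and s.ranks.min() == 1
        assert s.df == 6 - 3

    def test_from_values_recovers_band_partition(self):
        grid = printed_grid("sv_perpetration").means
        s = ConstraintScheme.from_values(grid)
        assert s.n_ranks == 4  # bands -0.04 / 1.51 / 2.16 / 2.75

    def test_nesting_relation(self):
        fine = ConstraintScheme(np.array([[1, 2, 3, 4]]))
        coarse = ConstraintScheme(np.array([[1, 1, 2, 2]]))
        assert coarse.coarsens(fine)
        assert not fine.coarsens(coarse)
        other = ConstraintScheme(np.array([[1, 2, 2, 1]]))
        assert not other.coarsens(fine) or other.coarsens(fine)  # well-defined
        assert coarse.merge(1, 2).n_ranks == 1

    def test_partition_equality_ignores_labels(self):
        a = ConstraintScheme(np.array([[1, 1, 2]]))
        b = ConstraintScheme(np.array([[5, 5, 3]]))
        assert a.same_partition(b)


class TestFitConstrained:
    def test_saturated_scheme_recovers_cell_means(self, rng):
        grid = _random_grid(rng)
        fit = fit_constrained(grid, ConstraintScheme.saturated(2, 6))
        assert fit.chisq == pytest.approx(0.0, abs=1e-8)
        assert fit.df == 0
        assert np.allclose(fit.cell_means(), grid.group_means(), atol=1e-8)

    def test_spherical_single_rank_is_grand_mean(self, rng):
        grid = _random_grid(rng, G=1)
        fit = fit_constrained(grid, ConstraintScheme(np.ones((1, 6), int)),
                              covariance="spherical")
        assert fit.rank_means[0] == pytest.approx(grid.data[0].mean(), abs=1e-8)

    def test_loglik_matches_generic_optimizer(self, rng):
        # small instances, well-specified means; BFGS on an independently
        # coded profile likelihood is the oracle
        for _ in range(5):
            G = int(rng.integers(2, 5))
            scheme = ConstraintScheme(rng.integers(1, 4, size=(G, 6)))
            m_true = rng.normal(0, 2, scheme.n_ranks)
            data = tuple(rng.normal(size=(50, 6)) + m_true[scheme.ranks - 1][g]
                         for g in range(G))
            grid = OutcomeGrid("sim", tuple(range(G)), data)
            fit = fit_constrained(grid, scheme)
            n, ybar, S = (grid.n_per_group(), grid.group_means(),
                          grid.group_covariances())
            A = scheme.design_matrix()
            w = np.sqrt(np.repeat(n, 6).astype(float))
            start = np.linalg.lstsq(A * w[:, None], ybar.ravel() * w,
                                    rcond=None)[0]
            res = minimize(lambda m: -profile_loglik(m, scheme, n, ybar, S),
                           start, method="BFGS", options=dict(gtol=1e-9))
            assert fit.loglik == pytest.approx(-res.fun, rel=1e-6)

    def test_coarsening_never_decreases_chisq(self, rng):
        grid = _random_grid(rng, G=3)
        fine = ConstraintScheme(rng.integers(1, 7, size=(3, 6)))
        coarse = ConstraintScheme((fine.ranks + 1) // 2)
        assert coarse.coarsens(fine)
        f_fine = fit_constrained(grid, fine)
        f_coarse = fit_constrained(grid, coarse)
        assert f_coarse.chisq >= f_fine.chisq - 1e-8

    def test_rank_mean_recovery_on_known_scheme(self):
        means = printed_grid("sv_perpetration").means
        scheme = ConstraintScheme.from_values(means)
        grid = synthesize_outcome_grid(means, n_per_cell=400, sd=2.0, seed=7,
                                       labels=GROUPS)
        fit = fit_constrained(grid, scheme).rank_order_by_mean()
        truth = np.unique(means)
        se = np.sqrt(np.diag(fit.rank_mean_cov))
        assert np.all(np.abs(fit.rank_means - truth) < 3 * se)

    def test_too_small_group_rejected(self, rng):
        grid = OutcomeGrid("sim", (0,), (rng.normal(size=(5, 6)),))
        with pytest.raises(ValueError):
            fit_constrained(grid, ConstraintScheme.saturated(1, 6))


class TestChisqPvalue:
    @pytest.mark.parametrize("stat, df, expected", [
        (34.30, 44, 0.853),
        (44.82, 46, 0.522),
        (55.86, 44, 0.108),
        (22.65, 43, 0.995),
    ])
    def test_difference_test_p_values(self, stat, df, expected):
        assert chisq_pvalue(stat, df) == pytest.approx(expected, abs=5e-4)

    def test_zero_statistic_gives_one(self):
        assert chisq_pvalue(0.0, 7) == 1.0
        assert chisq_pvalue(0.0, 0) == 1.0

    def test_zero_df_with_positive_stat_rejected(self):
        with pytest.raises(ValueError):
            chisq_pvalue(3.0, 0)


class TestChisqDiff:
    def test_saturated_parent_reduces_to_own_test(self, rng):
        grid = _random_grid(rng)
        sat = fit_constrained(grid, ConstraintScheme.saturated(2, 6))
        nested = fit_constrained(grid, ConstraintScheme(np.ones((2, 6), int)))
        stat, df, p = chisq_diff(nested, sat)
        assert stat == pytest.approx(nested.chisq)
        assert df == nested.df
        assert p == pytest.approx(chisq_pvalue(nested.chisq, nested.df))

    def test_identical_schemes_give_null_test(self, rng):
        grid = _random_grid(rng)
        f = fit_constrained(grid, ConstraintScheme(np.ones((2, 6), int)))
        assert chisq_diff(f, f) == (0.0, 0, 1.0)

    def test_additive_over_nesting_chain(self, rng):
        grid = _random_grid(rng, G=2)
        s1 = ConstraintScheme(np.arange(1, 13).reshape(2, 6))
        s2 = ConstraintScheme((np.arange(12).reshape(2, 6) // 2) + 1)
        s3 = ConstraintScheme(np.ones((2, 6), int))
        f1, f2, f3 = (fit_constrained(grid, s) for s in (s1, s2, s3))
        d21, d32, d31 = chisq_diff(f2, f1), chisq_diff(f3, f2), chisq_diff(f3, f1)
        assert d31[0] == pytest.approx(d21[0] + d32[0], abs=1e-6)
        assert d31[1] == d21[1] + d32[1]

    def test_non_nested_rejected(self, rng):
        grid = _random_grid(rng)
        a = fit_constrained(grid, ConstraintScheme(np.array(
            [[1, 1, 2, 2, 3, 3], [4, 4, 5, 5, 6, 6]])))
        b = fit_constrained(grid, ConstraintScheme(np.array(
            [[1, 2, 1, 2, 1, 2], [3, 4, 3, 4, 3, 4]])))
        with pytest.raises(ValueError):
            chisq_diff(a, b)


class TestFitIndices:
    def test_rmsea_truncates_at_zero_and_matches_formula(self):
        assert rmsea(30.0, 44, 3301, 8) == 0.0
        expected = np.sqrt((2 * 44 - 44) / (44 * 3301)) * np.sqrt(8)
        assert rmsea(2 * 44, 44, 3301, 8) == pytest.approx(expected)
        assert rmsea(0.0, 0, 3301, 8) == 0.0  # saturated row prints 0.00

    def test_srmr_hand_example(self):
        # one group, two waves, observed means (0, 10), ML SDs 10, model
        # mean forced to 5: standardized residuals +/-0.5 -> SRMR 0.5
        data = np.array([[-10.0, 0.0], [10.0, 20.0], [-10.0, 0.0], [10.0, 20.0]])
        grid = OutcomeGrid("x", (0,), (data,))
        scheme = ConstraintScheme(np.ones((1, 2), int))
        fit = MeanModelFit(
            scheme=scheme, rank_means=np.array([5.0]),
            rank_mean_cov=np.eye(1), group_covariances=np.empty(0),
            loglik=0.0, loglik_saturated=0.0, chisq=0.0, df=1,
            n_per_group=np.array([4]), n_iter=0, converged=True)
        assert srmr(fit, grid) == pytest.approx(0.5)
        doubled = OutcomeGrid("x", (0,), (np.vstack([data, data]),))
        assert srmr(fit, doubled) == pytest.approx(0.5)

    def test_srmr_zero_for_saturated_fit(self, rng):
        grid = _random_grid(rng)
        fit = fit_constrained(grid, ConstraintScheme.saturated(2, 6))
        assert srmr(fit, grid) == pytest.approx(0.0, abs=1e-7)


class TestWald:
    def _manual_fit(self, means, cov):
        R = len(means)
        return MeanModelFit(
            scheme=ConstraintScheme(np.arange(1, R + 1).reshape(1, R)),
            rank_means=np.asarray(means, float),
            rank_mean_cov=np.asarray(cov, float),
            group_covariances=np.empty(0), loglik=0.0, loglik_saturated=0.0,
            chisq=0.0, df=0, n_per_group=np.array([10]), n_iter=0,
            converged=True)

    def test_equal_means_give_zero_statistic(self):
        fit = self._manual_fit([2.0, 2.0], np.eye(2) * 0.04)
        w = wald_separation(fit, 1, 2)
        assert w.statistic == 0.0 and w.p == 1.0

    def test_antisymmetric_in_rank_order(self):
        fit = self._manual_fit([1.0, 3.0], [[0.04, 0.01], [0.01, 0.09]])
        a, b = wald_separation(fit, 1, 2), wald_separation(fit, 2, 1)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)
        assert a.statistic < 0  # sign follows the mean ordering

    def test_matches_hand_two_sample_z(self, rng):
        # single group, two uncorrelated waves: the rank contrast SE reduces
        # to the two-cell z-test from cell means and SEs
        n = 4000
        data = np.column_stack([rng.normal(0, 1, n), rng.normal(0.2, 1.3, n)])
        grid = OutcomeGrid("x", (0,), (data,))
        fit = fit_constrained(grid, ConstraintScheme(np.array([[1, 2]])))
        w = wald_separation(fit, 1, 2)
        m = data.mean(axis=0)
        S = np.cov(data.T, ddof=0)
        z_hand = (m[0] - m[1]) / np.sqrt((S[0, 0] + S[1, 1] - 2 * S[0, 1]) / n)
        assert w.statistic == pytest.approx(z_hand, rel=1e-6)
        assert w.p == pytest.approx(2 * norm.sf(abs(z_hand)), rel=1e-6)

    def test_degenerate_contrast_rejected(self):
        fit = self._manual_fit([1.0, 2.0], [[0.04, 0.04], [0.04, 0.04]])
        with pytest.raises(ValueError):
            wald_separation(fit, 1, 2)


class TestPooling:
    def test_identical_imputations_collapse_to_single_fit(self, rng):
        grid = _random_grid(rng)
        fit = fit_constrained(grid, ConstraintScheme(np.ones((2, 6), int)))
        pooled = pool_fits([fit, fit, fit])
        assert np.allclose(pooled.rank_means, fit.rank_means)
        assert np.allclose(pooled.rank_mean_cov, fit.rank_mean_cov)
        assert np.allclose(pooled.between_cov, 0.0)
        w_single = wald_separation(fit, 1, 1 if fit.scheme.n_ranks == 1 else 2) \
            if fit.scheme.n_ranks > 1 else None
        assert pooled.m == 3

    def test_d1_reduces_to_wald_chi_square_for_single_fit(self, rng):
        grid = _random_grid(rng)
        parent = ConstraintScheme(np.array([[1, 1, 1, 2, 2, 2],
                                            [3, 3, 3, 4, 4, 4]]))
        nested = ConstraintScheme(np.array([[1, 1, 1, 1, 1, 1],
                                            [2, 2, 2, 2, 2, 2]]))
        fit = fit_constrained(grid, parent)
        stat, k, df2, p = d1_constraint_test([fit], nested)
        assert k == 2 and np.isinf(df2)
        from scipy.stats import chi2
        assert p == pytest.approx(chi2.sf(stat * k, k))

    def test_d1_accepts_true_constraints_rejects_false(self, rng):
        means = np.array([[0.0, 0.0, 0.0, 5.0, 5.0, 5.0]])
        parent = ConstraintScheme(np.array([[1, 1, 2, 3, 3, 4]]))
        true_nested = ConstraintScheme(np.array([[1, 1, 1, 2, 2, 2]]))
        all_one = ConstraintScheme(np.ones((1, 6), int))
        grids = [synthesize_outcome_grid(means, 300, 1.0, seed=s)
                 for s in range(5)]
        fits = [fit_constrained(g, parent) for g in grids]
        _, _, _, p_true = d1_constraint_test(fits, true_nested)
        _, _, _, p_false = d1_constraint_test(fits, all_one)
        assert p_true > 0.05
        assert p_false < 1e-6
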