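"""Mixed-model fitting, LRT and the naive-regression comparator.

Oracles: a direct multivariate-normal log-density for the likelihood, an
exhaustive 2-D grid search over (variance ratio, profiled beta) for the
ML optimum, and textbook regression formulas for the OLS comparator.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from carscan.lmm import (
    AssociationMatrix,
    associate_all,
    associate_motif,
    expression_covariance,
    fit_lmm,
    lrt_pvalue,
    ols_pvalues,
)
from carscan.normalize import ExpressionMatrix, normalize_expression
from carscan.simulate import simulate_matrices


def make_expression(rng, p=40, n=12) -> ExpressionMatrix:
    return normalize_expression(pd.DataFrame(
        rng.standard_normal((p, n)),
        index=[f"g{i}" for i in range(p)],
        columns=[f"c{j}" for j in range(n)],
    ))


def direct_loglik(y, x, beta, s2r, s2e, C):
    """Dense multivariate-normal log-density; independent of the spectral path."""
    n = y.size
    mean = x * beta if x is not None else np.zeros(n)
    V = s2e * C + s2r * np.eye(n)
    return stats.multivariate_normal.logpdf(y, mean=mean, cov=V)


def grid_search_ml(y, x, cov, n_lam=400, n_beta=None):
    """Exhaustive oracle: best profiled loglik over a dense lambda grid.

    beta and the scale are profiled with the same closed forms a
    textbook GLS derivation gives, but the likelihood is evaluated
    densely (no rotation), so the oracle shares no code with fit_lmm.
    """
    n = y.size
    best = -np.inf
    lams = np.concatenate([[0.0], np.logspace(-5, 5, n_lam)])
    for lam in lams:
        V = lam * cov.C_e + np.eye(n)
        Vi = np.linalg.inv(V)
        if x is None:
            beta = 0.0
            resid = y
        else:
            beta = float(x @ Vi @ y / (x @ Vi @ x))
            resid = y - beta * x
        s2r = float(resid @ Vi @ resid / n)
        ll = direct_loglik(y, x, beta if x is not None else 0.0, s2r, lam * s2r, cov.C_e)
        best = max(best, ll)
    return best


class TestExpressionCovariance:
    def test_trace_identity_and_psd(self, rng):
        X = make_expression(rng)
        cov = expression_covariance(X)
        V = np.asarray(X.values)
        np.testing.assert_allclose(
            np.trace(cov.C_e), np.sum(V**2) / cov.p, rtol=1e-10)
        assert (cov.S >= -1e-10).all()
        np.testing.assert_allclose(
            cov.U @ np.diag(cov.S) @ cov.U.T, cov.C_e, atol=1e-8)

    def test_reconstruction_from_gene_outer_products(self, rng):
        X = make_expression(rng)
        cov = expression_covariance(X)
        V = np.asarray(X.values)
        C = sum(np.outer(v, v) for v in V) / cov.p
        np.testing.assert_allclose(C, cov.C_e, atol=1e-10)


class TestFitLmm:
    def test_white_covariance_collapses_to_ols(self, rng):
        n = 20
        X = ExpressionMatrix(np.eye(n) * np.sqrt(n), [f"g{i}" for i in range(n)],
                             [f"c{j}" for j in range(n)], tag="final")
        cov = expression_covariance(X)  # C_e = I exactly
        np.testing.assert_allclose(cov.C_e, np.eye(n), atol=1e-12)
        y = rng.standard_normal(n)
        x = rng.standard_normal(n)
        fit = fit_lmm(y, x, cov)
        beta_ols = float(x @ y / (x @ x))
        assert fit.beta == pytest.approx(beta_ols, abs=1e-6)

    def test_noiseless_self_regression(self, rng):
        X = make_expression(rng, p=30, n=15)
        cov = expression_covariance(X)
        x = np.asarray(X.values[0])
        fit = fit_lmm(x.copy(), x, cov)
        assert fit.beta == pytest.approx(1.0, abs=1e-6)
        assert fit.sigma2_r < 1e-10

    def test_loglik_matches_direct_mvn_density(self, rng):
        X = make_expression(rng, p=25, n=12)
        cov = expression_covariance(X)
        y = rng.standard_normal(12)
        x = rng.standard_normal(12)
        fit = fit_lmm(y, x, cov)
        ll = direct_loglik(y, x, fit.beta, fit.sigma2_r, fit.sigma2_e, cov.C_e)
        assert fit.loglik == pytest.approx(ll, abs=1e-8)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(13)
        X = make_expression(rng, p=60, n=20)
        cov = expression_covariance(X)
        for _ in range(5):
            y = rng.standard_normal(20)
            x = rng.standard_normal(20)
            fit = fit_lmm(y, x, cov)
            oracle = grid_search_ml(y, x, cov)
            assert fit.loglik >= oracle - 1e-4

    def test_collinear_covariates_raise(self, rng):
        X = make_expression(rng)
        cov = expression_covariance(X)
        y = rng.standard_normal(cov.n)
        x = rng.standard_normal(cov.n)
        with pytest.raises(ValueError, match="collinear"):
            fit_lmm(y, x, cov, covariates=[2 * x])

    def test_covariate_changes_fit(self, rng):
        X = make_expression(rng, p=30, n=15)
        cov = expression_covariance(X)
        y = rng.standard_normal(15)
        x = rng.standard_normal(15)
        c = rng.standard_normal(15)
        plain = fit_lmm(y, x, cov)
        adjusted = fit_lmm(y, x, cov, covariates=[c])
        assert adjusted.loglik >= plain.loglik - 1e-10
        assert adjusted.coefficients.size == 2


class TestLrt:
    def test_equal_fits_give_p_one(self, rng):
        X = make_expression(rng)
        cov = expression_covariance(X)
        y = rng.standard_normal(cov.n)
        null = fit_lmm(y, None, cov)
        assert lrt_pvalue(null, null) == 1.0

    def test_chi2_quantile(self):
        from carscan.lmm import LmmFit
        null = LmmFit(0, 1, 0, loglik=0.0, converged=True)
        alt = LmmFit(1, 1, 0, loglik=3.841459 / 2, converged=True)
        assert lrt_pvalue(alt, null) == pytest.approx(0.05, abs=1e-6)

    def test_worse_alternative_clipped(self, rng):
        from carscan.lmm import LmmFit
        null = LmmFit(0, 1, 0, loglik=0.0, converged=True)
        worse = LmmFit(1, 1, 0, loglik=-0.5, converged=True)
        assert lrt_pvalue(worse, null) == 1.0


class TestAssociateMotif:
    def test_duplicate_genes_get_identical_pvalues(self, rng):
        X = make_expression(rng, p=10, n=15)
        V = np.vstack([X.values, X.values[0]])
        X2 = ExpressionMatrix(V, [f"g{i}" for i in range(11)],
                              X.cell_line_ids, tag="final")
        cov = expression_covariance(X2)
        y = rng.standard_normal(15)
        p, b = associate_motif(y, X2, cov)
        assert p[0] == p[10]
        assert b[0] == b[10]

    def test_planted_gene_has_smallest_pvalue(self):
        acc, expr, sfmap, truth = simulate_matrices(
            n_cells=100, n_motifs=4, n_tf_genes=16, n_genes=60,
            car_fraction=0.5, effect_size=1.0, seed=19,
        )
        X = normalize_expression(expr)
        cov = expression_covariance(X)
        planted = {d["motif"]: d["tf"] for d in truth.planted}
        motif_idx = {m: i for i, m in enumerate(acc.row_ids)}
        for motif, tf in planted.items():
            y = np.asarray(acc.values[motif_idx[motif]], float)
            p, _ = associate_motif(y, X, cov)
            assert X.gene_ids[int(np.argmin(p))] == tf


class TestOls:
    def test_textbook_t_statistic(self):
        rng = np.random.default_rng(1)
        n = 10
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        X = ExpressionMatrix(x[None, :], ["g0"], [f"c{j}" for j in range(n)], tag="final")
        p = ols_pvalues(y, X)[0]
        beta = x @ y / (x @ x)
        rss = np.sum((y - beta * x) ** 2)
        se = np.sqrt(rss / (n - 1) / (x @ x))
        expect = 2 * stats.t.sf(abs(beta / se), n - 1)
        assert p == pytest.approx(expect, rel=1e-10)

    def test_self_regression_is_minimum(self, rng):
        X = make_expression(rng, p=20, n=15)
        y = np.asarray(X.values[7])
        p = ols_pvalues(y, X)
        assert int(np.argmin(p)) == 7

    def test_ols_inflated_versus_lmm_under_confounding(self):
        acc, expr, _, _ = simulate_matrices(
            n_cells=80, n_motifs=3, n_tf_genes=12, n_genes=120,
            car_fraction=0.0, effect_size=0.0, confounder_strength=1.5, seed=23,
        )
        X = normalize_expression(expr)
        cov = expression_covariance(X)
        lmm_p, ols_p = [], []
        for y in np.asarray(acc.values, float):
            p, _ = associate_motif(y, X, cov)
            lmm_p.append(p)
            ols_p.append(ols_pvalues(y, X))
        lmm_p, ols_p = np.concatenate(lmm_p), np.concatenate(ols_p)

        def inflation(p):
            return np.median(stats.chi2.isf(p, 1)) / stats.chi2.ppf(0.5, 1)

        assert inflation(ols_p) > inflation(lmm_p)
        assert inflation(ols_p) > 2.0


class TestAssociateAll:
    def test_shapes_and_equivariance(self, small_cohort):
        acc, expr, _, _ = small_cohort
        X = normalize_expression(expr.iloc[:12])
        from carscan.normalize import AccessibilityMatrix, inverse_normal_transform
        A = AccessibilityMatrix(
            np.apply_along_axis(inverse_normal_transform, 1, acc.values[:3]),
            acc.row_ids[:3], acc.cell_line_ids, tag="final",
        )
        assoc = associate_all(A, X)
        assert assoc.pvalues.shape == (3, 12)
        assert ((assoc.pvalues.to_numpy() > 0) & (assoc.pvalues.to_numpy() <= 1)).all()
        # permuting gene rows permutes p-value columns identically
        perm = np.random.default_rng(0).permutation(12)
        Xp = ExpressionMatrix(np.asarray(X.values)[perm],
                              [X.gene_ids[i] for i in perm],
                              X.cell_line_ids, tag="final")
        assoc_p = associate_all(A, Xp)
        np.testing.assert_allclose(
            assoc.pvalues.to_numpy()[:, perm], assoc_p.pvalues.to_numpy())

    def test_cell_line_mismatch_lists_difference(self, small_cohort):
        acc, expr, _, _ = small_cohort
        X = normalize_expression(expr.iloc[:12, :-1])
        from carscan.normalize import AccessibilityMatrix
        A = AccessibilityMatrix(np.asarray(acc.values[:2]), acc.row_ids[:2],
                                acc.cell_line_ids, tag="final")
        with pytest.raises(ValueError, match=acc.cell_line_ids[-1]):
            associate_all(A, X)
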