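"""Design construction, nodewise lasso, de-sparsified estimator, PCA baseline."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from nlhsim.inference import (
    DesignMatrix,
    build_design,
    desparsified_lasso,
    linear_hsim_design,
    nodewise_lasso_cv,
    nodewise_lasso_fixed,
    pca_retain,
)
from nlhsim.kpca import KpcSet


def _kpc(set_id, scores, strategy="A"):
    n, h = scores.shape
    return KpcSet(
        set_id=set_id, scores=scores, eigenvalues=np.zeros(n),
        strategy=strategy, retained=np.arange(h),
    )


def _exact_cov_data(rng, n, Sigma):
    """Sample matrix whose empirical covariance equals Sigma exactly."""
    Z = rng.standard_normal((n, Sigma.shape[0]))
    Z -= Z.mean(axis=0)
    Q, _ = np.linalg.qr(Z)
    L = np.linalg.cholesky(Sigma)
    return np.sqrt(n) * Q @ L.T


class TestBuildDesign:
    def test_concatenation_count(self):
        rng = np.random.default_rng(0)
        sets = [_kpc("g1", rng.standard_normal((30, 2))),
                _kpc("g2", rng.standard_normal((30, 3)))]
        design = build_design(sets, covariates=rng.standard_normal((30, 4)))
        assert design.q == 9
        assert (design.column_map["kind"] == "covariate").sum() == 4

    def test_columns_standardized(self):
        rng = np.random.default_rng(1)
        design = build_design([_kpc("g", 5 + 3 * rng.standard_normal((40, 3)))])
        assert np.max(np.abs(design.Z.mean(axis=0))) < 1e-12
        assert np.allclose(design.Z.std(axis=0), 1.0)

    def test_column_map_partitions_design(self):
        rng = np.random.default_rng(2)
        sets = [_kpc("a", rng.standard_normal((20, 2))),
                _kpc("b", rng.standard_normal((20, 1)))]
        design = build_design(sets)
        cols = sorted(
            int(c) for sid in ("a", "b") for c in design.set_columns(sid)
        )
        assert cols == list(range(design.q))

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal((25, 2))
        scores[:, 1] = 4.2
        with pytest.warns(UserWarning):
            design = build_design([_kpc("g", scores), _kpc("h", rng.standard_normal((25, 1)))])
        assert design.q == 2

    def test_set_losing_all_columns_is_error(self):
        with pytest.raises(ValueError):
            build_design([_kpc("g", np.ones((20, 1)))])


class TestNodewise:
    @pytest.mark.parametrize("lam", [0.05, 0.2, 0.5])
    def test_fixed_penalty_matches_sklearn_lasso(self, lam):
        rng = np.random.default_rng(4)
        Z = rng.standard_normal((80, 8)) + 0.6 * rng.standard_normal((80, 1))
        Z = (Z - Z.mean(0)) / Z.std(0)
        Gamma, _, tau2 = nodewise_lasso_fixed(Z, lam)
        for j in range(8):
            keep = np.arange(8) != j
            ref = Lasso(alpha=lam, fit_intercept=False, tol=1e-12).fit(
                Z[:, keep], Z[:, j]
            )
            assert np.allclose(Gamma[keep, j], ref.coef_, atol=1e-4)
            resid = Z[:, j] - Z[:, keep] @ ref.coef_
            assert tau2[j] == pytest.approx(Z[:, j] @ resid / 80, abs=1e-4)

    def test_cv_variant_reasonable_and_deterministic(self):
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((60, 6))
        Z = (Z - Z.mean(0)) / Z.std(0)
        g1 = nodewise_lasso_cv(Z, n_alphas=10, cv_folds=5, seed=3)
        g2 = nodewise_lasso_cv(Z, n_alphas=10, cv_folds=5, seed=3)
        assert np.array_equal(g1[0], g2[0])
        assert np.all(g1[2] > 0)


class TestDesparsified:
    def test_zero_penalty_exact_inverse_reproduces_ols(self):
        rng = np.random.default_rng(6)
        Z = rng.standard_normal((50, 5))
        beta = np.array([1.0, -0.5, 0.0, 0.3, 0.0])
        y = Z @ beta + 0.4 * rng.standard_normal(50)
        design = build_design([_kpc("g", Z)])
        res = desparsified_lasso(design, y, penalty=0.0, exact_inverse=True)
        ols, *_ = np.linalg.lstsq(design.Z, y - y.mean(), rcond=None)
        assert np.allclose(res.beta_debiased, ols, atol=1e-8)

    def test_pvalue_identity_and_monotonicity(self):
        rng = np.random.default_rng(7)
        Z = rng.standard_normal((60, 4))
        y = Z[:, 0] * 0.8 + rng.standard_normal(60)
        design = build_design([_kpc("g", Z)])
        res = desparsified_lasso(design, y, cv_folds=5, seed=0)
        from scipy.stats import norm

        expected = 2 * norm.sf(np.abs(res.beta_debiased) / res.se)
        assert np.allclose(res.p, np.clip(expected, np.finfo(float).tiny, 1), rtol=1e-12)
        t = np.abs(res.beta_debiased) / res.se
        order = np.argsort(t)
        assert np.all(np.diff(res.p[order]) <= 1e-15)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(8)
        Z = rng.standard_normal((70, 5))
        y = Z[:, 1] + rng.standard_normal(70)
        d1 = build_design([_kpc("g", Z)])
        Zf = Z * np.array([1, -1, 1, -1, 1])
        d2 = build_design([_kpc("g", Zf)])
        r1 = desparsified_lasso(d1, y, cv_folds=5, seed=1)
        r2 = desparsified_lasso(d2, y, cv_folds=5, seed=1)
        assert np.allclose(r1.p, r2.p, atol=1e-10)

    def test_null_pvalues_roughly_uniform(self):
        # pooled over replicates: pointwise normal calibration of the
        # de-sparsified estimator under a global null
        from scipy.stats import kstest

        pvals = []
        for s in range(60):
            rng = np.random.default_rng(1000 + s)
            Z = rng.standard_normal((120, 12))
            y = rng.standard_normal(120)
            design = build_design([_kpc("g", Z[:, :6]), _kpc("h", Z[:, 6:])])
            res = desparsified_lasso(design, y, cv_folds=5, n_alphas=10, seed=s)
            pvals.extend(res.p)
        assert kstest(pvals, "uniform").pvalue > 1e-3

    def test_unpenalized_covariates_partialling(self):
        # covariates left out of the l1 penalty get classical OLS estimates,
        # and the KPC block is tested after projecting the covariates out
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        n = 150
        cov = rng.standard_normal((n, 2))
        Z = rng.standard_normal((n, 6)) + 0.4 * cov[:, [0]]
        y = 1.5 * cov[:, 0] + 0.8 * Z[:, 0] + rng.standard_normal(n)
        design = build_design([_kpc("g", Z)], covariates=cov,
                              covariate_ids=["age", "sex"])
        res = desparsified_lasso(design, y, cv_folds=5, n_alphas=10,
                                 seed=0, penalize_covariates=False)
        is_cov = design.column_map["kind"].to_numpy() == "covariate"
        ols = sm.OLS(y, sm.add_constant(design.Z[:, is_cov])).fit()
        assert np.allclose(res.beta_debiased[is_cov], ols.params[1:], atol=1e-8)
        assert np.allclose(res.se[is_cov], ols.bse[1:], atol=1e-8)
        # the causal KPC stays detectable after partialling
        kpc_p = res.p[~is_cov]
        assert kpc_p.min() < 0.01
        assert np.all((res.p > 0) & (res.p <= 1))

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            desparsified_lasso(
                DesignMatrix(Z=np.empty((20, 0)), column_map=None, strategy="A"),
                np.zeros(20),
            )


class TestLinearBaseline:
    def test_one_dimensional_set_keeps_single_component(self):
        rng = np.random.default_rng(9)
        assert pca_retain(rng.standard_normal((30, 1))).shape[1] == 1

    def test_equicorrelated_set_compresses_to_one(self):
        rng = np.random.default_rng(10)
        Sigma = np.full((5, 5), 0.9) + 0.1 * np.eye(5)
        X = _exact_cov_data(rng, 200, Sigma)
        # leading share (1 + 4*0.9)/5 = 0.92 > 0.85
        assert pca_retain(X).shape[1] == 1

    def test_isotropic_set_needs_all_components(self):
        rng = np.random.default_rng(11)
        X = _exact_cov_data(rng, 200, np.eye(5))
        # each component explains exactly 20%: four give 0.80 <= 0.85
        assert pca_retain(X).shape[1] == 5

    def test_linear_design_from_sets(self):
        rng = np.random.default_rng(12)
        sets = {"g1": rng.standard_normal((50, 3)), "g2": rng.standard_normal((50, 2))}
        design = linear_hsim_design(sets)
        assert design.strategy == "PCA"
        assert design.q >= 2
        assert set(design.column_map["set_id"]) == {"g1", "g2"}
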