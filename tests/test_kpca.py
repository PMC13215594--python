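"""Kernel PCA decomposition, component retention, pre-image machinery."""

import numpy as np
import pytest

from nlhsim.kernel import bandwidth, center_kernel, exact_fit, nystrom_fit
from nlhsim.kpca import (
    cv_reconstruction_curve,
    cv_reconstruction_error,
    kpca_decompose,
    preimage_fixed_point,
    refine_average_eigenvalue,
    select_A,
    select_PA,
)


@pytest.fixture
def cloud():
    rng = np.random.default_rng(0)
    return rng.standard_normal((60, 3))


class TestDecompose:
    def test_trace_preserved(self, cloud):
        ck = center_kernel(exact_fit(cloud))
        dec = kpca_decompose(ck)
        assert dec.eigenvalues.sum() == pytest.approx(np.trace(ck.implied_matrix()), abs=1e-8)

    def test_exact_and_full_landmark_paths_agree(self, cloud):
        sigma = bandwidth(cloud)
        d1 = kpca_decompose(center_kernel(exact_fit(cloud, sigma)))
        d2 = kpca_decompose(center_kernel(nystrom_fit(cloud, sigma, m=len(cloud), seed=0)))
        assert np.allclose(d1.eigenvalues, d2.eigenvalues, atol=1e-8)

    def test_duplicate_rows_give_zero_eigenvalue(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 2))
        X[5] = X[4]
        dec = kpca_decompose(center_kernel(exact_fit(X)))
        assert dec.eigenvalues[-1] == pytest.approx(0.0, abs=1e-10)

    def test_scores_orthogonal_with_eigenvalue_norms(self, cloud):
        dec = kpca_decompose(center_kernel(exact_fit(cloud)))
        G = dec.scores.T @ dec.scores
        lam = dec.eigenvalues[: dec.rank]
        assert np.allclose(G, np.diag(lam), atol=1e-6 * lam[0])

    def test_descending_order(self, cloud):
        dec = kpca_decompose(center_kernel(nystrom_fit(cloud, m=20, seed=3)))
        assert np.all(np.diff(dec.eigenvalues) <= 1e-12)
        assert dec.eigenvalues.min() >= 0.0


class TestSelectA:
    def test_single_dominant_component(self):
        assert select_A([3.0, 1.0, 0.0, 0.0]).tolist() == [0]

    def test_two_of_eight(self):
        lam = [4.0, 3.0, 1.0, 0, 0, 0, 0, 0]
        assert select_A(lam).tolist() == [0, 1]

    def test_flat_spectrum_fallback(self):
        assert select_A([2.0, 2.0, 2.0]).tolist() == [0]

    def test_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            select_A([0.0, 0.0])


class TestRefinePA:
    def test_strict_rule_within_bound(self):
        lam = np.array([3.0, 1.0, 0.0, 0.0])
        # lambda_bar = 1: component 2 (value 1) fails the strict rule
        assert refine_average_eigenvalue(lam, h_pre=2).tolist() == [0]

    def test_fallback_to_leading(self):
        lam = np.array([1.0, 1.0, 1.0, 1.0])
        assert refine_average_eigenvalue(lam, h_pre=2).tolist() == [0]


class TestPreimage:
    def test_single_training_point_fixed_immediately(self):
        x0 = np.array([[1.5, -2.0]])
        x, conv = preimage_fixed_point([1.0], x0, sigma=1.0)
        assert conv
        assert np.allclose(x, x0[0])

    def test_tight_cluster_recovers_mean(self):
        # kernel wide relative to the cluster: the fixed point (the
        # kernel-weighted mean) coincides with the arithmetic mean up to
        # O(r^3 / sigma^2) for cluster radius r
        rng = np.random.default_rng(2)
        X = 0.05 * rng.standard_normal((40, 2)) + np.array([1.0, -1.0])
        x, conv = preimage_fixed_point(np.full(40, 1.0 / 40), X, sigma=1.0)
        assert conv
        assert np.linalg.norm(x - X.mean(axis=0)) < 1e-3

    def test_gamma_scale_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((25, 2))
        gamma = rng.random(25)
        x1, _ = preimage_fixed_point(gamma, X, sigma=2.0, max_iter=200)
        x2, _ = preimage_fixed_point(7.3 * gamma, X, sigma=2.0, max_iter=200)
        assert np.allclose(x1, x2, atol=1e-10)

    def test_all_zero_gamma_rejected(self):
        with pytest.raises(ValueError):
            preimage_fixed_point(np.zeros(5), np.zeros((5, 2)), sigma=1.0)


class TestCvReconstruction:
    def test_re_is_mean_of_fold_errors(self, cloud):
        sigma = bandwidth(cloud)
        re, trace = cv_reconstruction_error(cloud, sigma, h=2, n_folds=5, seed=0)
        assert re == pytest.approx(trace.fold_errors.mean(), abs=1e-12)

    def test_deterministic_given_seed(self, cloud):
        sigma = bandwidth(cloud)
        t1 = cv_reconstruction_curve(cloud, sigma, [1, 2, 3], n_folds=5, seed=7)
        t2 = cv_reconstruction_curve(cloud, sigma, [1, 2, 3], n_folds=5, seed=7)
        assert np.array_equal(t1.RE, t2.RE)
        assert np.array_equal(t1.fold_errors, t2.fold_errors)

    def test_too_few_rows_for_folds(self):
        with pytest.raises(ValueError):
            cv_reconstruction_curve(np.random.default_rng(0).standard_normal((5, 2)),
                                    1.0, [1], n_folds=10)

    def test_more_components_do_not_hurt_mean_reconstruction(self):
        # on single-cluster Gaussian data the curve is non-increasing in
        # tendency: RE at the largest candidate dimension does not exceed
        # RE(1) (richer targets reconstruct the held-out mean at least as
        # well as the coarse one)
        ok = 0
        for s in range(6):
            rng = np.random.default_rng(40 + s)
            X = rng.standard_normal((70, 3))
            sigma = bandwidth(X)
            trace = cv_reconstruction_curve(X, sigma, range(1, 9), n_folds=10, seed=s)
            ok += trace.RE[-1] <= trace.RE[0] + 1e-6
        assert ok >= 5


class TestSelectPA:
    def test_single_candidate(self, cloud):
        sigma = bandwidth(cloud)
        lam = kpca_decompose(center_kernel(exact_fit(cloud, sigma))).eigenvalues
        retained, h_pre, _ = select_PA(cloud, lam, sigma, h_max=1, n_folds=5, seed=0)
        assert h_pre == 1
        assert retained.tolist() == [0]

    def test_retained_subset_of_top_h_pre(self, cloud):
        sigma = bandwidth(cloud)
        lam = kpca_decompose(center_kernel(exact_fit(cloud, sigma))).eigenvalues
        retained, h_pre, _ = select_PA(cloud, lam, sigma, h_max=6, n_folds=5, seed=1)
        assert retained.size >= 1
        assert retained.max() < h_pre
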