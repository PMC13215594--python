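"""Kernel PCA per set and retention of kernel principal components.

Two complementary retention strategies:

* **A** (average eigenvalue): keep components whose eigenvalue strictly
  exceeds the mean of the full length-n spectrum (numerical zeros included,
  so the rule deliberately depends on n).
* **PA** (pre-image guided + average-eigenvalue refinement): a 10-fold
  cross-validated pre-image reconstruction error picks a coarse dimension
  h_pre = argmin_h RE(h); the average-eigenvalue rule is then applied within
  the top h_pre components.

The pre-image of a feature-space expansion is computed with Mika's
fixed-point iteration for Gaussian kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .kernel import CenteredKernel, center_kernel, fit_kernel

__all__ = [
    "KpcaDecomposition",
    "KpcSet",
    "PreimageTrace",
    "kpca_decompose",
    "select_A",
    "preimage_fixed_point",
    "cv_reconstruction_error",
    "cv_reconstruction_curve",
    "select_PA",
]

_RANK_RTOL = 1e-10


@dataclass
class KpcaDecomposition:
    """Eigenpairs of a centered per-set kernel.

    ``eigenvalues`` is the full descending length-n spectrum (exact zeros
    beyond the numerical rank); ``scores[:, k]`` = nu_k * sqrt(lambda_k)
    with nu_k the unit-norm eigenvector, so score columns are orthogonal
    with squared norm lambda_k.  Only the first ``rank`` score columns are
    stored.
    """

    eigenvalues: np.ndarray
    scores: np.ndarray
    n: int

    @property
    def rank(self) -> int:
        return self.scores.shape[1]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude loading of each column positive
    (reproducibility across linear-algebra backends)."""
    if vectors.size == 0:
        return vectors
    idx = np.abs(vectors).argmax(axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def kpca_decompose(ck: CenteredKernel) -> KpcaDecomposition:
    """Eigendecompose the centered kernel, descending, negatives clamped.

    On the low-rank path the decomposition runs on the small r x r core
    F^T F and is lifted back, never materializing n x n.
    """
    n = ck.n
    if ck.matrix is not None:
        w, V = np.linalg.eigh(ck.matrix)
        w, V = w[::-1].copy(), V[:, ::-1]
        np.clip(w, 0.0, None, out=w)
        keep = w > _RANK_RTOL * max(w[0], 1e-300)
        V = _fix_signs(V[:, keep])
        scores = V * np.sqrt(w[keep])
        w[~keep] = 0.0
        return KpcaDecomposition(eigenvalues=w, scores=scores, n=n)
    F = ck.factor
    G = F.T @ F
    w, V = np.linalg.eigh(G)
    w, V = w[::-1].copy(), V[:, ::-1]
    np.clip(w, 0.0, None, out=w)
    keep = w > _RANK_RTOL * max(w[0], 1e-300)
    scores = F @ V[:, keep]  # = nu_k sqrt(lambda_k)
    nu = scores / np.sqrt(w[keep])
    signs = np.sign(nu[np.abs(nu).argmax(axis=0), np.arange(nu.shape[1])])
    signs[signs == 0] = 1.0
    scores = scores * signs
    eigenvalues = np.zeros(n)
    eigenvalues[: keep.sum()] = w[keep]
    return KpcaDecomposition(eigenvalues=eigenvalues, scores=scores, n=n)


def select_A(eigenvalues) -> np.ndarray:
    """Average-eigenvalue rule: retain {k : lambda_k > mean(lambda)} (strict).

    The mean is over the full spectrum including numerical zeros.  If the
    strict rule retains nothing (all positive eigenvalues equal), fall back
    to the single leading component.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0 or lam.max() <= 0.0:
        raise ValueError("all-zero spectrum: degenerate kernel")
    retained = np.flatnonzero(lam > lam.mean())
    if retained.size == 0:
        retained = np.array([0])
    return retained


def preimage_fixed_point(
    gamma,
    X_train,
    sigma: float,
    init=None,
    tol: float = 1e-5,
    max_iter: int = 100,
    rng=None,
):
    """Mika's fixed-point pre-image of psi = sum_i gamma_i phi(x_i).

    Iterates  x <- sum_i gamma_i k(x, x_i) x_i / sum_i gamma_i k(x, x_i)
    until the step norm drops below ``tol``.  A vanishing denominator
    (|.| < 1e-12) triggers one restart from a small random perturbation of
    the training mean; a second occurrence returns non-converged.

    Returns (x, converged).
    """
    gamma = np.asarray(gamma, dtype=float).ravel()
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    if not np.any(gamma != 0.0):
        raise ValueError("expansion has no nonzero coefficient")
    if rng is None:
        rng = np.random.default_rng(0)
    mean = X_train.mean(axis=0)
    x = mean.copy() if init is None else np.asarray(init, dtype=float).copy()
    restarted = False
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for _ in range(max_iter):
        d2 = ((X_train - x) ** 2).sum(axis=1)
        w = gamma * np.exp(-d2 * inv2s2)
        den = w.sum()
        if abs(den) < 1e-12:
            if restarted:
                return x, False
            restarted = True
            scale = X_train.std() if X_train.std() > 0 else 1.0
            x = mean + 1e-3 * scale * rng.standard_normal(X_train.shape[1])
            continue
        x_new = (w @ X_train) / den
        if np.linalg.norm(x_new - x) < tol:
            return x_new, True
        x = x_new
    return x, False


def _preimage_batch(gammas, X_train, sigma, init, tol, max_iter, rng):
    """Run the fixed-point iteration for several expansions at once.

    ``gammas`` is (t, H): one expansion per column over the same training
    rows; ``init`` is (H, d).  Semantics per column match
    :func:`preimage_fixed_point` (including the single restart on a
    vanishing denominator).  Returns (points (H, d), converged (H,)).
    """
    t, H = gammas.shape
    P = np.array(init, dtype=float, copy=True)
    converged = np.zeros(H, dtype=bool)
    movable = np.any(gammas != 0.0, axis=0)  # all-zero expansions stay at init
    restarted = np.zeros(H, dtype=bool)
    mean = X_train.mean(axis=0)
    sq = (X_train * X_train).sum(axis=1)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    tol2 = tol * tol
    for _ in range(max_iter):
        live = movable & ~converged
        if not live.any():
            break
        d2 = sq[:, None] + (P * P).sum(axis=1)[None, :] - 2.0 * (X_train @ P.T)
        np.maximum(d2, 0.0, out=d2)
        W = gammas * np.exp(-d2 * inv2s2)
        den = W.sum(axis=0)
        bad = (np.abs(den) < 1e-12) & live
        if bad.any():
            scale = X_train.std() if X_train.std() > 0 else 1.0
            for j in np.flatnonzero(bad):
                if restarted[j]:
                    movable[j] = False  # give up; stays non-converged
                else:
                    restarted[j] = True
                    P[j] = mean + 1e-3 * scale * rng.standard_normal(X_train.shape[1])
            live = live & ~bad
            if not live.any():
                continue
        den = np.where(np.abs(den) < 1e-12, 1.0, den)
        P_new = (W.T @ X_train) / den[:, None]
        step2 = ((P_new - P) ** 2).sum(axis=1)
        upd = live
        P[upd] = P_new[upd]
        converged |= upd & (step2 < tol2)
    return P, converged


@dataclass
class PreimageTrace:
    """Reconstruction-error curve from the pre-image cross-validation."""

    h_grid: np.ndarray
    RE: np.ndarray  # mean over folds, per h
    fold_errors: np.ndarray  # (n_folds, len(h_grid))
    converged: np.ndarray  # bool, same shape as fold_errors


def _fold_assignment(n: int, n_folds: int, seed) -> np.ndarray:
    """Deterministic folds: seeded shuffle, then position modulo n_folds."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.intp)
    fold_of[perm] = np.arange(n) % n_folds
    return fold_of


def cv_reconstruction_curve(
    X_set,
    sigma: float,
    h_grid,
    n_folds: int = 10,
    seed=0,
    preimage_tol: float = 1e-5,
    preimage_max_iter: int = 100,
    kernel_opts: dict | None = None,
) -> PreimageTrace:
    """RE(h) for every h in ``h_grid``, averaged over ``n_folds`` folds.

    In fold i, KPCA runs on the training rows; the raw feature-space mean of
    the training rows is projected onto the top-h centered eigenvectors
    (the centered mean projects to zero, so the raw mean is the only
    non-degenerate target), its pre-image x_hat is computed by fixed point,
    and RE_i(h) = ||mu_i - x_hat||^2 against the held-out input-space mean.
    The fixed point for h warm-starts from the solution at h-1.
    """
    X = np.atleast_2d(np.asarray(X_set, dtype=float))
    n = X.shape[0]
    h_grid = np.asarray(sorted(set(int(h) for h in np.atleast_1d(h_grid))), dtype=int)
    if h_grid.min() < 1:
        raise ValueError("candidate dimensions must be >= 1")
    if n < n_folds:
        raise ValueError(f"n={n} < n_folds={n_folds}")
    kernel_opts = dict(kernel_opts or {})
    fold_of = _fold_assignment(n, n_folds, seed)
    H = len(h_grid)
    fold_errors = np.zeros((n_folds, H))
    converged = np.zeros((n_folds, H), dtype=bool)
    # expansion coefficients for every (fold, h) pair, zero-padded to the
    # full row set so all pre-images run in a single batched fixed point
    gammas = np.zeros((n, n_folds * H))
    init = np.zeros((n_folds * H, X.shape[1]))
    mus = np.zeros((n_folds, X.shape[1]))
    for i in range(n_folds):
        T = np.flatnonzero(fold_of != i)
        S = np.flatnonzero(fold_of == i)
        if T.size < 2:
            raise ValueError(f"fold {i} has fewer than 2 training rows")
        Xt = X[T]
        model = fit_kernel(Xt, sigma, **kernel_opts)
        dec = kpca_decompose(center_kernel(model))
        rank = dec.rank
        lam = dec.eigenvalues[:rank]
        # expansion basis over training rows: alpha_k = nu_k / sqrt(lambda_k)
        A = dec.scores / lam  # (t, rank)
        # projection of the raw training feature mean onto each eigenvector:
        # <phi_bar, v_k> = alpha_k . (colmeans(K) - grandmean(K))
        if model.exact:
            u = model.C.mean(axis=0)
        else:
            u = model.half @ model.half.mean(axis=0)
        c = A.T @ (u - u.mean())
        mus[i] = X[S].mean(axis=0)
        # cumulative expansions: column h-1 of the cumsum is the projection
        # onto the top-h eigenvectors
        Gh = np.cumsum(A * c[None, :], axis=1)
        h_eff = np.minimum(h_grid, rank)
        g = Gh[:, h_eff - 1]
        g = g - g.mean(axis=0, keepdims=True)
        gammas[T, i * H : (i + 1) * H] = g
        init[i * H : (i + 1) * H] = Xt.mean(axis=0)
    rng = np.random.default_rng(seed)
    pts, conv = _preimage_batch(
        gammas, X, sigma, init, preimage_tol, preimage_max_iter, rng
    )
    for i in range(n_folds):
        block = slice(i * H, (i + 1) * H)
        fold_errors[i] = ((mus[i][None, :] - pts[block]) ** 2).sum(axis=1)
        converged[i] = conv[block]
    return PreimageTrace(
        h_grid=h_grid,
        RE=fold_errors.mean(axis=0),
        fold_errors=fold_errors,
        converged=converged,
    )


def cv_reconstruction_error(
    X_set, sigma: float, h: int, n_folds: int = 10, seed=0, **kwargs
) -> tuple[float, PreimageTrace]:
    """RE(h) for a single candidate dimension (mean of the fold errors)."""
    trace = cv_reconstruction_curve(X_set, sigma, [h], n_folds=n_folds, seed=seed, **kwargs)
    return float(trace.RE[0]), trace


def refine_average_eigenvalue(eigenvalues, h_pre: int) -> np.ndarray:
    """Strict average-eigenvalue rule restricted to the top ``h_pre``
    components (the PA stage-2 refinement); the mean is over the full
    spectrum, and the leading component is kept if the rule empties."""
    lam = np.asarray(eigenvalues, dtype=float)
    within = np.flatnonzero(lam[:h_pre] > lam.mean())
    if within.size == 0:
        within = np.array([0])
    return within


def select_PA(
    X_set,
    eigenvalues,
    sigma: float,
    h_max: int = 20,
    n_folds: int = 10,
    seed=0,
    preimage_tol: float = 1e-5,
    preimage_max_iter: int = 100,
    kernel_opts: dict | None = None,
) -> tuple[np.ndarray, int, PreimageTrace]:
    """Pre-image-guided retention: h_pre = argmin_h RE(h) (smallest h on
    ties), then the strict average-eigenvalue rule within the top h_pre
    components (mean over the full spectrum, as in :func:`select_A`);
    fallback to the leading component if the refinement empties the set.

    Returns (retained indices, h_pre, trace).
    """
    if h_max < 1:
        raise ValueError("h_max must be >= 1")
    lam = np.asarray(eigenvalues, dtype=float)
    trace = cv_reconstruction_curve(
        X_set,
        sigma,
        np.arange(1, h_max + 1),
        n_folds=n_folds,
        seed=seed,
        preimage_tol=preimage_tol,
        preimage_max_iter=preimage_max_iter,
        kernel_opts=kernel_opts,
    )
    h_pre = int(trace.h_grid[int(np.argmin(trace.RE))])
    return refine_average_eigenvalue(lam, h_pre), h_pre, trace


@dataclass
class KpcSet:
    """Retained kernel principal components of one set."""

    set_id: str
    scores: np.ndarray  # n x h retained KPC scores
    eigenvalues: np.ndarray  # full descending spectrum, length n
    strategy: str  # "A" or "PA"
    retained: np.ndarray  # indices into the spectrum
    h_pre: int | None = None  # coarse bound (PA only)

    @property
    def h(self) -> int:
        return self.scores.shape[1]
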