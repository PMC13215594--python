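"""Per-set Gaussian kernel with data-driven bandwidth and Nyström low rank.

The kernel for a set with predictor block X is K(x_i, x_j) =
exp(-||x_i - x_j||^2 / (2 sigma^2)), with sigma the square root of the
average pairwise squared Euclidean distance over distinct sample pairs.
For large n the full n x n kernel is replaced by the Nyström approximation
K~ = C W^+ C^T built from m landmark rows, which cuts the eigendecomposition
cost from O(n^3) to O(n m^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelModel",
    "CenteredKernel",
    "bandwidth",
    "rbf_kernel",
    "nystrom_fit",
    "exact_fit",
    "fit_kernel",
    "center_kernel",
    "default_landmarks",
]

_PINV_RTOL = 1e-10  # relative singular-value cutoff for the landmark block


def bandwidth(X) -> float:
    """sigma = sqrt(mean over distinct unordered pairs of ||x_i - x_j||^2).

    Self-pairs are excluded: their distances are identically zero and would
    deflate sigma.  Computed in closed form from first and second moments,
    which is exact and O(n p):

        sum_{i<j} ||x_i - x_j||^2 = n * sum_i ||x_i||^2 - ||sum_i x_i||^2
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    sq = float((X * X).sum())
    s = X.sum(axis=0)
    total = n * sq - float(s @ s)
    mean_sq = 2.0 * total / (n * (n - 1))
    if mean_sq <= 0.0 or not np.isfinite(mean_sq):
        raise ValueError("all rows identical: degenerate set, bandwidth undefined")
    return math.sqrt(mean_sq)


def rbf_kernel(A, B, sigma: float) -> np.ndarray:
    """Gaussian kernel block exp(-||a - b||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("column counts differ")
    d2 = (A * A).sum(1)[:, None] + (B * B).sum(1)[None, :] - 2.0 * (A @ B.T)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / (2.0 * sigma * sigma))


def default_landmarks(n: int) -> int:
    """Default landmark count m = min(n, max(50, ceil(2 sqrt(n))))."""
    return min(n, max(50, math.ceil(2.0 * math.sqrt(n))))


@dataclass
class KernelModel:
    """Low-rank (or exact) Gaussian kernel for one predictor set.

    The implied kernel is K~ = C W^+ C^T; ``half`` is a factor with
    K~ = half @ half.T, used so that centering and eigendecomposition never
    materialize an n x n matrix on the Nyström path.  When ``exact`` is
    True, C is the full kernel K itself and ``half`` is unset.
    """

    sigma: float
    landmarks: np.ndarray
    C: np.ndarray
    W_pinv: np.ndarray | None
    n: int
    exact: bool = False
    half: np.ndarray | None = None

    @property
    def m(self) -> int:
        return len(self.landmarks)

    def implied_kernel(self) -> np.ndarray:
        """The full n x n K~ (materializes it; small-n diagnostics only)."""
        if self.exact:
            return self.C
        return self.half @ self.half.T


def exact_fit(X, sigma: float | None = None) -> KernelModel:
    """Exact-kernel pathway: the full Gaussian kernel, no approximation."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if sigma is None:
        sigma = bandwidth(X)
    K = rbf_kernel(X, X, sigma)
    n = X.shape[0]
    return KernelModel(sigma=sigma, landmarks=np.arange(n), C=K, W_pinv=None, n=n, exact=True)


def nystrom_fit(X, sigma: float | None = None, m: int | None = None, seed=None) -> KernelModel:
    """Nyström approximation from m uniformly sampled landmark rows.

    Landmarks are drawn without replacement; the landmark block W is
    pseudo-inverted with singular values below 1e-10 * s_max truncated, which
    keeps the implied K~ symmetric positive semidefinite.  With m = n the
    implied kernel reproduces the exact one to numerical precision.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if sigma is None:
        sigma = bandwidth(X)
    if m is None:
        m = default_landmarks(n)
    if not 1 <= m <= n:
        raise ValueError(f"landmark count m={m} outside 1..n={n}")
    rng = np.random.default_rng(seed)
    landmarks = np.sort(rng.choice(n, size=m, replace=False))
    C = rbf_kernel(X, X[landmarks], sigma)
    W = rbf_kernel(X[landmarks], X[landmarks], sigma)
    w, V = np.linalg.eigh(W)
    keep = w > _PINV_RTOL * w.max()
    w, V = w[keep], V[:, keep]
    W_pinv = (V / w) @ V.T
    half = C @ (V / np.sqrt(w))  # K~ = half half^T
    return KernelModel(
        sigma=sigma, landmarks=landmarks, C=C, W_pinv=W_pinv, n=n, exact=False, half=half
    )


def fit_kernel(
    X,
    sigma: float | None = None,
    *,
    exact_threshold: int = 2000,
    landmarks: int | None = None,
    seed=None,
) -> KernelModel:
    """Dispatch: exact kernel for small sets, Nyström above the threshold."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] <= exact_threshold:
        return exact_fit(X, sigma)
    return nystrom_fit(X, sigma, m=landmarks, seed=seed)


@dataclass
class CenteredKernel:
    """Feature-space-centered kernel K~_C = H K~ H, H = I - (1/n) 1 1^T.

    Held either as a dense symmetric ``matrix`` (exact path) or as a
    low-rank ``factor`` F with K~_C = F F^T (Nyström path).
    """

    n: int
    matrix: np.ndarray | None = None
    factor: np.ndarray | None = None

    def implied_matrix(self) -> np.ndarray:
        if self.matrix is not None:
            return self.matrix
        return self.factor @ self.factor.T


def center_kernel(model: KernelModel) -> CenteredKernel:
    """Center the (possibly low-rank) kernel in feature space.

    Exact path: K_C = K - rowmean - colmean + grandmean.  Nyström path: with
    K~ = F F^T it suffices to subtract the column means of F, since
    H F F^T H = (F - mean(F)) (F - mean(F))^T.  Row sums of the implied
    centered kernel are zero to numerical precision either way.
    """
    if model.exact:
        K = model.C
        rm = K.mean(axis=1, keepdims=True)
        Kc = K - rm - rm.T + rm.mean()
        Kc = 0.5 * (Kc + Kc.T)
        return CenteredKernel(n=model.n, matrix=Kc)
    F = model.half - model.half.mean(axis=0, keepdims=True)
    return CenteredKernel(n=model.n, factor=F)
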