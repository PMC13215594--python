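"""De-sparsified LASSO inference over concatenated kernel components.

The retained KPCs of all sets (plus carried-forward covariates) form a
joint design Z; an initial cross-validated LASSO fit is bias-corrected with
nodewise regressions, giving asymptotically normal per-column estimators

    b_hat = beta_lasso + (1/n) Theta_hat Z^T (y - Z beta_lasso)

with Theta_hat the nodewise relaxed inverse of Sigma_hat = Z^T Z / n, and
standard errors se_j = sigma_eps * sqrt((Theta_hat Sigma_hat Theta_hat^T)_jj / n).

All nodewise problems share the design, so the per-node lasso paths are
solved jointly by accelerated proximal gradient (FISTA) on the Gram matrix
— one matrix recursion for all q nodes per penalty level — with per-node
penalties chosen by cross-validation (lambda_min rule).  The objective per
node is the same as scikit-learn's Lasso: (1/2n)||r||^2 + alpha ||gamma||_1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .kpca import KpcSet

__all__ = [
    "DesignMatrix",
    "InferenceResult",
    "build_design",
    "desparsified_lasso",
    "linear_hsim_design",
    "pca_retain",
    "nodewise_lasso_cv",
]


@dataclass
class DesignMatrix:
    """Standardized joint design: KPC columns set by set, then covariates."""

    Z: np.ndarray
    column_map: pd.DataFrame  # column_id, kind ("kpc"|"covariate"), set_id
    strategy: str

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def set_columns(self, set_id: str) -> np.ndarray:
        return np.flatnonzero((self.column_map["set_id"] == set_id).to_numpy())


def _standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    sd = M.std(axis=0)
    ok = sd > 1e-12 * (np.abs(mean) + 1.0)  # constant up to rounding -> drop
    out = np.zeros_like(M, dtype=float)
    out[:, ok] = (M[:, ok] - mean[ok]) / sd[ok]
    return out, ok


def build_design(
    kpc_sets: list[KpcSet],
    covariates=None,
    covariate_ids: list[str] | None = None,
    strategy: str | None = None,
) -> DesignMatrix:
    """Concatenate retained KPC scores set by set, standardize every column
    (mean 0, variance 1), append standardized covariates, and record the
    column -> set mapping.  Zero-variance columns are dropped with a
    warning; a set losing all its columns is an error.
    """
    if not kpc_sets:
        raise ValueError("no KPC sets supplied")
    strategies = {ks.strategy for ks in kpc_sets}
    if strategy is None:
        if len(strategies) != 1:
            raise ValueError(f"mixed strategies in design: {strategies}")
        strategy = strategies.pop()
    n = kpc_sets[0].scores.shape[0]
    blocks, ids, kinds, set_ids = [], [], [], []
    for ks in kpc_sets:
        if ks.scores.shape[0] != n:
            raise ValueError("KPC sets disagree on sample count")
        S, ok = _standardize(ks.scores)
        if not ok.any():
            raise ValueError(f"set {ks.set_id!r} lost all columns (zero variance)")
        if not ok.all():
            warnings.warn(f"set {ks.set_id!r}: dropped {int((~ok).sum())} zero-variance column(s)")
        blocks.append(S[:, ok])
        for k in np.flatnonzero(ok):
            ids.append(f"{ks.set_id}:kpc{ks.retained[k] + 1}")
            kinds.append("kpc")
            set_ids.append(ks.set_id)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if covariate_ids is None:
            covariate_ids = [f"cov{j + 1}" for j in range(C.shape[1])]
        Cs, ok = _standardize(C)
        if not ok.all():
            warnings.warn(f"dropped {int((~ok).sum())} zero-variance covariate(s)")
        blocks.append(Cs[:, ok])
        for k in np.flatnonzero(ok):
            ids.append(str(covariate_ids[k]))
            kinds.append("covariate")
            set_ids.append(str(covariate_ids[k]))
    Z = np.hstack(blocks)
    cmap = pd.DataFrame({"column_id": ids, "kind": kinds, "set_id": set_ids})
    return DesignMatrix(Z=Z, column_map=cmap, strategy=strategy)


# ---------------------------------------------------------------------------
# nodewise lasso, all nodes jointly


def _fista_multinode(Sig: np.ndarray, lam: np.ndarray, Gamma0: np.ndarray,
                     tol: float = 1e-7, max_iter: int = 1000,
                     L: float | None = None) -> np.ndarray:
    """Solve, for every node j simultaneously,

        min_{gamma, gamma_j = 0}  (1/2) gamma' Sig gamma - Sig[:,j]' gamma
                                   + lam_j ||gamma||_1

    (the nodewise lasso of column j on the others, written on the
    normalized Gram Sig = Z'Z/n).  FISTA with constant step 1/L.
    """
    q = Sig.shape[0]
    if L is None:
        L = float(np.linalg.eigvalsh(Sig)[-1])
    if L <= 0:
        return np.zeros_like(Gamma0)
    step = 1.0 / L
    Gamma = Gamma0.copy()
    Y = Gamma.copy()
    t = 1.0
    diag = np.arange(q)
    thresh = step * lam[None, :]
    for _ in range(max_iter):
        grad = Sig @ Y - Sig
        Gnew = Y - step * grad
        Gnew = np.sign(Gnew) * np.maximum(np.abs(Gnew) - thresh, 0.0)
        Gnew[diag, diag] = 0.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Y = Gnew + ((t - 1.0) / t_new) * (Gnew - Gamma)
        delta = np.abs(Gnew - Gamma).max()
        Gamma, t = Gnew, t_new
        if delta < tol:
            break
    return Gamma


def nodewise_lasso_fixed(Z: np.ndarray, lam) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nodewise lasso at fixed per-node penalties (no cross-validation).

    ``lam`` may be a scalar or a length-q vector.  The scalar default used
    by :func:`desparsified_lasso` under ``nodewise="universal"`` is the
    theory rate sqrt(2 log q / n) appropriate for standardized columns.
    """
    n, q = Z.shape
    Sig = (Z.T @ Z) / n
    lam_vec = np.broadcast_to(np.asarray(lam, dtype=float), (q,)).copy()
    if q == 1:
        return np.zeros((1, 1)), lam_vec, np.array([Sig[0, 0]])
    Gamma = np.zeros((q, q))
    # nodes whose largest off-diagonal |Sigma_hat| is below lambda have the
    # exact solution 0 (KKT); only the rest need the iterative solve
    offdiag = np.abs(Sig - np.diag(np.diag(Sig)))
    active = np.flatnonzero(offdiag.max(axis=0) > lam_vec)
    if active.size:
        sub = _fista_multinode_cols(Sig, lam_vec[active], active, tol=1e-6, max_iter=2000)
        Gamma[:, active] = sub
    tau2 = np.diag(Sig) - np.einsum("jk,kj->j", Sig, Gamma)
    return Gamma, lam_vec, tau2


def _fista_multinode_cols(Sig: np.ndarray, lam: np.ndarray, cols: np.ndarray,
                          tol: float = 1e-5, max_iter: int = 1000) -> np.ndarray:
    """FISTA restricted to a subset of node columns (same objective as
    :func:`_fista_multinode`; the gradient still uses the full Sigma)."""
    q = Sig.shape[0]
    L = float(np.linalg.eigvalsh(Sig)[-1])
    step = 1.0 / L
    B = np.zeros((q, cols.size))
    Y = B.copy()
    t = 1.0
    rows = cols
    pos = np.arange(cols.size)
    target = Sig[:, cols]
    thresh = step * lam[None, :]
    for _ in range(max_iter):
        grad = Sig @ Y - target
        Bn = Y - step * grad
        Bn = np.sign(Bn) * np.maximum(np.abs(Bn) - thresh, 0.0)
        Bn[rows, pos] = 0.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Y = Bn + ((t - 1.0) / t_new) * (Bn - B)
        delta = np.abs(Bn - B).max()
        B, t = Bn, t_new
        if delta < tol:
            break
    return B


def nodewise_lasso_cv(
    Z: np.ndarray,
    n_alphas: int = 20,
    eps: float = 1e-3,
    cv_folds: int = 10,
    seed=0,
    tol: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node cross-validated nodewise lasso over a shared design.

    Each node j gets its own geometric penalty grid from lambda_max_j =
    max_{k != j} |Sigma_hat_kj| down to eps * lambda_max_j; the grid index
    minimizing the summed held-out prediction error is chosen per node
    (lambda_min rule), and the final coefficients are refit on all rows.

    Returns (Gamma, lam_chosen, tau2) where Gamma[:, j] holds node j's
    coefficients (Gamma[j, j] = 0) and
    tau2_j = (1/n) z_j' (z_j - Z_{-j} gamma_j).
    """
    n, q = Z.shape
    if q == 1:
        return np.zeros((1, 1)), np.zeros(1), np.array([float(Z[:, 0] @ Z[:, 0]) / n])
    G = Z.T @ Z
    Sig = G / n
    offdiag = np.abs(Sig - np.diag(np.diag(Sig)))
    lam_max = offdiag.max(axis=0)
    lam_max = np.maximum(lam_max, 1e-12)
    grid = np.geomspace(1.0, eps, n_alphas)  # multiplicative ladder
    folds = np.empty(n, dtype=np.intp)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds[perm] = np.arange(n) % cv_folds
    cv_err = np.zeros((q, n_alphas))
    eye = np.eye(q)
    for f in range(cv_folds):
        tr = folds != f
        va = ~tr
        Ztr, Zva = Z[tr], Z[va]
        Sig_tr = (Ztr.T @ Ztr) / max(tr.sum(), 1)
        G_va = Zva.T @ Zva
        Gamma = np.zeros((q, q))
        L_tr = float(np.linalg.eigvalsh(Sig_tr)[-1])
        for a in range(n_alphas):
            Gamma = _fista_multinode(Sig_tr, lam_max * grid[a], Gamma, tol=tol, L=L_tr)
            R = eye - Gamma
            cv_err[:, a] += np.einsum("ij,ij->j", R, G_va @ R) / max(va.sum(), 1)
    best = cv_err.argmin(axis=1)
    # full-data path, harvesting each node at its chosen grid position
    Gamma_path = np.zeros((q, q))
    Gamma_final = np.zeros((q, q))
    lam_chosen = lam_max * grid[best]
    L_full = float(np.linalg.eigvalsh(Sig)[-1])
    for a in range(n_alphas):
        Gamma_path = _fista_multinode(Sig, lam_max * grid[a], Gamma_path, tol=tol, L=L_full)
        sel = best == a
        if sel.any():
            Gamma_final[:, sel] = Gamma_path[:, sel]
    # tau2_j = (1/n) z_j'(z_j - Z_{-j} gamma_j) = Sig_jj - Sig[j,:] gamma_j
    tau2 = np.diag(Sig) - np.einsum("jk,kj->j", Sig, Gamma_final)
    return Gamma_final, lam_chosen, tau2


@dataclass
class InferenceResult:
    """De-sparsified LASSO estimates with per-column normal p-values."""

    beta_debiased: np.ndarray
    se: np.ndarray
    p: np.ndarray
    lambda_: float
    sigma_eps: float
    column_map: pd.DataFrame
    beta_lasso: np.ndarray = field(default=None, repr=False)
    diagnostics: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        out = self.column_map.copy()
        out["beta_debiased"] = self.beta_debiased
        out["se"] = self.se
        out["p"] = self.p
        return out

    def pvalues_by_set(self) -> dict[str, np.ndarray]:
        """Per-set vectors of KPC p-values (covariates excluded)."""
        out: dict[str, np.ndarray] = {}
        kpc = self.column_map["kind"].to_numpy() == "kpc"
        for set_id in pd.unique(self.column_map.loc[kpc, "set_id"]):
            mask = kpc & (self.column_map["set_id"].to_numpy() == set_id)
            out[str(set_id)] = self.p[mask]
        return out


def desparsified_lasso(
    design: DesignMatrix,
    y,
    cv_folds: int = 10,
    n_alphas: int = 20,
    eps: float = 1e-3,
    seed=0,
    penalty: float | str = "cv",
    nodewise: str = "cv",
    exact_inverse: bool = False,
    penalize_covariates: bool = True,
) -> InferenceResult:
    """De-sparsified (debiased) LASSO over a standardized design.

    ``penalty="cv"`` selects the initial penalty by K-fold cross-validation
    over a geometric grid of ``n_alphas`` values down to ``eps`` times the
    largest useful penalty; a float forces that penalty (0 gives the
    un-penalized initial fit used by the least-squares oracle check).

    ``nodewise`` chooses how the relaxed-inverse penalties are set:
    ``"cv"`` (per-node cross-validation, lambda_min rule) or
    ``"universal"`` (the single theory rate sqrt(2 log q / n), much cheaper
    when q is large).  ``exact_inverse=True`` replaces the nodewise relaxed
    inverse with Sigma_hat^{-1} (valid only for q < n).

    With ``penalize_covariates=False`` covariate columns are left out of the
    l1 penalty entirely: the outcome and the KPC columns are residualized
    on the covariates (Frisch-Waugh partialling), the de-sparsified lasso
    runs on the residualized KPC design, and the covariates receive
    classical least-squares estimates.
    """
    Z = design.Z
    n, q = Z.shape
    if q < 1:
        raise ValueError("empty design")
    if n < 10:
        raise ValueError("need n >= 10")
    y = np.asarray(y, dtype=float).ravel()

    if not penalize_covariates and design.column_map is not None:
        cov_cols = np.flatnonzero(design.column_map["kind"].to_numpy() == "covariate")
        if cov_cols.size:
            return _partialled_desparsified(
                design, y, cov_cols, cv_folds=cv_folds, n_alphas=n_alphas,
                eps=eps, seed=seed, penalty=penalty, nodewise=nodewise,
                exact_inverse=exact_inverse,
            )

    ybar = y.mean()
    yc = y - ybar

    if penalty == "cv":
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=_seed_int(seed))
        lcv = LassoCV(alphas=n_alphas, eps=eps, cv=cv, fit_intercept=False).fit(Z, yc)
        beta = lcv.coef_
        lam = float(lcv.alpha_)
    else:
        lam = float(penalty)
        if lam == 0.0:
            beta, *_ = np.linalg.lstsq(Z, yc, rcond=None)
        else:
            from sklearn.linear_model import Lasso

            beta = Lasso(alpha=lam, fit_intercept=False).fit(Z, yc).coef_

    resid = yc - Z @ beta
    s_hat = int(np.count_nonzero(beta))
    df = max(n - s_hat, n // 2)  # degrees-of-freedom floor at n/2
    sigma_eps = float(np.sqrt((resid @ resid) / df))

    Sig = (Z.T @ Z) / n
    if exact_inverse:
        Theta = np.linalg.inv(Sig)
    else:
        if nodewise == "universal":
            lam_node = np.sqrt(2.0 * np.log(q) / n)
            Gamma, _, tau2 = nodewise_lasso_fixed(Z, lam_node)
        elif nodewise == "cv":
            Gamma, _, tau2 = nodewise_lasso_cv(
                Z, n_alphas=n_alphas, eps=max(eps, 1e-3), cv_folds=cv_folds, seed=seed
            )
        else:
            raise ValueError(f"unknown nodewise mode {nodewise!r}")
        bad = tau2 <= 1e-10
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} singular nodewise problem(s); ridge fallback applied"
            )
            # ridge fallback: gamma_j solves (Sig_{-j,-j} + lam_r I) g = Sig_{-j,j}
            lam_r = 1e-3
            for j in np.flatnonzero(bad):
                keep = np.arange(q) != j
                g = np.linalg.solve(
                    Sig[np.ix_(keep, keep)] + lam_r * np.eye(q - 1), Sig[keep, j]
                )
                Gamma[keep, j] = g
                Gamma[j, j] = 0.0
                tau2[j] = max(Sig[j, j] - Sig[j, :] @ Gamma[:, j], lam_r)
        C = np.eye(q) - Gamma.T  # row j: e_j - gamma_j
        Theta = C / tau2[:, None]

    b = beta + (Theta @ (Z.T @ resid)) / n
    M = Theta @ Sig @ Theta.T
    se = sigma_eps * np.sqrt(np.clip(np.diag(M), 1e-300, None) / n)
    pvals = 2.0 * stats.norm.sf(np.abs(b) / se)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    sel = np.flatnonzero(beta)
    diag = {}
    if sel.size:
        diag["min_eig_selected"] = float(np.linalg.eigvalsh(Sig[np.ix_(sel, sel)])[0])
    return InferenceResult(
        beta_debiased=b,
        se=se,
        p=pvals,
        lambda_=lam,
        sigma_eps=sigma_eps,
        column_map=design.column_map,
        beta_lasso=beta,
        diagnostics=diag,
    )


def _partialled_desparsified(design, y, cov_cols, **kwargs) -> InferenceResult:
    """Unpenalized-covariate variant (Frisch-Waugh partialling).

    The outcome and every KPC column are projected off the covariates (plus
    an intercept); the de-sparsified lasso then runs on the re-standardized
    residual design.  Covariate rows of the result carry the classical
    least-squares estimates from the y-on-covariates fit (normal p-values,
    consistent with the penalized columns).
    """
    Z = design.Z
    n, q = Z.shape
    kpc_cols = np.setdiff1d(np.arange(q), cov_cols)
    if kpc_cols.size == 0:
        raise ValueError("design contains only covariates")
    C = np.column_stack([np.ones(n), Z[:, cov_cols]])
    Qc, _ = np.linalg.qr(C)

    def _resid(M):
        return M - Qc @ (Qc.T @ M)

    yr = _resid(y)
    Zr, ok = _standardize(_resid(Z[:, kpc_cols]))
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} KPC column(s) collinear with covariates dropped"
        )
    keep_kpc = kpc_cols[ok]
    sub_map = design.column_map.iloc[keep_kpc].reset_index(drop=True)
    sub = desparsified_lasso(
        DesignMatrix(Z=Zr[:, ok], column_map=sub_map, strategy=design.strategy),
        yr, penalize_covariates=True, **kwargs,
    )
    # classical OLS block for the unpenalized covariates
    beta_c, *_ = np.linalg.lstsq(C, y, rcond=None)
    res_y = y - C @ beta_c
    dof = max(n - C.shape[1], 1)
    s2 = float(res_y @ res_y) / dof
    cov_beta = s2 * np.linalg.inv(C.T @ C)
    se_c = np.sqrt(np.diag(cov_beta))[1:]
    b_c = beta_c[1:]
    p_c = np.clip(2.0 * stats.norm.sf(np.abs(b_c) / se_c), np.finfo(float).tiny, 1.0)

    beta_out = np.full(q, np.nan)
    se_out = np.full(q, np.nan)
    p_out = np.full(q, np.nan)
    beta_out[keep_kpc], se_out[keep_kpc], p_out[keep_kpc] = sub.beta_debiased, sub.se, sub.p
    beta_out[cov_cols], se_out[cov_cols], p_out[cov_cols] = b_c, se_c, p_c
    dropped = np.setdiff1d(kpc_cols, keep_kpc)
    if dropped.size:  # collinear columns: no signal left, report null
        beta_out[dropped], se_out[dropped], p_out[dropped] = 0.0, np.inf, 1.0
    return InferenceResult(
        beta_debiased=beta_out, se=se_out, p=p_out,
        lambda_=sub.lambda_, sigma_eps=sub.sigma_eps,
        column_map=design.column_map, beta_lasso=None,
        diagnostics=sub.diagnostics,
    )


def _seed_int(seed) -> int:
    return int(np.random.default_rng(seed).integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# Linear-HSIM baseline: per-set PCA at 85% cumulative variance


def pca_retain(X_set, threshold: float = 0.85) -> np.ndarray:
    """Leading principal-component scores of a standardized set, keeping the
    smallest block whose cumulative explained variance exceeds ``threshold``."""
    Xs, ok = _standardize(np.atleast_2d(np.asarray(X_set, dtype=float)))
    Xs = Xs[:, ok]
    if Xs.shape[1] == 0:
        raise ValueError("set has no varying column")
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, threshold, side="right")) + 1
    k = min(k, len(s))
    return U[:, :k] * s[:k]


def linear_hsim_design(
    screened_sets: dict[str, np.ndarray],
    covariates=None,
    covariate_ids: list[str] | None = None,
    threshold: float = 0.85,
) -> DesignMatrix:
    """Design for the Linear-HSIM comparator: per-set linear PCA retaining
    components that explain over ``threshold`` cumulative variance, then the
    identical standardization/concatenation as :func:`build_design`."""
    kpc_sets = []
    for set_id, X_set in screened_sets.items():
        scores = pca_retain(X_set, threshold=threshold)
        kpc_sets.append(
            KpcSet(
                set_id=set_id,
                scores=scores,
                eigenvalues=np.zeros(scores.shape[0]),
                strategy="PCA",
                retained=np.arange(scores.shape[1]),
            )
        )
    return build_design(kpc_sets, covariates, covariate_ids, strategy="PCA")
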