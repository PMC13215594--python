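"""Distance-correlation sure independence screening (DC-SIS).

Model-free marginal screening: each candidate predictor (and covariate) is
ranked by its sample distance correlation with the outcome, and the top
``d = floor(n / log n)`` columns are retained.  Distance correlation is zero
(in population) if and only if the predictor and outcome are independent, so
the ranking is sensitive to nonlinear as well as linear dependence.

Surviving covariates are flagged so the downstream pipeline carries them
forward as linear adjusters only, never kernelizing them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ScreeningResult", "distance_correlation", "dcsis_screen", "default_retention"]


def _center_distance_matrix(v: np.ndarray) -> np.ndarray:
    """Double-centered pairwise |v_i - v_j| matrix of a 1-d sample."""
    d = np.abs(v[:, None] - v[None, :])
    rm = d.mean(axis=1, keepdims=True)
    return d - rm - rm.T + d.mean()


def distance_correlation(x, y) -> float:
    """Sample distance correlation of two univariate samples, in [0, 1].

    Uses the V-statistic (double-centering) form: with A, B the
    double-centered distance matrices of x and y,

        dCov^2 = mean(A * B),  dVar^2 = mean(A * A),
        dCor   = sqrt( dCov^2 / sqrt(dVarx^2 * dVary^2) ).

    Returns 0.0 when either sample has zero distance variance (constant
    input), by convention.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    a = _center_distance_matrix(x)
    b = _center_distance_matrix(y)
    dvar_x = (a * a).mean()
    dvar_y = (b * b).mean()
    if dvar_x <= 0.0 or dvar_y <= 0.0:
        return 0.0
    dcov2 = max((a * b).mean(), 0.0)
    return float(np.sqrt(dcov2 / np.sqrt(dvar_x * dvar_y)))


def _distance_correlation_columns(X: np.ndarray, y: np.ndarray, chunk: int = 32) -> np.ndarray:
    """Distance correlation of each column of X with y, vectorized in chunks."""
    n, p = X.shape
    b = _center_distance_matrix(y)
    dvar_y = (b * b).mean()
    scores = np.zeros(p)
    if dvar_y <= 0.0:
        return scores
    for lo in range(0, p, chunk):
        cols = X[:, lo : lo + chunk]
        d = np.abs(cols[:, None, :] - cols[None, :, :])  # (n, n, c)
        rm = d.mean(axis=1, keepdims=True)
        a = d - rm - np.swapaxes(rm, 0, 1) + d.mean(axis=(0, 1), keepdims=True)
        dcov2 = np.einsum("ijc,ij->c", a, b) / (n * n)
        dvar_x = np.einsum("ijc,ijc->c", a, a) / (n * n)
        ok = dvar_x > 0.0
        np.clip(dcov2, 0.0, None, out=dcov2)
        scores[lo : lo + chunk][ok] = np.sqrt(dcov2[ok] / np.sqrt(dvar_x[ok] * dvar_y))
    return scores


def default_retention(n: int) -> int:
    """The DC-SIS retention count floor(n / log n), natural logarithm."""
    if n < 8:
        raise ValueError("need n >= 8 so that n/log n >= 3")
    return int(math.floor(n / math.log(n)))


@dataclass
class ScreeningResult:
    """Outcome of DC-SIS screening.

    ``scores`` holds the distance correlation of every candidate column
    (predictors then covariates) with the outcome; ``kept_predictors`` and
    ``kept_covariates`` are the ids that survive, predictors ordered by
    score descending (ties broken by original column order).
    """

    scores: pd.Series
    kept_predictors: list[str]
    kept_covariates: list[str]
    d: int
    status: str = "ok"
    kept_predictor_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    kept_covariate_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    def to_frame(self) -> pd.DataFrame:
        kept = set(self.kept_predictors) | set(self.kept_covariates)
        kinds = self.scores.index.to_series().map(
            lambda c: "covariate" if c in set(self.kept_covariates) or c in self._covariate_ids else "snp"
        )
        return pd.DataFrame(
            {
                "column_id": self.scores.index,
                "kind": kinds.values,
                "dcor": self.scores.values,
                "kept": [c in kept for c in self.scores.index],
            }
        ).reset_index(drop=True)

    # populated by dcsis_screen; used only for reporting
    _covariate_ids: set = field(default_factory=set)


def dcsis_screen(
    X,
    y,
    covariates=None,
    d: int | None = None,
    predictor_ids: list[str] | None = None,
    covariate_ids: list[str] | None = None,
) -> ScreeningResult:
    """Rank predictors and covariates by distance correlation with y and
    retain the top ``d`` columns overall (default ``floor(n/log n)``).

    Covariates that survive are flagged as linear adjusters and are excluded
    from downstream kernelization; surviving predictors proceed to gene
    mapping.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have different sample counts")
    if predictor_ids is None:
        predictor_ids = [f"x{j + 1}" for j in range(p)]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if covariate_ids is None:
            covariate_ids = [f"cov{j + 1}" for j in range(C.shape[1])]
    else:
        C = np.empty((n, 0))
        covariate_ids = covariate_ids or []
    if d is None:
        d = default_retention(n)
    if d <= 0:
        raise ValueError("retention count d must be positive")

    all_ids = list(predictor_ids) + list(covariate_ids)
    Z = np.hstack([X, C]) if C.size else X
    status = "ok"
    if np.all(Z.std(axis=0) == 0.0):
        warnings.warn("all candidate columns are constant; nothing screened")
        status = "all_constant"
        scores = pd.Series(np.zeros(Z.shape[1]), index=all_ids)
        return ScreeningResult(scores, [], [], d, status, _covariate_ids=set(covariate_ids))

    vals = _distance_correlation_columns(Z, y)
    scores = pd.Series(vals, index=all_ids)
    order = np.argsort(-vals, kind="stable")  # ties -> original column order
    kept = order[: min(d, len(order))]
    kept_pred = [int(k) for k in kept if k < p]
    kept_cov = [int(k) - p for k in kept if k >= p]
    return ScreeningResult(
        scores=scores,
        kept_predictors=[predictor_ids[k] for k in kept_pred],
        kept_covariates=[covariate_ids[k] for k in kept_cov],
        d=d,
        status=status,
        kept_predictor_indices=np.asarray(kept_pred, dtype=np.intp),
        kept_covariate_indices=np.asarray(kept_cov, dtype=np.intp),
        _covariate_ids=set(covariate_ids),
    )
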