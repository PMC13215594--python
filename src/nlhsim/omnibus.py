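"""Set-level p-value aggregation and the two-stage omnibus test.

Per set and per KPC-retention strategy, the de-sparsified per-KPC p-values
are combined with two complementary statistics:

* **MinP** — Sidak-adjusted minimum, sensitive to sparse strong effects;
* **ART-A** — adaptive rank-truncated product, sensitive to dense weak
  signals: for several truncation points k, W_k = -sum_{i<=k} log p_(i) is
  calibrated by Monte Carlo under independent uniforms, and the minimum
  per-k p-value is itself calibrated against the same null draws (so the
  adaptivity over k is accounted for exactly at Monte-Carlo resolution).

Stage 1 merges MinP and ART-A with the Cauchy combination test within each
strategy; Stage 2 merges the two strategies' stage-1 p-values with another
Cauchy aggregation, yielding one omnibus p per set.  Benjamini-Hochberg
FDR is applied across sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SetResult",
    "minp_combine",
    "arta_combine",
    "ArtaCalibration",
    "cauchy_combine",
    "two_stage_omnibus",
    "bh_fdr",
    "default_k_grid",
]

_P_FLOOR = 1e-300
_CAUCHY_CLIP = 1e-15


def minp_combine(p_vec) -> float:
    """Sidak-adjusted minimum p-value: 1 - (1 - min p)^L."""
    p = np.asarray(p_vec, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    pmin = p.min()
    if pmin >= 1.0:
        return 1.0
    # -expm1(L * log1p(-min)) is the numerically stable form
    return float(-np.expm1(p.size * np.log1p(-pmin)))


def cauchy_combine(p_vec, weights=None) -> float:
    """Cauchy combination test: T = sum w_i tan((0.5 - p_i) pi),
    p = 0.5 - arctan(T)/pi.  Valid under arbitrary dependence; inputs are
    clipped to [1e-15, 1 - 1e-15] before the tangent transform."""
    p = np.asarray(p_vec, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        w = w / w.sum()
    p = np.clip(p, _CAUCHY_CLIP, 1.0 - _CAUCHY_CLIP)
    T = float(w @ np.tan((0.5 - p) * math.pi))
    return min(max(0.5 - math.atan(T) / math.pi, _P_FLOOR), 1.0)


def default_k_grid(L: int) -> np.ndarray:
    """Truncation points {1, ceil(L/4), ceil(L/2), ceil(3L/4), L}, deduped."""
    ks = {1, math.ceil(L / 4), math.ceil(L / 2), math.ceil(3 * L / 4), L}
    return np.asarray(sorted(ks), dtype=int)


class ArtaCalibration:
    """Shared Monte-Carlo null tables for the adaptive rank-truncated product.

    For a fixed vector length L, truncation grid and draw count, the null
    statistics W_k and the per-draw adaptive minima are simulated once and
    reused for every observed vector of that length (the tables depend on
    nothing but (L, k_grid, n_mc), so sharing them across sets within an
    analysis is statistically free).
    """

    def __init__(self, L: int, k_grid=None, n_mc: int = 5000, rng=None):
        if L < 1:
            raise ValueError("L must be >= 1")
        if n_mc < 1000:
            raise ValueError("n_mc must be >= 1000")
        self.L = int(L)
        self.k_grid = default_k_grid(L) if k_grid is None else np.asarray(
            sorted(set(int(k) for k in k_grid)), dtype=int
        )
        if self.k_grid.min() < 1 or self.k_grid.max() > L:
            raise ValueError("truncation points must lie in 1..L")
        self.n_mc = int(n_mc)
        rng = np.random.default_rng(rng)
        U = rng.random((self.n_mc, self.L))
        U.sort(axis=1)
        W = np.cumsum(-np.log(np.clip(U, _P_FLOOR, None)), axis=1)[:, self.k_grid - 1]
        # per-draw per-k p-values against the shared draws (rank from the top)
        self._W_sorted = np.sort(W, axis=0)  # ascending, per k
        ranks = np.empty_like(W, dtype=float)
        for j in range(W.shape[1]):
            # p = P(W_null >= w); self included -> at least 1/n_mc
            ranks[:, j] = self.n_mc - np.searchsorted(self._W_sorted[:, j], W[:, j], side="left")
        p_null = ranks / self.n_mc
        self._T_sorted = np.sort(p_null.min(axis=1))

    def pvalue(self, p_vec) -> float:
        p = np.sort(np.asarray(p_vec, dtype=float).ravel())
        if p.size != self.L:
            raise ValueError(f"expected length {self.L}, got {p.size}")
        W_obs = np.cumsum(-np.log(p))[self.k_grid - 1]
        per_k = np.empty(len(self.k_grid))
        for j in range(len(self.k_grid)):
            ge = self.n_mc - np.searchsorted(self._W_sorted[:, j], W_obs[j], side="left")
            per_k[j] = (1 + ge) / (1 + self.n_mc)
        T_obs = per_k.min()
        le = np.searchsorted(self._T_sorted, T_obs, side="right")
        return float((1 + le) / (1 + self.n_mc))


def arta_combine(p_vec, k_grid=None, n_mc: int = 5000, seed=None,
                 calibration: ArtaCalibration | None = None) -> float:
    """Adaptive rank-truncated product p-value via Monte-Carlo calibration.

    Zero inputs are clipped to 1e-300 with a warning.  Deterministic given
    ``seed``.  A precomputed :class:`ArtaCalibration` (matching L and
    k_grid) may be supplied to amortize the null simulation.
    """
    p = np.asarray(p_vec, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0.0):
        warnings.warn("p-value of 0 clipped to 1e-300")
        p = np.clip(p, _P_FLOOR, None)
    if np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    if calibration is None:
        calibration = ArtaCalibration(p.size, k_grid=k_grid, n_mc=n_mc, rng=seed)
    return calibration.pvalue(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values across sets."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("no sets")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SetResult:
    """Per-set aggregation across signal models and retention strategies."""

    set_id: str
    p_minp_A: float | None = None
    p_arta_A: float | None = None
    p_stage1_A: float | None = None
    p_minp_PA: float | None = None
    p_arta_PA: float | None = None
    p_stage1_PA: float | None = None
    p_omnibus: float = np.nan
    q_fdr: float = np.nan
    n_kpcs_A: int = 0
    n_kpcs_PA: int = 0


def two_stage_omnibus(
    pvalues_by_strategy: dict[str, dict[str, np.ndarray]],
    k_grid=None,
    n_mc: int = 5000,
    seed=None,
) -> list[SetResult]:
    """Two-stage omnibus across signal models and KPC strategies.

    ``pvalues_by_strategy`` maps strategy label ("A", "PA", or a single
    other label such as "PCA") to {set_id: vector of per-KPC p-values}.
    Stage 1 per strategy: Cauchy(MinP, ART-A); Stage 2: Cauchy across the
    strategies' stage-1 values (a single strategy passes through).
    """
    strategies = list(pvalues_by_strategy)
    if not strategies:
        raise ValueError("no strategies supplied")
    set_ids = list(pvalues_by_strategy[strategies[0]])
    for s in strategies[1:]:
        if set(pvalues_by_strategy[s]) != set(set_ids):
            raise ValueError("strategies disagree on the set list")
    rng = np.random.default_rng(seed)
    calib: dict[int, ArtaCalibration] = {}
    results = []
    for set_id in set_ids:
        res = SetResult(set_id=str(set_id))
        stage1 = {}
        for s in strategies:
            p = np.asarray(pvalues_by_strategy[s][set_id], dtype=float).ravel()
            if p.size == 0:
                raise ValueError(f"set {set_id!r} has no p-values under strategy {s!r}")
            L = p.size
            if L not in calib:
                calib[L] = ArtaCalibration(L, k_grid=k_grid, n_mc=n_mc, rng=rng)
            p_minp = minp_combine(p)
            p_arta = arta_combine(p, calibration=calib[L])
            p_s1 = cauchy_combine([p_minp, p_arta])
            stage1[s] = p_s1
            if s == "A":
                res.p_minp_A, res.p_arta_A, res.p_stage1_A = p_minp, p_arta, p_s1
                res.n_kpcs_A = L
            elif s == "PA":
                res.p_minp_PA, res.p_arta_PA, res.p_stage1_PA = p_minp, p_arta, p_s1
                res.n_kpcs_PA = L
            else:  # single-strategy pipelines (e.g. Linear-HSIM)
                res.p_minp_A, res.p_arta_A, res.p_stage1_A = p_minp, p_arta, p_s1
                res.n_kpcs_A = L
        res.p_omnibus = (
            stage1[strategies[0]]
            if len(strategies) == 1
            else cauchy_combine([stage1[s] for s in strategies])
        )
        results.append(res)
    qs = bh_fdr([r.p_omnibus for r in results])
    for r, q in zip(results, qs):
        r.q_fdr = float(q)
    return results


def set_results_frame(results: list[SetResult]) -> pd.DataFrame:
    cols = [
        "set_id",
        "p_minp_A", "p_arta_A", "p_stage1_A",
        "p_minp_PA", "p_arta_PA", "p_stage1_PA",
        "p_omnibus", "q_fdr", "n_kpcs_A", "n_kpcs_PA",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results])
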