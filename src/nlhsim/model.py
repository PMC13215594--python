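"""Model-level interface: NL-HSIM and its linear comparator.

`NLHSIM` is built from data (phenotype, predictor matrix, set map, optional
covariates) the way statsmodels models are; ``fit()`` runs the full
pipeline — optional DC-SIS screening, per-set Gaussian-kernel KPCA with the
A and PA retention strategies, joint de-sparsified LASSO inference, and the
two-stage omnibus — and returns an :class:`NLHSIMResults` with per-set
p-values, FDR q-values and a ``summary()`` table.

`LinearHSIM` swaps the KPCA module for per-set linear PCA retaining >85%
cumulative variance, keeping everything else identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    InferenceConfig,
    KernelConfig,
    KpcaConfig,
    OmnibusConfig,
    ScreeningConfig,
)
from .genesets import GeneSetMap
from .inference import (
    InferenceResult,
    build_design,
    desparsified_lasso,
    linear_hsim_design,
)
from .kernel import bandwidth, center_kernel, fit_kernel
from .kpca import KpcSet, kpca_decompose, select_A, select_PA
from .omnibus import SetResult, set_results_frame, two_stage_omnibus
from .screening import ScreeningResult, dcsis_screen, default_retention

__all__ = ["NLHSIM", "LinearHSIM", "NLHSIMResults"]


def _standardize_set(X_set: np.ndarray) -> np.ndarray | None:
    """Standardized copy of a set's predictor block; constant columns are
    dropped; returns None if nothing varies."""
    X_set = np.asarray(X_set, dtype=float)
    mean = X_set.mean(axis=0)
    sd = X_set.std(axis=0)
    ok = sd > 1e-12 * (np.abs(mean) + 1.0)
    if not ok.any():
        return None
    return (X_set[:, ok] - mean[ok]) / sd[ok]


@dataclass
class NLHSIMResults:
    """Fitted pipeline output.

    ``set_results`` holds the per-set MinP / ART-A / stage-1 p-values for
    each retention strategy, the omnibus p and the BH-FDR q.  The raw
    per-KPC inference results are kept per strategy in ``inference``.
    """

    model: object
    set_results: list[SetResult]
    inference: dict[str, InferenceResult]
    kpc_sets: dict[str, list[KpcSet]]
    screening: ScreeningResult | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def frame(self) -> pd.DataFrame:
        return set_results_frame(self.set_results)

    def pvalues(self) -> pd.Series:
        f = self.frame
        return pd.Series(f["p_omnibus"].to_numpy(), index=f["set_id"], name="p_omnibus")

    def qvalues(self) -> pd.Series:
        f = self.frame
        return pd.Series(f["q_fdr"].to_numpy(), index=f["set_id"], name="q_fdr")

    def significant_sets(self, q: float = 0.05) -> list[str]:
        f = self.frame
        return list(f.loc[f["q_fdr"] <= q, "set_id"])

    def summary(self) -> str:
        f = self.frame.copy()
        name = type(self.model).__name__
        lines = [
            f"{name} set-based association results",
            f"  sets tested: {len(f)}   strategies: {', '.join(self.inference)}",
            "",
        ]
        cols = ["set_id", "p_stage1_A", "p_stage1_PA", "p_omnibus", "q_fdr"]
        cols = [c for c in cols if c in f.columns]
        with pd.option_context("display.float_format", lambda v: f"{v:.4g}"):
            lines.append(f[cols].to_string(index=False))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


class NLHSIM:
    """Nonlinear high-dimensional set-based association model.

    Parameters
    ----------
    y : array-like, shape (n,)
        Continuous phenotype.
    X : array-like, shape (n, p)
        Predictors (0/1/2 genotypes or continuous features).
    sets : GeneSetMap
        Assignment of predictor columns to named sets (genes).
    covariates : array-like, optional
        Linear adjusters; never kernelized.
    """

    def __init__(
        self,
        y,
        X,
        sets: GeneSetMap,
        covariates=None,
        covariate_ids=None,
        *,
        screening: ScreeningConfig | None = None,
        kernel: KernelConfig | None = None,
        kpca: KpcaConfig | None = None,
        inference: InferenceConfig | None = None,
        omnibus: OmnibusConfig | None = None,
        seed: int = 0,
    ):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.asarray(X, dtype=float)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y disagree on sample count")
        self.sets = sets
        self.covariates = None if covariates is None else np.atleast_2d(
            np.asarray(covariates, dtype=float)
        ).reshape(self.y.size, -1)
        self.covariate_ids = covariate_ids
        self.screening_config = screening or ScreeningConfig(enabled=False)
        self.kernel_config = kernel or KernelConfig()
        self.kpca_config = kpca or KpcaConfig()
        self.inference_config = inference or InferenceConfig()
        self.omnibus_config = omnibus or OmnibusConfig()
        self.seed = seed

    @classmethod
    def from_dataframes(
        cls, phenotype: pd.Series, genotypes: pd.DataFrame, set_map: pd.DataFrame,
        covariates: pd.DataFrame | None = None, **kwargs
    ) -> "NLHSIM":
        """Build from aligned pandas objects; ``set_map`` is a two-column
        (snp_id, set_id) table over the genotype columns."""
        sets = GeneSetMap.from_table(set_map, list(genotypes.columns))
        cov = None if covariates is None else covariates.to_numpy(dtype=float)
        cov_ids = None if covariates is None else list(covariates.columns)
        return cls(phenotype.to_numpy(dtype=float), genotypes.to_numpy(dtype=float),
                   sets, cov, cov_ids, **kwargs)

    # -- pipeline stages -----------------------------------------------------

    def _screen(self):
        cfg = self.screening_config
        if not cfg.enabled:
            return None, self.X, self.sets, self.covariates, self.covariate_ids
        n, p = self.X.shape
        d = default_retention(n) if cfg.top == "n_over_log_n" else int(cfg.top)
        cov_ids = self.covariate_ids
        if self.covariates is not None and cov_ids is None:
            cov_ids = [f"cov{j + 1}" for j in range(self.covariates.shape[1])]
        res = dcsis_screen(
            self.X, self.y, self.covariates, d=d,
            predictor_ids=self.sets.snp_ids, covariate_ids=cov_ids,
        )
        kept_cols = np.sort(res.kept_predictor_indices)
        sets = self.sets.restrict(kept_cols)
        X = self.X[:, kept_cols]
        if self.covariates is not None and res.kept_covariate_indices.size:
            ci = np.sort(res.kept_covariate_indices)
            cov = self.covariates[:, ci]
            cov_ids = [cov_ids[int(j)] for j in ci]
        else:
            cov, cov_ids = None, None
        return res, X, sets, cov, cov_ids

    def _extract_kpcs(self, X, sets, strategies) -> dict[str, list[KpcSet]]:
        kcfg, pcfg = self.kernel_config, self.kpca_config
        out: dict[str, list[KpcSet]] = {s: [] for s in strategies}
        entropy = (int(self.seed), int(kcfg.seed), int(pcfg.seed))
        children = np.random.SeedSequence(entropy).spawn(sets.n_sets)
        for (set_id, idx), ss in zip(sets, children):
            Xs = _standardize_set(X[:, idx])
            if Xs is None:
                warnings.warn(f"set {set_id!r} is constant; skipped")
                continue
            kseed, pseed = ss.spawn(2)
            try:
                sigma = bandwidth(Xs)
            except ValueError:
                warnings.warn(f"set {set_id!r} has identical rows; skipped")
                continue
            kern_opts = dict(
                exact_threshold=kcfg.exact_threshold, landmarks=kcfg.landmarks, seed=kseed
            )
            dec = kpca_decompose(center_kernel(fit_kernel(Xs, sigma, **kern_opts)))
            if "A" in strategies:
                ra = select_A(dec.eigenvalues)
                out["A"].append(KpcSet(set_id, dec.scores[:, ra], dec.eigenvalues, "A", ra))
            if "PA" in strategies:
                rpa, h_pre, _ = select_PA(
                    Xs, dec.eigenvalues, sigma,
                    h_max=min(pcfg.h_max, dec.rank),
                    n_folds=pcfg.folds, seed=pseed,
                    preimage_tol=pcfg.preimage_tol,
                    preimage_max_iter=pcfg.preimage_max_iter,
                    kernel_opts=kern_opts,
                )
                out["PA"].append(
                    KpcSet(set_id, dec.scores[:, rpa], dec.eigenvalues, "PA", rpa, h_pre=h_pre)
                )
        for s, lst in out.items():
            if not lst:
                raise ValueError(f"no usable set under strategy {s!r}")
        return out

    def fit(self) -> NLHSIMResults:
        scfg = self.kpca_config.strategy
        strategies = ("A", "PA") if scfg == "both" else (scfg,)
        screening, X, sets, cov, cov_ids = self._screen()
        kpc_sets = self._extract_kpcs(X, sets, strategies)
        icfg = self.inference_config
        inference: dict[str, InferenceResult] = {}
        pvals: dict[str, dict[str, np.ndarray]] = {}
        for s in strategies:
            design = build_design(kpc_sets[s], cov, cov_ids, strategy=s)
            inference[s] = desparsified_lasso(
                design, self.y, cv_folds=icfg.cv_folds, n_alphas=icfg.n_alphas,
                eps=icfg.eps, nodewise=icfg.nodewise,
                penalize_covariates=icfg.penalize_covariates,
                seed=icfg.seed if icfg.seed else self.seed,
            )
            pvals[s] = inference[s].pvalues_by_set()
        ocfg = self.omnibus_config
        results = two_stage_omnibus(
            pvals, k_grid=ocfg.k_grid, n_mc=ocfg.n_mc,
            seed=ocfg.seed if ocfg.seed else self.seed,
        )
        return NLHSIMResults(
            model=self, set_results=results, inference=inference,
            kpc_sets=kpc_sets, screening=screening,
        )


class LinearHSIM(NLHSIM):
    """Linear comparator: per-set PCA (components explaining >85% cumulative
    variance) in place of KPCA; identical screening, inference and
    set-level aggregation."""

    def __init__(self, *args, pca_threshold: float = 0.85, **kwargs):
        super().__init__(*args, **kwargs)
        self.pca_threshold = pca_threshold

    def fit(self) -> NLHSIMResults:
        screening, X, sets, cov, cov_ids = self._screen()
        blocks = {}
        for set_id, idx in sets:
            Xs = _standardize_set(X[:, idx])
            if Xs is None:
                warnings.warn(f"set {set_id!r} is constant; skipped")
                continue
            blocks[set_id] = Xs
        if not blocks:
            raise ValueError("no usable set")
        design = linear_hsim_design(blocks, cov, cov_ids, threshold=self.pca_threshold)
        icfg = self.inference_config
        inf = desparsified_lasso(
            design, self.y, cv_folds=icfg.cv_folds, n_alphas=icfg.n_alphas,
            eps=icfg.eps, nodewise=icfg.nodewise,
            penalize_covariates=icfg.penalize_covariates,
            seed=icfg.seed if icfg.seed else self.seed,
        )
        ocfg = self.omnibus_config
        results = two_stage_omnibus(
            {"PCA": inf.pvalues_by_set()}, k_grid=ocfg.k_grid, n_mc=ocfg.n_mc,
            seed=ocfg.seed if ocfg.seed else self.seed,
        )
        return NLHSIMResults(
            model=self, set_results=results, inference={"PCA": inf},
            kpc_sets={}, screening=screening,
        )
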