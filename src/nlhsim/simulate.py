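"""Synthetic genotype / continuous-predictor generator with controlled
within-set dependence and four signal architectures.

Predictors are generated from a latent Gaussian copula: within each set the
latent normals are block-exchangeable with correlation ``rho`` (zero between
sets).  Genotype columns threshold the latent normal at the Hardy-Weinberg
quantiles of a per-column minor-allele frequency drawn uniformly from
``maf_range``, so marginals are Binomial(2, MAF); continuous columns return
the latent normals directly.

Phenotypes follow y = signal(X) + eps, eps ~ N(0, noise_sd^2), under one of

* ``null``            — y = eps, independent of all predictors;
* ``linear_cwsm``     — every predictor in each causal set gets a
                        Uniform(c1, c2) coefficient on its standardized
                        column (cumulative weak signals);
* ``linear_dssm``     — exactly two predictors per causal set get the fixed
                        coefficients c1 and c2 (dominating strong signals);
* ``nonlinear_*``     — identical coefficient schemes, but each causal
                        predictor acts through the threshold code
                        I(x >= 1) (genotypes, dominant coding; configurable
                        recessive I(x = 2)) or I(x >= column median)
                        (continuous) in place of the raw value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .genesets import GeneSetMap

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_predictors",
    "simulate_phenotype",
    "simulate_dataset",
    "EFFECT_MODELS",
]

EFFECT_MODELS = ("null", "linear_cwsm", "linear_dssm", "nonlinear_cwsm", "nonlinear_dssm")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset."""

    n: int = 400
    set_sizes: tuple = (8,) * 20
    maf_range: tuple = (0.05, 0.5)
    rho: float = 0.3
    effect_model: str = "null"
    c1: float = 0.0
    c2: float = 0.0
    causal_sets: tuple = ()
    noise_sd: float = 1.0
    seed: int = 0
    predictor_kind: str = "genotype"
    threshold_coding: str = "dominant"  # or "recessive" (genotype kind only)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not self.set_sizes or any(int(s) <= 0 for s in self.set_sizes):
            raise ValueError("set_sizes must be positive integers")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.effect_model not in EFFECT_MODELS:
            raise ValueError(f"unknown effect_model {self.effect_model!r}")
        if not 0.0 <= self.c1 <= self.c2:
            raise ValueError("require 0 <= c1 <= c2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.predictor_kind not in ("genotype", "continuous"):
            raise ValueError("predictor_kind must be 'genotype' or 'continuous'")
        if self.threshold_coding not in ("dominant", "recessive"):
            raise ValueError("threshold_coding must be 'dominant' or 'recessive'")
        self.set_sizes = tuple(int(s) for s in self.set_sizes)
        self.causal_sets = tuple(self.causal_sets)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SimulatedDataset:
    """Predictors, optional phenotype, set map and per-set causal truth."""

    X: np.ndarray
    y: np.ndarray | None
    sets: GeneSetMap
    truth: dict[str, bool] = field(default_factory=dict)
    mafs: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _resolve_causal(sets: GeneSetMap, causal_sets) -> list[str]:
    ids = sets.set_ids
    out = []
    for c in causal_sets:
        if isinstance(c, (int, np.integer)):
            if not 0 <= int(c) < len(ids):
                raise ValueError(f"causal set index {c} out of range")
            out.append(ids[int(c)])
        else:
            if str(c) not in sets.columns:
                raise ValueError(f"unknown causal set {c!r}")
            out.append(str(c))
    return out


def simulate_predictors(config: SimulationConfig, rng=None) -> SimulatedDataset:
    """Draw the predictor matrix (no phenotype).

    Genotype kind: latent block-exchangeable normals thresholded at the
    Hardy-Weinberg quantiles for each column's MAF; continuous kind: the
    latent normals themselves.  Deterministic given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    sets = GeneSetMap.from_sizes(config.set_sizes)
    p = sum(config.set_sizes)
    Z = np.empty((n, p))
    sr, cr = np.sqrt(config.rho), np.sqrt(1.0 - config.rho)
    for _, idx in sets:
        shared = rng.standard_normal((n, 1))
        Z[:, idx] = sr * shared + cr * rng.standard_normal((n, idx.size))
    if config.predictor_kind == "continuous":
        return SimulatedDataset(X=Z, y=None, sets=sets, mafs=None)
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=p)
    q0 = stats.norm.ppf((1.0 - mafs) ** 2)  # P(X = 0) under HWE
    q1 = stats.norm.ppf((1.0 - mafs) ** 2 + 2.0 * mafs * (1.0 - mafs))
    X = (Z > q0[None, :]).astype(np.int64) + (Z > q1[None, :]).astype(np.int64)
    return SimulatedDataset(X=X, y=None, sets=sets, mafs=mafs)


def _effect_columns(X: np.ndarray, cols: np.ndarray, config: SimulationConfig,
                    nonlinear: bool) -> np.ndarray:
    """Per-predictor contribution basis for the causal columns."""
    B = X[:, cols].astype(float)
    if not nonlinear:
        mean, sd = B.mean(axis=0), B.std(axis=0)
        out = np.zeros_like(B)
        ok = sd > 0
        out[:, ok] = (B[:, ok] - mean[ok]) / sd[ok]
        return out
    if config.predictor_kind == "genotype":
        cut = 2.0 if config.threshold_coding == "recessive" else 1.0
        return (B >= cut).astype(float)
    med = np.median(B, axis=0)
    return (B >= med[None, :]).astype(float)


def simulate_phenotype(X, sets: GeneSetMap, config: SimulationConfig, rng=None) -> np.ndarray:
    """Phenotype under the configured effect architecture.

    CWSM draws a Uniform(c1, c2) coefficient for every predictor of each
    causal set; DSSM assigns the fixed coefficients c1 and c2 to two
    randomly chosen predictors per causal set (the others get zero).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31 - 1) + 1)
    X = np.asarray(X)
    n = X.shape[0]
    signal = np.zeros(n)
    if config.effect_model != "null":
        nonlinear = config.effect_model.startswith("nonlinear")
        dssm = config.effect_model.endswith("dssm")
        for set_id in _resolve_causal(sets, config.causal_sets):
            cols = sets[set_id]
            basis = _effect_columns(X, cols, config, nonlinear)
            if dssm:
                if cols.size < 2:
                    raise ValueError(f"DSSM needs >= 2 predictors in causal set {set_id!r}")
                pick = rng.choice(cols.size, size=2, replace=False)
                coef = np.zeros(cols.size)
                coef[pick[0]], coef[pick[1]] = config.c1, config.c2
            else:
                coef = rng.uniform(config.c1, config.c2, size=cols.size)
            signal += basis @ coef
    return signal + config.noise_sd * rng.standard_normal(n)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Predictors + phenotype + causal truth, deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    ds = simulate_predictors(config, rng=rng)
    ds.y = simulate_phenotype(ds.X, ds.sets, config, rng=rng)
    causal = set(_resolve_causal(ds.sets, config.causal_sets)) if config.effect_model != "null" else set()
    ds.truth = {s: s in causal for s in ds.sets.set_ids}
    return ds
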