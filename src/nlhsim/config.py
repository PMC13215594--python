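"""Configuration dataclasses for the analysis pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields


@dataclass
class ScreeningConfig:
    enabled: bool = True
    top: int | str = "n_over_log_n"  # count, or the floor(n/log n) rule


@dataclass
class KernelConfig:
    exact_threshold: int = 2000  # exact kernel up to this n; Nystrom above
    landmarks: int | None = None  # default m = min(n, max(50, ceil(2 sqrt n)))
    seed: int = 0


@dataclass
class KpcaConfig:
    strategy: str = "both"  # "A", "PA" or "both"
    h_max: int = 20
    preimage_tol: float = 1e-5
    preimage_max_iter: int = 100
    folds: int = 10
    seed: int = 0


@dataclass
class InferenceConfig:
    cv_folds: int = 10
    n_alphas: int = 20
    eps: float = 1e-3  # penalty-grid floor as a fraction of lambda_max
    nodewise: str = "cv"  # per-node CV, or "universal" sqrt(2 log q / n)
    penalize_covariates: bool = True
    seed: int = 0


@dataclass
class OmnibusConfig:
    n_mc: int = 5000
    k_grid: tuple | None = None
    seed: int = 0


@dataclass
class AnalysisConfig:
    """End-to-end run configuration (file paths + stage sub-configs)."""

    genotypes: str = ""
    phenotype: str = ""
    covariates: str | None = None
    set_map: str = ""
    out_dir: str = "."
    genotype_format: str = "tsv"  # or "plink"
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    kpca: KpcaConfig = field(default_factory=KpcaConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    omnibus: OmnibusConfig = field(default_factory=OmnibusConfig)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        sub = {
            "screening": ScreeningConfig,
            "kernel": KernelConfig,
            "kpca": KpcaConfig,
            "inference": InferenceConfig,
            "omnibus": OmnibusConfig,
        }
        kwargs = {}
        valid = {f.name for f in fields(cls)}
        for k, v in d.items():
            if k not in valid:
                raise ValueError(f"unknown config key {k!r}")
            if k in sub and isinstance(v, dict):
                kwargs[k] = sub[k](**v)
            else:
                kwargs[k] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)
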