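"""File I/O: genotype/phenotype/covariate tables, PLINK bed/bim/fam,
SNP-to-gene maps, result writers and the end-to-end pipeline runner."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .model import NLHSIM
from .simulate import SimulatedDataset

logger = logging.getLogger("nlhsim")

__all__ = [
    "read_genotypes",
    "read_phenotype",
    "read_covariates",
    "read_set_map",
    "write_dataset",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# readers


def read_genotypes(path, format: str = "tsv") -> pd.DataFrame:
    """Subjects x SNPs additive-coded genotype matrix.

    TSV: first column subject id, remaining columns SNP dosages in
    {0, 1, 2} (blank = missing).  PLINK: ``path`` is the bed/bim/fam prefix
    (or the .bed file).  Either way the coding counts minor alleles by
    within-sample frequency (ties broken toward the bim A1 allele for
    PLINK), and residual missing genotypes are mean-imputed per SNP with a
    logged count.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        vals = df.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype coding outside {{0,1,2,missing}} at subject "
                f"{df.index[r]!r}, SNP {df.columns[c]!r}: {vals[r, c]!r}"
            )
        return _impute_and_orient(df, a1_first=None)
    if format == "plink":
        return _read_plink(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _impute_and_orient(df: pd.DataFrame, a1_first) -> pd.DataFrame:
    vals = df.to_numpy(dtype=float)
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        logger.info("mean-imputing %d missing genotype(s)", n_missing)
        col_mean = np.nanmean(vals, axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        idx = np.where(np.isnan(vals))
        vals[idx] = col_mean[idx[1]]
    # orient to minor-allele counts by within-sample frequency
    freq = vals.mean(axis=0) / 2.0
    flip = freq > 0.5
    if a1_first is not None:  # PLINK: ties at 0.5 stay on the A1 allele
        flip = np.where(np.isclose(freq, 0.5), ~a1_first, flip)
    vals[:, flip] = 2.0 - vals[:, flip]
    return pd.DataFrame(vals, index=df.index, columns=df.columns)


def _read_plink(prefix) -> pd.DataFrame:
    """Minimal SNP-major PLINK .bed/.bim/.fam decoder."""
    prefix = str(prefix)
    if prefix.endswith(".bed"):
        prefix = prefix[:-4]
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype={"snp": str},
    )
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"iid": str},
    )
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw.size < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise ValueError(f"{prefix}.bed is not a PLINK bed file")
    if raw[2] != 0x01:
        raise ValueError("only SNP-major bed files are supported")
    n, p = len(fam), len(bim)
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * p:
        raise ValueError("bed payload size inconsistent with bim/fam")
    codes = body.reshape(p, bytes_per_snp)
    # unpack 2-bit genotypes, little-endian within each byte
    shifts = np.arange(4) * 2
    g2 = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    g2 = g2.reshape(p, -1)[:, :n]
    # PLINK codes: 00 hom A1 (2 A1 alleles), 10 het, 11 hom A2, 01 missing
    decode = np.array([2.0, np.nan, 1.0, 0.0])
    vals = decode[g2].T  # subjects x SNPs, counting A1 alleles
    df = pd.DataFrame(vals, index=fam["iid"].astype(str), columns=bim["snp"])
    return _impute_and_orient(df, a1_first=np.full(p, True))


def read_phenotype(path) -> pd.Series:
    """Two-column TSV (subject id, value) -> Series indexed by id."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("phenotype file needs (subject, value) columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))
    return s


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def read_set_map(path, snp_positions: pd.DataFrame | None = None,
                 snp_ids: list[str] | None = None) -> pd.DataFrame:
    """SNP-to-set assignments as a two-column (snp_id, set_id) table.

    Accepts either a two-column TSV directly, or a BED-like table
    (chrom, start, end, set_id; 0-based half-open intervals) together with
    ``snp_positions`` (snp_id, chrom, pos; 1-based positions as in bim
    files).  SNPs inside several intervals are duplicated into each set.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] == 2:
        if df.isna().any().any():
            bad = int(df.isna().any(axis=1).idxmax()) + 1
            raise ValueError(f"malformed set-map line {bad}")
        out = df.rename(columns={0: "snp_id", 1: "set_id"})
    elif df.shape[1] >= 4:
        if snp_positions is None:
            raise ValueError("BED-like set map requires snp_positions")
        try:
            start = df[1].astype(int)
            end = df[2].astype(int)
        except ValueError as exc:
            raise ValueError(f"malformed BED interval: {exc}") from exc
        rows = []
        for _, snp in snp_positions.iterrows():
            pos0 = int(snp["pos"]) - 1  # bim is 1-based; BED is 0-based half-open
            hit = (df[0] == str(snp["chrom"])) & (start <= pos0) & (pos0 < end)
            for gene in df.loc[hit, 3]:
                rows.append((str(snp["snp_id"]), str(gene)))
        out = pd.DataFrame(rows, columns=["snp_id", "set_id"])
    else:
        raise ValueError("set map must have 2 (snp, set) or >= 4 (BED) columns")
    if out.empty:
        raise ValueError("empty set map")
    if snp_ids is not None:
        known = out["snp_id"].isin(set(snp_ids))
        dropped = int((~known).sum())
        if dropped:
            logger.info("dropping %d set-map entries for unknown SNPs", dropped)
        out = out[known]
        if out.empty:
            raise ValueError("set map matches no genotyped SNP")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# writers


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Write a simulated dataset as plain TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = [f"s{i + 1}" for i in range(ds.n)]
    paths = {}
    g = pd.DataFrame(ds.X, index=subjects, columns=ds.sets.snp_ids)
    g.index.name = "subject"
    paths["genotypes"] = out / "genotypes.tsv"
    g.to_csv(paths["genotypes"], sep="\t", lineterminator="\n")
    if ds.y is not None:
        paths["phenotype"] = out / "phenotype.tsv"
        pd.DataFrame({"subject": subjects, "value": ds.y}).to_csv(
            paths["phenotype"], sep="\t", index=False, lineterminator="\n"
        )
    paths["set_map"] = out / "setmap.tsv"
    ds.sets.to_table().to_csv(paths["set_map"], sep="\t", index=False, header=False,
                              lineterminator="\n")
    if ds.truth:
        paths["truth"] = out / "truth.tsv"
        pd.DataFrame(
            {"set_id": list(ds.truth), "causal": [int(v) for v in ds.truth.values()]}
        ).to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    return paths


# ---------------------------------------------------------------------------
# end-to-end runner


def _align(genotypes: pd.DataFrame, phenotype: pd.Series,
           covariates: pd.DataFrame | None):
    common = genotypes.index.intersection(phenotype.index)
    if covariates is not None:
        common = common.intersection(covariates.index)
    if len(common) == 0:
        raise ValueError("no overlapping subject ids between genotype and phenotype files")
    g = genotypes.loc[common]
    y = phenotype.loc[common]
    c = covariates.loc[common] if covariates is not None else None
    return g, y, c


def run_pipeline(config: AnalysisConfig) -> pd.DataFrame:
    """screen -> map -> per-gene kernel/KPCA -> de-sparsified LASSO ->
    two-stage omnibus -> BH-FDR, with TSV outputs and a JSON run manifest."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    genotypes = read_genotypes(config.genotypes, format=config.genotype_format)
    phenotype = read_phenotype(config.phenotype)
    covariates = read_covariates(config.covariates) if config.covariates else None
    genotypes, phenotype, covariates = _align(genotypes, phenotype, covariates)
    logger.info("aligned %d subjects, %d SNPs", *genotypes.shape)

    set_map = read_set_map(config.set_map, snp_ids=list(genotypes.columns))
    model = NLHSIM.from_dataframes(
        phenotype, genotypes, set_map, covariates,
        screening=config.screening, kernel=config.kernel, kpca=config.kpca,
        inference=config.inference, omnibus=config.omnibus, seed=config.seed,
    )
    results = model.fit()

    frame = results.frame
    results.to_tsv(out_dir / "results.tsv")
    for s, inf in results.inference.items():
        inf.to_frame().to_csv(out_dir / f"inference_{s}.tsv", sep="\t", index=False,
                              lineterminator="\n")
    if results.screening is not None:
        results.screening.to_frame().to_csv(out_dir / "screening.tsv", sep="\t",
                                            index=False, lineterminator="\n")
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "n_subjects": int(genotypes.shape[0]),
        "n_snps": int(genotypes.shape[1]),
        "n_sets": int(frame.shape[0]),
        "versions": _versions(),
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("wrote %s", out_dir / "results.tsv")
    return frame


def _versions() -> dict:
    import numpy
    import pandas
    import scipy
    import sklearn

    from . import __version__

    return {
        "nlhsim": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "sklearn": sklearn.__version__,
    }
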