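"""File I/O (TSV + PLINK), set maps, model facade and the end-to-end runner."""

import numpy as np
import pandas as pd
import pytest

from nlhsim import (
    AnalysisConfig,
    KernelConfig,
    KpcaConfig,
    InferenceConfig,
    NLHSIM,
    OmnibusConfig,
    SimulationConfig,
    simulate_dataset,
)
from nlhsim.io import (
    read_genotypes,
    read_set_map,
    run_pipeline,
    write_dataset,
)


def _fast_configs():
    return dict(
        kernel=KernelConfig(exact_threshold=10_000),
        kpca=KpcaConfig(strategy="both", h_max=3, folds=10),
        inference=InferenceConfig(cv_folds=5, n_alphas=10, eps=0.05),
        omnibus=OmnibusConfig(n_mc=2000),
    )


@pytest.fixture(scope="module")
def small_dataset():
    cfg = SimulationConfig(n=120, set_sizes=(4, 3, 5, 4, 4), rho=0.2,
                           effect_model="null", seed=3)
    return simulate_dataset(cfg)


class TestGenotypeTsv:
    def test_roundtrip(self, tmp_path, small_dataset):
        paths = write_dataset(small_dataset, tmp_path)
        g = read_genotypes(paths["genotypes"])
        assert g.shape == (120, 20)
        assert np.array_equal(g.to_numpy(), small_dataset.X.astype(float))

    def test_missing_value_mean_imputed(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("subject\tsnp1\tsnp2\ns1\t0\t1\ns2\t2\t1\ns3\t\t0\n")
        g = read_genotypes(path)
        # observed values (0, 2) -> imputed 1.0
        assert g.loc["s3", "snp1"] == pytest.approx(1.0)

    def test_major_allele_coding_flipped(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("subject\tsnp1\ns1\t2\ns2\t2\ns3\t1\n")
        g = read_genotypes(path)
        # frequency 5/6 > 0.5: recoded to count the minor allele
        assert g["snp1"].tolist() == [0.0, 0.0, 1.0]

    def test_invalid_coding_rejected(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("subject\tsnp1\ns1\t3\ns2\t0\n")
        with pytest.raises(ValueError, match="coding"):
            read_genotypes(path)


class TestPlink:
    @staticmethod
    def _write_triple(tmp_path, genos, a1_minor=True):
        """genos: subjects x snps with values in {0,1,2,None} counting A1."""
        n, p = len(genos), len(genos[0])
        fam = "\n".join(f"f{i} s{i} 0 0 1 -9" for i in range(n))
        bim = "\n".join(f"1 snp{j} 0 {100 + j} A G" for j in range(p))
        (tmp_path / "toy.fam").write_text(fam + "\n")
        (tmp_path / "toy.bim").write_text(bim + "\n")
        code = {2: 0b00, None: 0b01, 1: 0b10, 0: 0b11}
        body = bytearray([0x6C, 0x1B, 0x01])
        for j in range(p):
            for start in range(0, n, 4):
                byte = 0
                for k, i in enumerate(range(start, min(start + 4, n))):
                    byte |= code[genos[i][j]] << (2 * k)
                body.append(byte)
        (tmp_path / "toy.bed").write_bytes(bytes(body))
        return tmp_path / "toy"

    def test_decode_matches_expected(self, tmp_path):
        genos = [[0, 1], [1, 2], [2, 0], [1, 1], [0, 2]]
        prefix = self._write_triple(tmp_path, genos)
        g = read_genotypes(prefix, format="plink")
        assert g.shape == (5, 2)
        # snp0: A1 frequency 0.4 -> A1 is minor, counts unchanged;
        # snp1: A1 frequency 0.6 -> flipped to count the minor allele
        assert g["snp0"].tolist() == [0.0, 1.0, 2.0, 1.0, 0.0]
        assert g["snp1"].tolist() == [1.0, 0.0, 2.0, 1.0, 0.0]

    def test_tie_frequency_stays_on_a1(self, tmp_path):
        genos = [[1], [2], [0], [1]]  # A1 frequency exactly 0.5
        prefix = self._write_triple(tmp_path, genos)
        g = read_genotypes(prefix, format="plink")
        assert g["snp0"].tolist() == [1.0, 2.0, 0.0, 1.0]

    def test_missing_genotype_imputed(self, tmp_path):
        genos = [[0], [2], [None], [0]]
        prefix = self._write_triple(tmp_path, genos)
        g = read_genotypes(prefix, format="plink")
        assert g.iloc[2, 0] == pytest.approx(2.0 / 3.0)

    def test_bad_magic_rejected(self, tmp_path):
        prefix = self._write_triple(tmp_path, [[0], [1]])
        (tmp_path / "toy.bed").write_bytes(b"\x00\x00\x01\xff")
        with pytest.raises(ValueError, match="bed"):
            read_genotypes(prefix, format="plink")


class TestSetMap:
    def test_two_column_with_shared_snp(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("snp1\tgeneA\nsnp1\tgeneB\nsnp2\tgeneA\n")
        table = read_set_map(path)
        from nlhsim.genesets import GeneSetMap

        gsm = GeneSetMap.from_table(table, ["snp1", "snp2"])
        assert 0 in gsm["geneA"] and 0 in gsm["geneB"]

    def test_empty_map_rejected(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("")
        with pytest.raises((ValueError, pd.errors.EmptyDataError)):
            read_set_map(path)

    def test_bed_half_open_convention(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t100\t200\tgeneA\n")
        pos = pd.DataFrame(
            {"snp_id": ["snpL", "snpR"], "chrom": ["1", "1"], "pos": [101, 201]}
        )  # bim 1-based: positions 101 and 201 are 0-based 100 and 200
        table = read_set_map(bed, snp_positions=pos)
        assert table["snp_id"].tolist() == ["snpL"]  # 100 in, 200 out


class TestModelFacade:
    def test_fit_produces_valid_set_results(self, small_dataset):
        fit = NLHSIM(small_dataset.y, small_dataset.X, small_dataset.sets,
                     seed=0, **_fast_configs()).fit()
        frame = fit.frame
        assert len(frame) == 5
        for col in ("p_omnibus", "q_fdr", "p_stage1_A", "p_stage1_PA"):
            assert ((frame[col] > 0) & (frame[col] <= 1)).all()
        assert "set-based association results" in fit.summary()

    def test_from_dataframes_equivalent(self, small_dataset):
        ds = small_dataset
        genos = pd.DataFrame(ds.X, columns=ds.sets.snp_ids)
        pheno = pd.Series(ds.y)
        fit1 = NLHSIM(ds.y, ds.X, ds.sets, seed=1, **_fast_configs()).fit()
        fit2 = NLHSIM.from_dataframes(
            pheno, genos, ds.sets.to_table(), seed=1, **_fast_configs()
        ).fit()
        assert np.allclose(
            fit1.frame["p_omnibus"].to_numpy(), fit2.frame["p_omnibus"].to_numpy()
        )

    def test_screening_stage_reduces_columns(self):
        cfg = SimulationConfig(n=150, set_sizes=(4,) * 10, rho=0.2,
                               effect_model="null", seed=9)
        ds = simulate_dataset(cfg)
        from nlhsim import ScreeningConfig

        model = NLHSIM(ds.y, ds.X, ds.sets, seed=0,
                       screening=ScreeningConfig(enabled=True, top=12),
                       **_fast_configs())
        fit = model.fit()
        assert fit.screening is not None
        assert len(fit.screening.kept_predictors) == 12
        assert len(fit.frame) <= 10


class TestRunPipeline:
    def _config(self, tmp_path, small_dataset, out="out"):
        paths = write_dataset(small_dataset, tmp_path)
        cfg = AnalysisConfig(
            genotypes=str(paths["genotypes"]),
            phenotype=str(paths["phenotype"]),
            set_map=str(paths["set_map"]),
            out_dir=str(tmp_path / out),
            seed=7,
        )
        cfg.screening.enabled = False
        cfg.kpca = KpcaConfig(strategy="both", h_max=3, folds=10)
        cfg.inference = InferenceConfig(cv_folds=5, n_alphas=10, eps=0.05)
        cfg.omnibus = OmnibusConfig(n_mc=2000)
        return cfg

    def test_end_to_end_and_deterministic_rerun(self, tmp_path, small_dataset):
        cfg = self._config(tmp_path, small_dataset)
        frame = run_pipeline(cfg)
        assert len(frame) == 5
        assert ((frame["q_fdr"] > 0) & (frame["q_fdr"] <= 1)).all()
        results1 = (tmp_path / "out" / "results.tsv").read_bytes()
        assert (tmp_path / "out" / "manifest.json").exists()
        cfg2 = self._config(tmp_path, small_dataset, out="out2")
        run_pipeline(cfg2)
        assert (tmp_path / "out2" / "results.tsv").read_bytes() == results1

    def test_disjoint_subjects_rejected(self, tmp_path, small_dataset):
        cfg = self._config(tmp_path, small_dataset)
        pheno = pd.read_csv(cfg.phenotype, sep="\t")
        pheno["subject"] = ["zz" + str(i) for i in range(len(pheno))]
        pheno.to_csv(cfg.phenotype, sep="\t", index=False)
        with pytest.raises(ValueError, match="overlapping"):
            run_pipeline(cfg)


class TestCli:
    def test_simulate_screen_roundtrip(self, tmp_path):
        import yaml
        from click.testing import CliRunner

        from nlhsim.cli import main

        sim_cfg = dict(n=80, set_sizes=[3, 3], effect_model="null", seed=1)
        cfg_path = tmp_path / "sim.yaml"
        cfg_path.write_text(yaml.safe_dump(sim_cfg))
        runner = CliRunner()
        out_dir = tmp_path / "data"
        r1 = runner.invoke(main, ["simulate", "--config", str(cfg_path),
                                  "--out", str(out_dir)])
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(main, [
            "screen", "--geno", str(out_dir / "genotypes.tsv"),
            "--pheno", str(out_dir / "phenotype.tsv"),
            "--top", "4", "--out", str(tmp_path / "screened.tsv"),
        ])
        assert r2.exit_code == 0, r2.output
        screened = pd.read_csv(tmp_path / "screened.tsv", sep="\t")
        assert screened["kept"].sum() == 4
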