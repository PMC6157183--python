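"""Genotype/phenotype I/O and the three-rule SNP QC."""

import numpy as np
import pandas as pd
import pytest
from numpy.testing import assert_allclose

from famgwas import simulate as sim
from famgwas.dataio import (
    GenotypeMatrix,
    qc_filter,
    read_covariates,
    read_genotypes,
    read_phenotypes,
    write_covariates,
    write_phenotypes,
    write_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
)


def _vcf(tmp_path, body):
    p = tmp_path / "g.vcf"
    p.write_text(VCF_HEADER + body)
    return p


class TestVcfReader:
    def test_alt_minor_dosages(self, tmp_path):
        g = read_genotypes(_vcf(tmp_path, "1\t100\trs1\tA\tC\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"))
        assert_allclose(g.dosages[:, 0], [0, 1, 2])

    def test_ref_minor_complemented(self, tmp_path):
        # ALT frequency 5/6 > 0.5, so REF is the minor allele
        g = read_genotypes(_vcf(tmp_path, "1\t100\trs1\tA\tC\t.\t.\t.\tGT\t1/1\t1/1\t0/1\n"))
        assert_allclose(g.dosages[:, 0], [0, 0, 1])

    def test_missing_call_preserved(self, tmp_path):
        g = read_genotypes(_vcf(tmp_path, "1\t100\trs1\tA\tC\t.\t.\t.\tGT\t./.\t0/1\t0/0\n"))
        assert np.isnan(g.dosages[0, 0])

    def test_multiallelic_strict_raises(self, tmp_path):
        p = _vcf(tmp_path, "1\t100\trs1\tA\tC,G\t.\t.\t.\tGT\t0/1\t0/2\t0/0\n")
        with pytest.raises(ValueError, match="biallelic"):
            read_genotypes(p)
        g = read_genotypes(p, strict_biallelic=False)
        assert g.m == 0

    def test_columns_sorted_by_position(self, tmp_path):
        body = (
            "1\t500\trs2\tA\tC\t.\t.\t.\tGT\t0/0\t0/1\t0/0\n"
            "1\t100\trs1\tA\tC\t.\t.\t.\tGT\t0/1\t0/0\t0/0\n"
        )
        g = read_genotypes(_vcf(tmp_path, body))
        assert g.snp_ids == ["rs1", "rs2"]

    def test_sample_mismatch(self, tmp_path):
        p = _vcf(tmp_path, "1\t100\trs1\tA\tC\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n")
        with pytest.raises(ValueError, match="mismatch"):
            read_genotypes(p, iids=["A", "B", "Z"])

    def test_write_read_roundtrip(self, tmp_path):
        cfg = sim.SimConfig(n_families=10, m_snps=8, seed=2)
        ped = sim.sim_pedigree(cfg)
        G = sim.sim_genotypes(ped, cfg)
        path = tmp_path / "rt.vcf"
        write_vcf(G, path)
        G2 = read_genotypes(path, iids=G.iids)
        # reader returns minor-allele dosages; compare on that scale
        expected = np.where(
            G.dosages.mean(axis=0) / 2 > 0.5, 2 - G.dosages, G.dosages
        )
        assert_allclose(G2.dosages, expected)


class TestPedMapReader:
    def test_basic(self, tmp_path):
        (tmp_path / "d.map").write_text("1\trs1\t0\t100\n1\trs2\t0\t200\n")
        (tmp_path / "d.ped").write_text(
            "F A 0 0 1 0 A A A C\n"
            "F B 0 0 2 0 A C C C\n"
            "F C 0 0 1 0 A A 0 0\n"
        )
        g = read_genotypes(tmp_path / "d.ped", format="plink_text")
        assert g.snp_ids == ["rs1", "rs2"]
        assert_allclose(g.dosages[:, 0], [0, 1, 0])  # C is minor at rs1
        assert_allclose(g.dosages[:2, 1], [1, 0])  # A is minor at rs2
        assert np.isnan(g.dosages[2, 1])


def _panel(cols: dict[str, list[float]]) -> GenotypeMatrix:
    names = list(cols)
    arr = np.column_stack([np.asarray(cols[c], dtype=float) for c in names])
    snps = pd.DataFrame(
        {"snp_id": names, "chrom": "1", "bp": np.arange(1, len(names) + 1) * 100}
    )
    return GenotypeMatrix(arr, [f"i{k}" for k in range(arr.shape[0])], snps)


class TestQcFilter:
    def test_rules(self):
        n = 100
        g = _panel(
            {
                "balanced": [0] * 50 + [1] * 50,           # kept: 2 classes >= 5%
                "rare_pair": [0] * 96 + [1] * 4,           # dropped: rare class < 5%
                "mono": [0] * n,                           # dropped: monomorphic
                "with_missing": [np.nan] + [1] * 49 + [0] * 50,  # dropped: missing
                "three_class_rare_hom": [0] * 80 + [1] * 17 + [2] * 3,  # kept
            }
        )
        out, rep = qc_filter(g)
        assert out.snp_ids == ["balanced", "three_class_rare_hom"]
        assert rep.removed == {
            "rare_pair": "rare_genotype",
            "mono": "monomorphic",
            "with_missing": "missing",
        }
        assert (rep.n_missing_removed, rep.n_monomorphic_removed,
                rep.n_rare_genotype_removed) == (1, 1, 1)

    def test_boundary_exactly_five_percent_kept(self):
        g = _panel({"edge": [0] * 95 + [1] * 5})
        out, _ = qc_filter(g)
        assert out.snp_ids == ["edge"]

    def test_optional_maf_filter(self):
        g = _panel({"three_class": [0] * 80 + [1] * 17 + [2] * 3})
        with pytest.raises(ValueError, match="review"):
            qc_filter(g, maf_min=0.15)  # maf = 0.115 < 0.15, sole SNP dropped
        kept, rep = qc_filter(g, maf_min=0.10)  # maf = 0.115 >= 0.10
        assert kept.snp_ids == ["three_class"] and rep.removed == {}

    def test_idempotent(self, nuclear_world):
        _, _, G, _ = nuclear_world
        once, _ = qc_filter(G)
        twice, rep2 = qc_filter(once)
        assert twice.snp_ids == once.snp_ids
        assert_allclose(twice.dosages, once.dosages)
        assert rep2.removed == {}

    def test_all_removed_raises(self):
        g = _panel({"mono": [0.0, 0.0, 0.0]})
        with pytest.raises(ValueError, match="review"):
            qc_filter(g)


class TestTables:
    def test_phenotype_roundtrip_exact(self, tmp_path, nuclear_world):
        cfg, ped, G, _ = nuclear_world
        pheno = sim.sim_longitudinal(ped, G, None, seed=3, missing_rate=0.05)
        path = tmp_path / "ph.tsv"
        write_phenotypes(pheno, path)
        back = read_phenotypes(path, iids=ped.ids)
        assert_allclose(back.values, pheno.values, rtol=0, atol=0)

    def test_blank_cell_missing(self, tmp_path):
        cols = "\t".join(
            f"{t}_v{v}" for t in ("tg", "hdl") for v in (1, 2, 3, 4)
        )
        path = tmp_path / "p.tsv"
        path.write_text(f"iid\t{cols}\nA\t120\t\t110\t100\t50\t51\t52\t53\n")
        df = read_phenotypes(path)
        assert np.isnan(df.loc["A", "tg_v2"])

    def test_nonpositive_raw_raises(self, tmp_path):
        cols = "\t".join(
            f"{t}_v{v}" for t in ("tg", "hdl") for v in (1, 2, 3, 4)
        )
        path = tmp_path / "p.tsv"
        path.write_text(f"iid\t{cols}\nA\t0\t120\t110\t100\t50\t51\t52\t53\n")
        with pytest.raises(ValueError, match="nonpositive"):
            read_phenotypes(path)

    def test_covariates_validation(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("iid\tage\tsmoking\nA\t40\t0\nB\t55\t1\n")
        df = read_covariates(path)
        assert list(df.columns) == ["age", "smoking"]
        path.write_text("iid\tage\tsmoking\nA\t40\t2\n")
        with pytest.raises(ValueError, match="binary"):
            read_covariates(path)

    def test_covariates_roundtrip(self, tmp_path, rng):
        df = pd.DataFrame(
            {"age": rng.integers(20, 70, 5).astype(float),
             "smoking": rng.integers(0, 2, 5).astype(float)},
            index=pd.Index([f"i{k}" for k in range(5)], name="iid"),
        )
        path = tmp_path / "c.tsv"
        write_covariates(df, path)
        assert_allclose(read_covariates(path).values, df.values)
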