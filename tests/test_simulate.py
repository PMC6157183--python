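"""The synthetic-data generator: determinism, Mendelian and moment checks."""

import numpy as np
import pandas as pd
import pytest
from numpy.testing import assert_allclose

from famgwas import simulate as sim
from famgwas.covstruct import build_structured_cov
from famgwas.pedkin import KinshipMatrix, compute_kinship


class TestPedigree:
    def test_nuclear_counts_and_blocks(self):
        cfg = sim.SimConfig(n_families=10, k_children=2, seed=1)
        ped = sim.sim_pedigree(cfg)
        assert len(ped) == 40
        K = compute_kinship(ped).values
        fams = [r.family for r in ped.records]
        cross = np.array(fams)[:, None] != np.array(fams)[None, :]
        assert (K[cross] == 0).all()
        # 10 disjoint blocks = 10 connected components of the nonzero pattern
        import networkx as nx

        g = nx.from_numpy_array(K != 0)
        assert nx.number_connected_components(g) == 10

    def test_seed_reproducible(self):
        cfg = sim.SimConfig(n_families=5, seed=9)
        a, b = sim.sim_pedigree(cfg), sim.sim_pedigree(cfg)
        assert a.records == b.records

    def test_three_generation_kinship(self, three_gen_ped):
        K = compute_kinship(three_gen_ped)
        idx = {iid: k for k, iid in enumerate(K.ids)}
        assert K.values[idx["F0001_gma"], idx["F0001_g12"]] == 0.125

    def test_config_validation(self):
        with pytest.raises(ValueError, match="maf_range"):
            sim.SimConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError, match="design"):
            sim.SimConfig(family_design="kibbutz")


class TestGenotypes:
    def test_seed_reproducible(self, nuclear_world):
        cfg, ped, G, _ = nuclear_world
        again = sim.sim_genotypes(ped, cfg)
        assert_allclose(again.dosages, G.dosages)

    def test_mendelian_zero_parents(self):
        cfg = sim.SimConfig(n_families=150, k_children=2, m_snps=20, seed=13)
        ped = sim.sim_pedigree(cfg)
        G = sim.sim_genotypes(ped, cfg)
        idx = {iid: k for k, iid in enumerate(G.iids)}
        checked = 0
        for f in range(cfg.n_families):
            fam = f"F{f:04d}"
            pa, ma = G.dosages[idx[f"{fam}_pa"]], G.dosages[idx[f"{fam}_ma"]]
            both_zero = (pa == 0) & (ma == 0)
            for c in (1, 2):
                child = G.dosages[idx[f"{fam}_c{c}"]]
                assert (child[both_zero] == 0).all()
            checked += both_zero.sum()
        assert checked > 0

    def test_founder_frequency_near_maf(self):
        cfg = sim.SimConfig(n_families=1000, k_children=0, m_snps=3,
                            maf_range=(0.3, 0.3), seed=17)
        ped = sim.sim_pedigree(cfg)
        G = sim.sim_genotypes(ped, cfg)
        freq = G.dosages.mean(axis=0) / 2.0
        assert np.abs(freq - 0.3).max() < 0.02

    def test_relative_genotype_covariance(self):
        """Dosage covariance between parent and child approximates
        2 * phi * 2 maf (1 - maf) with phi = 1/4."""
        cfg = sim.SimConfig(n_families=300, k_children=1, m_snps=400,
                            maf_range=(0.3, 0.3), seed=19)
        ped = sim.sim_pedigree(cfg)
        G = sim.sim_genotypes(ped, cfg)
        idx = {iid: k for k, iid in enumerate(G.iids)}
        pa = G.dosages[[idx[f"F{f:04d}_pa"] for f in range(300)]]
        ch = G.dosages[[idx[f"F{f:04d}_c1"] for f in range(300)]]
        covs = [np.cov(pa[:, j], ch[:, j])[0, 1] for j in range(400)]
        expected = 2 * 0.25 * 2 * 0.3 * 0.7
        assert np.mean(covs) == pytest.approx(expected, rel=0.15)


class TestLongitudinal:
    def test_no_missing_when_rate_zero(self, nuclear_world):
        cfg, ped, G, K = nuclear_world
        out = sim.sim_longitudinal(ped, G, None, seed=23, missing_rate=0.0, K=K)
        assert not out.isna().any().any()

    def test_missing_rate_respected(self, nuclear_world):
        cfg, ped, G, K = nuclear_world
        out = sim.sim_longitudinal(ped, G, None, seed=23, missing_rate=0.2, K=K)
        assert out.isna().to_numpy().mean() == pytest.approx(0.2, abs=0.04)

    def test_empirical_covariance_matches_model(self):
        """Unrelated individuals: the empirical 8x8 covariance converges
        to C1 + 0.5 C2 (self-kinship 1/2 scales the genetic block)."""
        n = 4000
        K = KinshipMatrix(0.5 * np.eye(n), [f"i{k}" for k in range(n)])
        cfg = sim.SimConfig(n_families=n, k_children=0, seed=29)
        ped = sim.sim_pedigree(cfg)
        vc = sim.DEFAULT_VC_TRUTH
        y = sim.sim_longitudinal(ped, None, None, vc, seed=29, K=K,
                                 raw_scale=False)
        emp = np.cov(y.to_numpy().T)
        C1, C2 = vc.blocks()
        assert np.abs(emp - (C1 + 0.5 * C2)).max() < 0.05

    def test_frobenius_error_shrinks_with_n(self):
        vc = sim.DEFAULT_VC_TRUTH
        C1, C2 = vc.blocks()
        truth = C1 + 0.5 * C2
        errs = []
        for n in (1000, 4000):
            K = KinshipMatrix(0.5 * np.eye(n), [f"i{k}" for k in range(n)])
            cfg = sim.SimConfig(n_families=n, k_children=0, seed=31)
            ped = sim.sim_pedigree(cfg)
            y = sim.sim_longitudinal(ped, None, None, vc, seed=31, K=K,
                                     raw_scale=False)
            errs.append(np.linalg.norm(np.cov(y.to_numpy().T) - truth))
        assert errs[1] < 0.8 * errs[0]

    def test_raw_scale_roundtrip(self, nuclear_world):
        cfg, ped, G, K = nuclear_world
        raw = sim.sim_longitudinal(ped, G, None, seed=37, K=K)
        trans = sim.sim_longitudinal(ped, G, None, seed=37, K=K, raw_scale=False)
        assert_allclose(np.log(np.log(raw.to_numpy())), trans.to_numpy(),
                        rtol=1e-10)

    def test_causal_effect_shifts_mean(self, nuclear_world):
        cfg, ped, G, K = nuclear_world
        base = sim.sim_longitudinal(ped, G, None, seed=41, K=K, raw_scale=False)
        shifted = sim.sim_longitudinal(ped, G, {"snp0000": (0.5, 0.0)},
                                       seed=41, K=K, raw_scale=False)
        g = G.column("snp0000")
        diff = shifted.to_numpy() - base.to_numpy()
        assert_allclose(diff[:, :4] - 0.5 * g[:, None], 0.0, atol=1e-12)
        assert_allclose(diff[:, 4:], 0.0, atol=1e-12)


class TestResponse:
    def test_reproducible_and_covariates(self, nuclear_world):
        cfg, ped, G, K = nuclear_world
        y1, cov1 = sim.sim_response(ped, G, seed=43, K=K)
        y2, cov2 = sim.sim_response(ped, G, seed=43, K=K)
        pd.testing.assert_series_equal(y1, y2)
        assert cov1["age"].between(20, 70).all()
        assert cov1["smoking"].isin([0.0, 1.0]).all()

    def test_no_genetic_variance_gives_cross_family_independence(self):
        cfg = sim.SimConfig(n_families=400, k_children=2, seed=47)
        ped = sim.sim_pedigree(cfg)
        truth = sim.ResponseTruth(sigma2_g=1e-12, sigma2_e=1.0)
        y, cov = sim.sim_response(ped, None, truth, seed=47)
        resid = y.to_numpy() - (-0.1 + 0.001 * cov["age"].to_numpy()
                                + 0.05 * cov["smoking"].to_numpy())
        fam = resid.reshape(400, 4)
        r = np.corrcoef(fam[:, 0], fam[:, 1])[0, 1]  # pa vs ma, unrelated
        assert abs(r) < 0.12

    def test_snp_effect_enters_mean(self, nuclear_world):
        cfg, ped, G, K = nuclear_world
        y0, _ = sim.sim_response(ped, G, sim.ResponseTruth(), seed=49, K=K)
        y1, _ = sim.sim_response(
            ped, G, sim.ResponseTruth(snp_effects={"snp0001": 1.0}), seed=49, K=K
        )
        assert_allclose(y1 - y0, G.column("snp0001"), atol=1e-12)
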