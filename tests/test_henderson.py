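"""Henderson solver, EM-REML, F-test and the response scans."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla
import statsmodels.api as sm
from numpy.testing import assert_allclose

from famgwas import simulate as sim
from famgwas.dataio import GenotypeMatrix
from famgwas.henderson_response import (
    FtestResult,
    HendersonModel,
    RandomStructure,
    em_reml,
    f_test,
    family_exchangeable_R,
    gls_fit,
    gwas_response,
    region_test,
    solve_mme,
)
from famgwas.pedkin import compute_kinship
from famgwas.regions import GenomicRegion
from oracles import gls_blup


def _random_instance(rng, n=40, q=3, r=None, family_R=False):
    r = r or n
    A = rng.normal(size=(r, r))
    K = A @ A.T / r + 0.5 * np.eye(r)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, q - 1))])
    if r == n:
        Z = np.eye(n)
    else:
        Z = np.zeros((n, r))
        Z[np.arange(n), rng.integers(0, r, n)] = 1.0
    if family_R:
        fams = rng.integers(0, n // 4, n)
        R = family_exchangeable_R(list(fams), 0.3)
    else:
        R = np.eye(n)
    y = rng.normal(size=n)
    return HendersonModel(y, X, Z, K, R)


class TestSolveMme:
    @pytest.mark.parametrize("family_R,r_frac", [(False, 1.0), (True, 1.0), (False, 0.3)])
    def test_matches_gls_blup_closed_forms(self, rng, family_R, r_frac):
        for _ in range(10):
            n = int(rng.integers(20, 50))
            m = _random_instance(rng, n=n, r=max(4, int(n * r_frac)),
                                 family_R=family_R)
            s2g, s2e = rng.uniform(0.3, 2.0, 2)
            beta, u = solve_mme(m, s2g, s2e)
            beta_o, u_o = gls_blup(m.y, m.X, m.Z, m.Kv, m.R, s2g, s2e)
            assert_allclose(beta, beta_o, atol=1e-8)
            assert_allclose(u, u_o, atol=1e-8)

    def test_vanishing_random_effect_is_ols(self, rng):
        m = _random_instance(rng, n=50)
        beta, _ = solve_mme(m, 1e-10, 1.0)
        ols = np.linalg.lstsq(m.X, m.y, rcond=None)[0]
        assert_allclose(beta, ols, atol=1e-6)

    def test_perfect_fit(self, rng):
        m = _random_instance(rng, n=30)
        c = np.array([1.0, -2.0, 0.5])
        m2 = HendersonModel(m.X @ c, m.X, m.Z, m.Kv, m.R)
        beta, u = solve_mme(m2, 0.8, 0.6)
        assert_allclose(beta, c, atol=1e-8)
        assert_allclose(u, 0.0, atol=1e-8)

    def test_rank_deficient_design_named(self, rng):
        n = 30
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            HendersonModel(rng.normal(size=n), X, np.eye(n), np.eye(n) * 0.5,
                           column_names=["const", "x", "x2"])


class TestEmReml:
    def test_balanced_sibships_match_anova_reml(self):
        """Balanced one-way layout: ANOVA estimators are the REML
        solution in closed form."""
        f, s = 60, 4
        n = f * s
        Kfam = sla.block_diag(*([np.ones((s, s))] * f))
        rng = np.random.default_rng(8)
        y = 2.0 + np.repeat(rng.normal(0, 1.0, f), s) + rng.normal(0, 0.8, n)
        m = HendersonModel(y, np.ones((n, 1)), np.eye(n), Kfam)
        fit = em_reml(m, init=(0.5, 0.5), tol=1e-10, max_iter=5000)
        grp = y.reshape(f, s)
        MSB = s * ((grp.mean(1) - y.mean()) ** 2).sum() / (f - 1)
        MSW = ((grp - grp.mean(1, keepdims=True)) ** 2).sum() / (f * (s - 1))
        assert fit.converged
        assert fit.sigma2_e == pytest.approx(MSW, abs=1e-4)
        assert fit.sigma2_g == pytest.approx((MSB - MSW) / s, abs=1e-4)

    def test_monotone_restricted_likelihood(self, rng):
        m = _random_instance(rng, n=80, family_R=True)
        fit = em_reml(m, init=(2.0, 0.1))
        diffs = np.diff(fit.loglik_path)
        assert (diffs > -1e-8).all()

    def test_confounded_structure_raises(self, rng):
        n = 20
        with pytest.raises(ValueError, match="confounded"):
            em_reml(HendersonModel(rng.normal(size=n), np.ones((n, 1)),
                                   np.eye(n), np.eye(n)))

    def test_needs_residual_df(self, rng):
        n = 3
        m = HendersonModel(rng.normal(size=n), np.eye(3), np.eye(n),
                           np.diag([0.5, 1.0, 2.0]))
        with pytest.raises(ValueError, match="n > q"):
            em_reml(m)


class TestFtest:
    def test_zero_contrast_gives_p_one(self, rng):
        m = _random_instance(rng, n=40)
        fit = em_reml(m, init=(1.0, 1.0), max_iter=50)
        # contrast chosen orthogonal to beta_hat: M beta = 0 exactly
        b = fit.beta_hat
        M = np.array([[b[1], -b[0], 0.0]])
        M /= np.linalg.norm(M)
        res = f_test(fit, M)
        assert res.f_stat == pytest.approx(0.0, abs=1e-18)
        assert res.p_value == pytest.approx(1.0)

    def test_single_df_equals_squared_wald(self, rng):
        m = _random_instance(rng, n=50, q=4)
        fit = em_reml(m, init=(1.0, 1.0))
        cov_beta = np.linalg.inv(fit.XtViX)
        for j in range(4):
            M = np.zeros((1, 4))
            M[0, j] = 1.0
            t2 = fit.beta_hat[j] ** 2 / cov_beta[j, j]
            assert f_test(fit, M).f_stat == pytest.approx(t2, abs=1e-10)

    def test_reduces_to_ols_partial_f(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2)),
                             rng.binomial(2, 0.3, n).astype(float)])
        y = X @ np.array([1.0, 0.4, 0.0, 0.1]) + rng.normal(size=n)
        K = np.eye(n) * 0.5 + 0.01
        m = HendersonModel(y, X, np.eye(n), K)
        rot = RandomStructure(np.eye(n), K, np.eye(n))
        ols = sm.OLS(y, X).fit()
        fit = gls_fit(m, rot, 0.0, ols.scale)
        M = np.zeros((2, 4))
        M[0, 2] = M[1, 3] = 1.0
        ours = f_test(fit, M)
        theirs = ols.f_test(M)
        assert ours.f_stat == pytest.approx(float(theirs.fvalue), abs=1e-10)
        assert ours.p_value == pytest.approx(float(theirs.pvalue), abs=1e-10)

    def test_redundant_contrast_raises(self, rng):
        m = _random_instance(rng, n=40)
        fit = em_reml(m, init=(1.0, 1.0), max_iter=50)
        with pytest.raises(ValueError, match="rank"):
            f_test(fit, np.array([[1.0, 0, 0], [2.0, 0, 0]]))


@pytest.fixture(scope="module")
def response_world():
    cfg = sim.SimConfig(n_families=40, k_children=2, m_snps=10, seed=55)
    ped = sim.sim_pedigree(cfg)
    G = sim.sim_genotypes(ped, cfg)
    K = compute_kinship(ped)
    truth = sim.ResponseTruth(snp_effects={"snp0002": 0.8})
    y, cov = sim.sim_response(ped, G, truth, seed=55)
    return ped, G, K, y, cov


class TestResponseScan:
    def test_planted_snp_has_smallest_p(self, response_world):
        ped, G, K, y, cov = response_world
        out = gwas_response(y, cov, G, K)
        assert out.loc[out["p"].idxmin(), "unit_id"] == "snp0002"
        assert (out["df1"] == 1).all()
        assert (out["df2"] == len(y) - 4).all()

    def test_refit_and_shared_agree_on_ranking(self, response_world):
        ped, G, K, y, cov = response_world
        full = gwas_response(y, cov, G, K, refit=True)
        fast = gwas_response(y, cov, G, K, refit=False)
        assert full.loc[full["p"].idxmin(), "unit_id"] == \
            fast.loc[fast["p"].idxmin(), "unit_id"]

    def test_constant_columns_reported_not_fatal(self, response_world):
        ped, G, K, y, cov = response_world
        const = GenotypeMatrix(
            np.zeros((len(y), 2)), list(y.index),
            pd.DataFrame({"snp_id": ["c1", "c2"], "chrom": "1", "bp": [1, 2]}),
        )
        out = gwas_response(y, cov, const, K)
        assert out["p"].isna().all()
        assert (out["reason"] == "constant genotype column").all()


class TestRegionTest:
    def _region(self, snp_ids, rid="genic:TEST"):
        return GenomicRegion(rid, "1", 1, 10**9, "genic",
                             snp_ids=list(snp_ids), pruned_snp_ids=list(snp_ids))

    def test_single_snp_region_equals_scan(self, response_world):
        ped, G, K, y, cov = response_world
        scan = gwas_response(y, cov, G, K)
        res = region_test(y, cov, self._region(["snp0004"]), G, K)
        row = scan[scan["unit_id"] == "snp0004"].iloc[0]
        assert res.f_stat == pytest.approx(row["f"], rel=1e-8)
        assert res.p_value == pytest.approx(row["p"], rel=1e-8)

    def test_snp_order_invariance(self, response_world):
        ped, G, K, y, cov = response_world
        ids = ["snp0001", "snp0003", "snp0005"]
        a = region_test(y, cov, self._region(ids), G, K)
        b = region_test(y, cov, self._region(ids[::-1]), G, K)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-10)
        assert a.df1 == b.df1 == 3

    def test_collinear_snp_dropped_with_warning(self, response_world):
        ped, G, K, y, cov = response_world
        dup = GenotypeMatrix(
            np.column_stack([G.dosages[:, 0], G.dosages[:, 0]]),
            list(G.iids),
            pd.DataFrame({"snp_id": ["a", "b"], "chrom": "1", "bp": [1, 2]}),
        )
        with pytest.warns(UserWarning, match="collinear"):
            res = region_test(y, cov, self._region(["a", "b"]), dup, K)
        assert res.df1 == 1

    def test_saturated_design_raises(self, response_world):
        ped, G, K, y, cov = response_world
        many = [f"s{k}" for k in range(len(y))]
        reg = GenomicRegion("genic:BIG", "1", 1, 10**9, "genic",
                            snp_ids=many, pruned_snp_ids=many)
        with pytest.raises(ValueError, match="saturate"):
            region_test(y, cov, reg, G, K)


def test_family_exchangeable_R_structure():
    R = family_exchangeable_R(["a", "a", "b"], 0.4)
    assert_allclose(R, [[1.0, 0.4, 0.0], [0.4, 1.0, 0.0], [0.0, 0.0, 1.0]])
    with pytest.raises(ValueError):
        family_exchangeable_R(["a"], 1.5)
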