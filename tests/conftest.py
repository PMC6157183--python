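import numpy as np
import pytest

from famgwas import simulate as sim
from famgwas.covstruct import KinshipEigen
from famgwas.pedkin import compute_kinship


@pytest.fixture(scope="session")
def nuclear_world():
    """50 nuclear families (n = 200) with kinship and genotypes."""
    cfg = sim.SimConfig(n_families=50, k_children=2, m_snps=12, seed=11)
    ped = sim.sim_pedigree(cfg)
    G = sim.sim_genotypes(ped, cfg)
    K = compute_kinship(ped)
    return cfg, ped, G, K


@pytest.fixture(scope="session")
def nuclear_eigen(nuclear_world):
    _, _, _, K = nuclear_world
    return KinshipEigen(K)


@pytest.fixture(scope="session")
def three_gen_ped():
    cfg = sim.SimConfig(n_families=5, family_design="three_generation", seed=7)
    return sim.sim_pedigree(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
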