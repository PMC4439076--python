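import numpy as np
import pytest

from karyofuse import PopulationConfig, SALocus
from karyofuse.simulate import TreeSimConfig, simulate_tree


@pytest.fixture(scope="session")
def unbiased_pop():
    return PopulationConfig(N_f=5000, N_m=5000, mu_f=1e-6, mu_m=1e-6)


@pytest.fixture(scope="session")
def fig6_locus():
    """Sex-symmetric antagonism: 10% homozygous / 9% heterozygous advantage."""
    return SALocus.symmetric(s_hom=0.10, s_het=0.09)


@pytest.fixture(scope="session")
def small_tree():
    return simulate_tree(TreeSimConfig(n_tips=6, seed=11))


@pytest.fixture(scope="session")
def medium_tree():
    return simulate_tree(TreeSimConfig(n_tips=100, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)
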