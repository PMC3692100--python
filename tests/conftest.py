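import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import phylocoev as pc
from phylocoev.benchmark import default_benchmark_mixture

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_leaf_tree():
    """The hand-worked two-leaf example: pendant branches of 0.5 each."""
    return pc.Phylogeny.from_newick("(A:0.5,B:0.5);")


@pytest.fixture(scope="session")
def unit_mix():
    """Single-category g = l = 1 model (already unit-flux)."""
    return pc.build_rate_mixture(pc.GainLossParams(g=1.0, l=1.0, model_tier="single"))


@pytest.fixture(scope="session")
def bench_mix():
    return default_benchmark_mixture()


@pytest.fixture(scope="session")
def tree8():
    return pc.random_phylogeny(8, seed=80, total_length=4.0)


@pytest.fixture(scope="session")
def tree64():
    return pc.random_phylogeny(64, seed=640)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pattern(tree8, unit_mix):
    return pc.simulate_independent_sites(tree8, unit_mix, 30, seed=81)
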