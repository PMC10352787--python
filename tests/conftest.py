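import pytest
from hypothesis import settings

from gtai import build_family_partition

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from gtai.synthetic_data import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def partition():
    return build_family_partition(1)


@pytest.fixture(scope="session")
def small_sim():
    """A small selected genome: 60 high-expression + 240 background genes."""
    config = SimulationConfig(
        n_high=60, n_background=240, gene_length_codons=(60, 150),
        beta=5.0, seed=7,
    )
    return simulate_genome(config)


@pytest.fixture(scope="session")
def small_genome(small_sim):
    return small_sim[0]


@pytest.fixture(scope="session")
def small_truth(small_sim):
    return small_sim[1]
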