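import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "derandomized", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("derandomized")

from tagedit.pcr import PrimerPair  # noqa: E402
from tagedit.simulate import (  # noqa: E402
    SimulationConfig,
    amplicon_primer_pair,
    build_array,
    long_primer_pair,
    simulate_population,
)
from tagedit.targets import enumerate_targets  # noqa: E402


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(n_lines=12)


@pytest.fixture(scope="session")
def array(sim_config):
    return build_array(sim_config, seed=11)


@pytest.fixture(scope="session")
def amp_pair(array) -> PrimerPair:
    return amplicon_primer_pair(array)


@pytest.fixture(scope="session")
def long_pair(array) -> PrimerPair:
    return long_primer_pair(array)


@pytest.fixture(scope="session")
def target_set(array, amp_pair):
    return enumerate_targets(array, amp_pair)


@pytest.fixture(scope="session")
def population(array, sim_config):
    return simulate_population(array, sim_config, seed=12)


@pytest.fixture(scope="session")
def cuts(array):
    return {g.id: g.cut_point for g in array.array_genes()}
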