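import pytest

from pansynkit.synthetic import SimConfig, simulate_homology, simulate_pav


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    # n=20 keeps the softcore range non-empty (19 only) under the strict rule
    return SimConfig(n_accessions=20, n_families=300, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_config):
    pav, truth = simulate_pav(small_config)
    hits = simulate_homology(pav, truth, small_config)
    return pav, truth, hits
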