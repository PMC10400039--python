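import pytest

from methyldup import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    return sd.SimulationConfig(
        genes_per_chromosome=150,
        n_tandem=5,
        n_proximal=5,
        n_translocated=5,
        n_dispersed=5,
        n_accessions=40,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A compact simulated dataset shared across read-only tests."""
    return sd.simulate_all(small_config, seed=11)


@pytest.fixture(scope="session")
def small_dataset_dir(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("simdata")
    sd.simulate_all(small_config, seed=11, out_dir=out)
    return out
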