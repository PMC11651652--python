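import pytest

from ribod.synthetic_data import SimulationParams, simulate_library


@pytest.fixture(scope="session")
def small_truth(tmp_path_factory):
    """A small zero-error synthetic library shared across tests."""
    out = tmp_path_factory.mktemp("sim_small")
    params = SimulationParams(n_cells=20, n_genes=12, n_rrna_genes=2, seed=11)
    return simulate_library(params, out)


@pytest.fixture(scope="session")
def tiny_whitelist():
    from ribod.synthetic_data import make_whitelist

    return make_whitelist(n=24, length=8, seed=5)
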