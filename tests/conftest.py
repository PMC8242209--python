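import pytest

from psas import (
    fit_matrix,
    load_index_set,
    make_scenario,
    simulate_assay,
)


@pytest.fixture(scope="session")
def index_set():
    return load_index_set()


@pytest.fixture(scope="session")
def paper_like():
    """Default paper_like scenario (noisy defaults)."""
    return make_scenario("paper_like", seed=7)


@pytest.fixture(scope="session")
def noiseless_scenario():
    return make_scenario("paper_like", seed=7, noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_matrix(noiseless_scenario):
    """Fitted matrix from one noiseless paper_like assay."""
    return fit_matrix(simulate_assay(noiseless_scenario))
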