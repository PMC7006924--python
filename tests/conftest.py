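import pytest

from coralquant import SpikeSpec, default_designs, gen_psm_experiment


@pytest.fixture(scope="session")
def designs():
    return default_designs()


@pytest.fixture(scope="session")
def small_experiment(designs):
    """A 60-protein spiked experiment shared across tests (seeded)."""
    spec = SpikeSpec(n_proteins=60, seed=11)
    psms, truth = gen_psm_experiment(spec, designs)
    return spec, psms, truth
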