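import numpy as np
import pytest

from convergene import synthdata


@pytest.fixture(scope="session")
def evidence_table():
    """The packaged 40-row driver-gene evidence table."""
    return synthdata.driver_gene_evidence()


@pytest.fixture(scope="session")
def planted_study():
    """A study with three planted modules and planted DEGs (fixed seed)."""
    config = synthdata.SimulationConfig(
        n_genes=400,
        n_samples_per_group=50,
        module_sizes=(50, 50, 50),
        within_module_correlation=0.7,
        deg_fraction=0.1,
        deg_effect_size=1.0,
        noise_sd=0.5,
        seed=11,
    )
    return synthdata.simulate_expression(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
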