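import numpy as np
import pytest

from slafbsa.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A fast, fully simulated study: 120 plants, 400 markers, one causal locus."""
    config = SimulationConfig(
        seed=11,
        n_plants=120,
        bulk_size=15,
        n_markers=400,
        chrom_length_bp=20_000_000,
    )
    return simulate_experiment(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
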