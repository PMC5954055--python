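import pytest

from pscqc.synthetic import SimulationConfig


@pytest.fixture
def small_config():
    """Desk-scale configuration shared by fast tests."""
    return SimulationConfig(
        seed=42,
        chromosomes=("1", "2", "3", "12"),
        n_probes_per_chromosome=200,
        n_snps_per_chromosome=200,
    )


@pytest.fixture
def tissue_config():
    return SimulationConfig(seed=42)
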