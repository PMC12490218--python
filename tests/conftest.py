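import numpy as np
import pytest

from cisprog.simulate import Condition, SimConfig, generate_experiment


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down study: quick to simulate, still carries all planted signal."""
    return SimConfig(
        n_genes=600,
        n_cells_per_condition=40,
        cell_line_archetypes=1,
        replicates_per_archetype=2,
        n_noise_programs=3,
        program_support=50,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_experiment(small_config, archetype=0, replicate=0)


@pytest.fixture(scope="session")
def default_bundle():
    """One experiment at the full default study conditions."""
    return generate_experiment(SimConfig(seed=5), archetype=0, replicate=0)
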