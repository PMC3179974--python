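import pytest

from coevotree import SimulationConfig, simulate_benchmark, simulate_species_tree


@pytest.fixture(scope="session")
def small_tree():
    return simulate_species_tree(12, seed=7)


@pytest.fixture(scope="session")
def small_benchmark():
    """Compact benchmark for structural tests: 15 organisms, 12 families."""
    cfg = SimulationConfig(
        n_organisms=15,
        n_families=12,
        n_interacting_pairs=4,
        retention_prob=0.9,
        seed=5,
    )
    return simulate_benchmark(cfg)


@pytest.fixture(scope="session")
def headline_benchmark():
    """The default study conditions: 40 organisms, 60 families, 20 strong
    co-evolving pairs."""
    return simulate_benchmark(SimulationConfig(seed=11))
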