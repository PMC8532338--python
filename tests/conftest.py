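import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitoarray.simulate import (
    ManifestSpec,
    SimulationConfig,
    simulate_dataset,
    simulate_haplotree,
    simulate_manifest,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg():
    """Compact study conditions: 2,000-bp genome, binary subdivisions down
    to five-character African terminals, defaults otherwise."""
    return SimulationConfig(seed=1, genome_length=2000, children_per_node=2)


@pytest.fixture(scope="session")
def sim_tree(small_cfg):
    return simulate_haplotree(small_cfg)


@pytest.fixture(scope="session")
def sim_dataset(small_cfg, sim_tree):
    return simulate_dataset(sim_tree, small_cfg)


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise-free variant of the compact conditions (no private mutations)."""
    return SimulationConfig(
        seed=1, genome_length=2000, children_per_node=2,
        private_mutations_per_sample=0.0,
    )


@pytest.fixture(scope="session")
def clean_tree(clean_cfg):
    return simulate_haplotree(clean_cfg)


@pytest.fixture(scope="session")
def clean_dataset(clean_cfg, clean_tree):
    return simulate_dataset(clean_tree, clean_cfg)


@pytest.fixture(scope="session")
def full_manifest(clean_tree):
    """Manifest covering every clade-defining position, no background."""
    return simulate_manifest(
        clean_tree, ManifestSpec("alldef", 1.0, 0, seed=1), 2000
    )
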