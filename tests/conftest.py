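import numpy as np
import pytest

from endotx.synthetic import Annotation, SimulationConfig, make_annotation


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact study configuration used across module tests."""
    return SimulationConfig(seed=11, n_genes=60, n_variant_sites=120,
                            n_editing_sites=20, n_splicing_events=80)


@pytest.fixture(scope="session")
def small_annotation(small_config) -> Annotation:
    return make_annotation(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
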