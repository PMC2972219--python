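import numpy as np
import pytest

import hapscan as hs


@pytest.fixture(scope="session")
def small_config() -> hs.SimConfig:
    """A quick three-chromosome study used across modules."""
    return hs.SimConfig(
        chromosomes=(("1", 50.0, 8), ("2", 50.0, 8), ("3", 50.0, 8)),
        n_generations=40,
        n_individuals=200,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config) -> hs.SimulatedStudy:
    return hs.simulate_population(small_config)


@pytest.fixture(scope="session")
def small_tails(small_study) -> hs.TailSelection:
    return hs.select_tails(small_study.phenotypes, small_study.sires, 42, 42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
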