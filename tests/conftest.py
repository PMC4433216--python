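import numpy as np
import pytest

from herbcode.pipeline import AnalysisParams, run_synthetic_study
from herbcode.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact but fully featured market survey: 3 target genera, 60 queries."""
    return SimulationConfig(
        n_genera=3,
        species_per_genus=3,
        refs_per_species=4,
        n_offtarget_genera=2,
        n_queries=60,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return run_synthetic_study(small_config, AnalysisParams())


@pytest.fixture(scope="session")
def default_study():
    """The full-size study conditions: 8 target genera, 200 queries."""
    return run_synthetic_study(SimulationConfig(seed=11), AnalysisParams())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240515)
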