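import numpy as np
import pytest

from immunosig import (SimulationConfig, TrainingConfig, preprocess,
                       simulate_cohort, simulate_single_cells,
                       train_signature_model)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Desk-scale study conditions shared by most tests."""
    return SimulationConfig(n_genes=120, n_cells=600, immuno_set_size=25,
                            n_patients=300, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    cells, truth = simulate_single_cells(small_cfg)
    return cells, truth


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_sim):
    _, truth = small_sim
    bulk, cohort = simulate_cohort(small_cfg, truth)
    return bulk, cohort


@pytest.fixture(scope="session")
def small_model(small_sim):
    cells, _ = small_sim
    pp = preprocess(cells)
    return train_signature_model(pp, 6, TrainingConfig(epochs=250, seed=3)), pp


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
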