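import numpy as np
import pytest

from climvel import Grid, MonthlyNormals


def constant_normals(monthly_temps, precip=600.0, shape=(2, 2), cell=50.0):
    """Normals where every month is spatially constant (helper for oracles)."""
    temps = [Grid(np.full(shape, float(t)), cell) for t in monthly_temps]
    return MonthlyNormals(temps=temps,
                          precip_annual=Grid(np.full(shape, float(precip)), cell))


@pytest.fixture
def small_grid():
    values = np.arange(20, dtype=float).reshape(4, 5)
    return Grid(values, cell_size=50.0, origin=(1000.0, 2000.0))


@pytest.fixture(scope="session")
def relief3_experiment():
    """One full fine-vs-coarse pipeline run, shared across pipeline tests."""
    from climvel import ExperimentConfig, run_experiment

    return run_experiment(ExperimentConfig(seed=11, shape=(300, 300),
                                           n_pas=120))
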