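import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import psdkme as pk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_grid():
    return pk.build_log_grid()


@pytest.fixture(scope="session")
def design29():
    return pk.load_table1_design()


@pytest.fixture(scope="session")
def scenario():
    return pk.ScenarioParams()


@pytest.fixture(scope="session")
def dataset29(design29, scenario, default_grid):
    """Noise-free 29-run synthetic dataset on the default grid."""
    design, histograms = pk.generate_dataset(design29, scenario, default_grid)
    return design, histograms


@pytest.fixture(scope="session")
def fitted29(dataset29):
    """Default-pipeline fit (median heuristic, LOOCV λ selection)."""
    design, histograms = dataset29
    return pk.fit_conditional_model(design, histograms)


@pytest.fixture(scope="session")
def report29(fitted29, dataset29):
    design, _ = dataset29
    return pk.evaluate_loocv(fitted29, design.experiment_ids)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_simplex(rng, n):
    w = rng.dirichlet(np.ones(n))
    return w / w.sum()
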