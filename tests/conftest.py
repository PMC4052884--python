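import numpy as np
import pandas as pd
import pytest

from fasem import bundled
from fasem.factor_engine import GroupMoments
from fasem.synthetic_data import SimulationConfig, generate

GROUPS = ("male", "female")


@pytest.fixture(scope="session")
def panel():
    return bundled.bundled_panel()


@pytest.fixture(scope="session")
def m7_params():
    return bundled.bundled_m7_parameters()


@pytest.fixture(scope="session")
def m7_spec():
    return bundled.bundled_m7_spec()


@pytest.fixture(scope="session")
def population_moments(m7_params):
    """Implied moments of the published model at the study's group sizes."""
    return GroupMoments.from_parameters(m7_params, {"male": 1434, "female": 1762})


@pytest.fixture(scope="session")
def synthetic_study():
    """One standardized-scale synthetic study at the published group sizes."""
    data, scores = generate(SimulationConfig(seed=20140415))
    return data, scores


def by_group(data: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {g: data[data["gender"] == g].drop(columns="gender") for g in GROUPS}


@pytest.fixture(scope="session")
def toy_one_factor():
    """p=2 single-factor model with closed-form implied covariance."""
    lam = np.array([0.8, 0.6])
    theta = np.diag([0.36, 0.64])
    sigma = np.outer(lam, lam) + theta
    return lam, theta, sigma
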