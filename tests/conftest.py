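import numpy as np
import pandas as pd
import pytest

from celltraffic.kinetics import KineticParameters
from celltraffic.physiology import CirculatorySystem, OrganSpec, build_system
from celltraffic.synthetic import default_truth, make_dataset


@pytest.fixture(scope="session")
def rat_system() -> CirculatorySystem:
    """The bundled 8-organ rat system with default wiring."""
    return build_system()


@pytest.fixture(scope="session")
def truth(rat_system) -> KineticParameters:
    return default_truth(rat_system, seed=0)


@pytest.fixture(scope="session")
def noise_free_dataset(rat_system, truth):
    """Eight points plus the initial condition per organ, no noise."""
    return make_dataset(rat_system, truth)


@pytest.fixture(scope="session")
def dense_dataset(rat_system, truth):
    """Densely sampled fixture spanning the organs' equilibration times."""
    grid = np.concatenate([[0.0], np.geomspace(0.05, 200.0, 160)])
    return make_dataset(rat_system, truth, time_grid=grid)


@pytest.fixture
def single_organ_system() -> CirculatorySystem:
    """Minimal closed system: blood pool plus one generic organ."""
    organ = OrganSpec(
        name="Muscle",
        vascular_volume=1.0,
        interstitial_volume=2.0,
        blood_flow=3.0,
        lymph_route="direct_to_heart",
    )
    return CirculatorySystem((organ,), blood_pool_volume=5.0)


@pytest.fixture
def single_organ_params(single_organ_system) -> KineticParameters:
    return KineticParameters(
        single_organ_system.names, e=np.array([0.3]), mu=np.array([0.4])
    )


def make_params(system, e, mu) -> KineticParameters:
    return KineticParameters(system.names, np.asarray(e, float), np.asarray(mu, float))
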