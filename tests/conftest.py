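import numpy as np
import pytest

from rhizodose.environment import EnvironmentSchedule, controlled_room_trajectory
from rhizodose.ions import N_IONS
from rhizodose.model_core import PlantParams, TankState
from rhizodose.synthetic_data import STEINER_MEAN_MOL_M3, species_preset


@pytest.fixture(scope="session")
def pakchoi():
    return species_preset("pakchoi")


@pytest.fixture(scope="session")
def schedule():
    return EnvironmentSchedule()


@pytest.fixture(scope="session")
def stochastic_schedule():
    return EnvironmentSchedule(mode="stochastic")


@pytest.fixture(scope="session")
def room_env(schedule):
    return controlled_room_trajectory(schedule, 168.0, 1.0)


@pytest.fixture
def steiner_state():
    return TankState.from_concentrations(0.0, 0.3, STEINER_MEAN_MOL_M3)


@pytest.fixture(scope="session")
def toy_params():
    """Small, fast, hand-checkable parameter set (single plant)."""
    return PlantParams(
        jmax=np.full(N_IONS, 2e-5), km=np.full(N_IONS, 0.5),
        rmax=1.0, K1=9.0, k1=0.01, r0=5e-4,
        a_lai=3.0, b_lai=120.0, x0=600.0,
        a_trs=1e-7, b_trs=5e-6, k_ext=0.7, n_plants=1)


class ConstantEnvironment:
    """Fixed (K+, VPD) forcing for analytic checks."""

    def __init__(self, k_plus=0.0, vpd=0.0):
        self.k_plus = k_plus
        self.vpd = vpd

    def sample(self, times):
        t = np.asarray(times, dtype=float)
        return np.full_like(t, self.k_plus), np.full_like(t, self.vpd)


@pytest.fixture
def dark_env():
    return ConstantEnvironment(0.0, 0.0)


@pytest.fixture
def const_env():
    return ConstantEnvironment(100.0, 1.2)
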