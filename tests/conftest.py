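import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cardiowean import (
    CVSParameters,
    DriverConfig,
    FreeParameterSet,
    NoiseWeights,
    PORCINE_BASELINE,
    SimulationSettings,
    steady_state_observables,
)


@pytest.fixture(scope="session")
def pig1() -> CVSParameters:
    """Baseline parameter set of the first reference pig (healthy heart,
    no extracorporeal support)."""
    return PORCINE_BASELINE["Pig1"]


@pytest.fixture(scope="session")
def pig1_free(pig1) -> FreeParameterSet:
    return FreeParameterSet(E_h=pig1.E_h, A_h=pig1.A_h, E_a=pig1.E_a,
                            R_s=pig1.R_s, SBV=pig1.SBV)


@pytest.fixture(scope="session")
def driver() -> DriverConfig:
    return DriverConfig()


@pytest.fixture(scope="session")
def pig1_observables(pig1):
    """Noise-free steady-state observables of the Pig1 baseline (shared:
    several identification tests fit against these)."""
    obs, y0, converged = steady_state_observables(pig1, 0.0)
    assert converged
    return obs


@pytest.fixture(scope="session")
def sigmas() -> NoiseWeights:
    return NoiseWeights()
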