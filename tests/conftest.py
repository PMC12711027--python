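import numpy as np
import pytest

from plasmidcomp.model import ModelParams, PopulationState


@pytest.fixture
def standard_params() -> ModelParams:
    """The standard parameter set used for all sweeps."""
    return ModelParams()


@pytest.fixture
def printed_params() -> ModelParams:
    """Standard parameters with the bare printed equations (no co-infection
    displacement flux)."""
    return ModelParams(displacement_flux=False)


@pytest.fixture
def invasion_state() -> PopulationState:
    """Wildtype near its equilibrium plus a small co-infected inoculum."""
    return PopulationState(N0=0.0, NW=0.89, NM=0.0, NWM=0.01)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
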