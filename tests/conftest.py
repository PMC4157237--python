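import numpy as np
import pytest

import reefmetab as rm


@pytest.fixture(scope="session")
def scenario():
    return rm.default_scenario(seed=7)


@pytest.fixture(scope="session")
def tables(scenario):
    """All synthetic input tables for the default scenario (generated once)."""
    return rm.generate_all(scenario)


@pytest.fixture(scope="session")
def scenario_factors(scenario):
    """Scenario-true 2D->3D conversion factor means per incubation group."""
    return {g: scenario.conversion_factors[g][0]
            for g in rm.INCUBATION_GROUPS}


@pytest.fixture(scope="session")
def fluxes(tables, scenario_factors):
    return rm.compute_fluxes(tables["incubations"], tables["blanks"],
                             scenario_factors)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
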