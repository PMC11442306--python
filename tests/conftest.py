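"""Shared fixtures: the default synthetic run and ensemble are expensive
(minutes), so they are computed once per session and shared between the
experiment-level unit tests and the acceptance suite."""

import numpy as np
import pytest

from borealfire.experiments import default_ensemble_scenarios
from borealfire.forcing import ScenarioConfig
from borealfire.simulate import RunProtocol, run_simulation


@pytest.fixture(scope="session")
def default_run():
    """One 30-year transient run of the default scenario (60-year spin-up)."""
    scenario = ScenarioConfig(seed=0, years=30)
    return run_simulation(RunProtocol(years=30, spinup_years=60), scenario)


@pytest.fixture(scope="session")
def ensemble_runs():
    """The default six-member synthetic ensemble (30-year transients)."""
    base = ScenarioConfig(seed=0, years=30)
    protocol = RunProtocol(years=30, spinup_years=60)
    return [
        run_simulation(protocol, m) for m in default_ensemble_scenarios(base, 6)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
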