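import numpy as np
import pytest

import clonobranch as cb


@pytest.fixture(scope="session")
def carbon_profiles():
    """Truth profiles of the default carbon-ion study (c = 0.4)."""
    return cb.default_dose_profiles(0.4)


@pytest.fixture(scope="session")
def gamma_profiles():
    return cb.gamma_dose_profiles(0.4)


@pytest.fixture(scope="session")
def carbon_study():
    """One default synthetic carbon study (~50 000 colonies per dose)."""
    return cb.generate_study(cb.SyntheticStudyConfig(seed=20260921))


def _simulate_map(profiles, seed, n_colonies=4000, n_runs=1):
    out = {}
    for i, dose in enumerate(sorted(profiles)):
        cfg = cb.SimulationConfig(
            seed=seed + i, n_colonies_per_run=n_colonies, n_runs=n_runs
        )
        out[dose] = cb.simulate_experiment(profiles[dose], cfg)
    return out


@pytest.fixture(scope="session")
def carbon_sims(carbon_profiles):
    """Lattice simulations of the carbon study, 4000 colonies per dose."""
    return _simulate_map(carbon_profiles, seed=101)


@pytest.fixture(scope="session")
def gamma_sims(gamma_profiles):
    return _simulate_map(gamma_profiles, seed=202)
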