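import numpy as np
import pytest

import socioclim as sc


@pytest.fixture(scope="session")
def baseline():
    """Packaged baseline configuration and its triangular distributions."""
    return sc.default_config()


@pytest.fixture(scope="session")
def baseline_config(baseline):
    return baseline[0]


@pytest.fixture(scope="session")
def distributions(baseline):
    return baseline[1]


@pytest.fixture(scope="session")
def baseline_traj(baseline_config):
    """One full coupled run at baseline, shared across tests."""
    return sc.run_coupled(baseline_config)


@pytest.fixture(scope="session")
def raw_social():
    """A social parameter set carrying the raw (alpha, gamma, c) form."""
    return sc.SocialParams.from_raw(
        alpha=1.2, gamma=0.2, c=1.5, ftilde_max=2.0,
        kappa=0.05, delta=1.0, omega=3.0, Tc=2.5, tf=25.0, tp=10.0,
    )


@pytest.fixture
def zero_schedule():
    """Emission schedule that is identically zero (equilibrium forcing)."""
    years = np.arange(1800, 2015, dtype=float)
    return sc.EmissionSchedule(
        years=years, rates=np.zeros_like(years), eps_max=0.0, s=50.0
    )
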