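import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import placond as pc

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ledger() -> pc.MassLedger:
    """The optimal-run reactor charge."""
    return pc.reference_ledger()


@pytest.fixture(scope="session")
def upper_init(ledger) -> pc.InitialState:
    """Initial concentrations from the 7.11 g upper-bound dry-acid mass."""
    return pc.initial_concentrations(ledger, 7.11)


@pytest.fixture(scope="session")
def table_params() -> pc.KineticParameters:
    """Optimal rate constants of the upper-bound mass scenario."""
    return pc.KineticParameters(k1=15.06, k_neg1=6.47e-2, kw=4.85e-4)


@pytest.fixture(scope="session")
def hourly_200h() -> np.ndarray:
    return np.arange(3600.0, 720_001.0, 3600.0)


@pytest.fixture(scope="session")
def reference_trajectory(table_params, upper_init, hourly_200h) -> pc.Trajectory:
    """Default-settings 200 h run at the optimal constants, sampled hourly."""
    return pc.simulate(table_params, upper_init, sample_times=hourly_200h)


@pytest.fixture(scope="session")
def smooth_fit_integrator() -> pc.IntegratorSettings:
    """Estimation-grade integrator: coarse base step, tight change threshold
    (smooth objective), bounded step budget for pathological corners."""
    return pc.IntegratorSettings(
        base_step=60.0, frac_threshold=0.01, t_end=720_000.0, max_steps=5_000_000
    )
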