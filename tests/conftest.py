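import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from rfepr.pipeline import CycleConfig, build_standard_system, run_rfepr  # noqa: E402
from rfepr.units import ThermoState  # noqa: E402


@pytest.fixture(scope="session")
def thermo300():
    return ThermoState(300.0)


@pytest.fixture(scope="session")
def standard_config():
    """The standard study conditions: default toy, default schedules,
    10^4 sweeps per lambda-state."""
    return CycleConfig(master_seed=11)


@pytest.fixture(scope="session")
def standard_system(standard_config):
    return build_standard_system(standard_config)


@pytest.fixture(scope="session")
def standard_cycle_report(standard_config):
    return run_rfepr(standard_config)


@pytest.fixture(scope="session")
def reverse_cycle_report():
    return run_rfepr(CycleConfig(master_seed=12, direction="syn_to_anti"))


@pytest.fixture(scope="session")
def doubled_restraint_report():
    return run_rfepr(CycleConfig(master_seed=13, restraint_k_angular=2000.0,
                                 restraint_k_distance=2000.0))


@pytest.fixture()
def mini_config():
    """Scaled-down cycle for fast pipeline plumbing tests."""
    return CycleConfig(
        master_seed=5, sweeps_per_state=400, thin=2,
        restrain_schedule=(0.0, 0.3, 1.0),
        fep_schedule=(0.0, 0.2, 0.5, 0.8, 1.0),
        release_schedule=(1.0, 0.3, 0.0),
        convergence_fractions=(0.25, 0.5, 0.75, 1.0),
    )
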