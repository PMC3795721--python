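import pytest
from hypothesis import HealthCheck, settings

from dpiscreen import DesignConfig, build_plate_layout, design_library

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config():
    return DesignConfig(seed=1)


@pytest.fixture(scope="session")
def default_library(default_config):
    """One full-scale designed library shared across the suite."""
    return design_library(default_config)


@pytest.fixture(scope="session")
def default_layout(default_library):
    return build_plate_layout(default_library)


@pytest.fixture(scope="session")
def toy_config_k2():
    return DesignConfig(
        k=2,
        min_probe_len=4,
        max_probe_len=6,
        min_completion_probe_len=3,
        masterstrand_target_len=30,
        n_masterstrands=1,
        well_budget=48,
        n_control_wells=4,
        seed=3,
    )


@pytest.fixture(scope="session")
def toy_config_k3():
    return DesignConfig(
        k=3,
        min_probe_len=6,
        max_probe_len=10,
        min_completion_probe_len=4,
        masterstrand_target_len=80,
        n_masterstrands=2,
        well_budget=96,
        n_control_wells=8,
        seed=3,
    )
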