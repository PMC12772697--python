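import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from protonboltz.materials import (
    load_nuclear_tables,
    load_range_table,
    water,
)

settings.register_profile(
    "ci", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def rt():
    return load_range_table()


@pytest.fixture(scope="session")
def nt():
    return load_nuclear_tables()


@pytest.fixture(scope="session")
def mat():
    return water()


@pytest.fixture(scope="session")
def grid100():
    from protonboltz.espectra import build_energy_grid
    return build_energy_grid(100.0, 0.42, 0.055, 93.0)


@pytest.fixture(scope="session")
def transport100():
    """One 100 MeV pencil transport shared across tests (Coulomb only)."""
    from protonboltz.driver import RunConfig, _transport
    return _transport(RunConfig(e_init=100.0, nuclear="off",
                                kernel="normal-only"))


@pytest.fixture(scope="session")
def depthdose40():
    from protonboltz.driver import RunConfig, run_depth_dose
    return run_depth_dose(RunConfig(e_init=40.0))


def assert_close(a, b, rtol):
    assert abs(a - b) <= rtol * abs(b), f"{a} vs {b} (rtol {rtol})"
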