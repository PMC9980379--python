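import numpy as np
import pytest
from hypothesis import settings

import mnm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def wb():
    return mnm.wb_spec()


@pytest.fixture(scope="session")
def sean():
    return mnm.sean_spec()


@pytest.fixture(scope="session")
def wb_boundaries(wb):
    """WB firing/DB boundaries on a coarse Δν_K ∈ [0, 20] grid."""
    grid = wb.nu_k_hat + np.linspace(0.0, 20.0, 5)
    return mnm.trace_boundaries(wb, grid)


@pytest.fixture(scope="session")
def sean_boundaries(sean):
    grid = sean.nu_k_hat + np.linspace(0.0, 20.0, 5)
    return mnm.trace_boundaries(sean, grid)


@pytest.fixture(scope="session")
def i_mass(wb, wb_boundaries):
    """I-mass parametrization at reduced resolution (fast test build)."""
    curves = mnm.maxima_along_shifted_db(wb, wb_boundaries,
                                         duration=1600.0, transient_ms=400.0)
    return mnm.fit_parametrization(curves, "I", spec=wb)


@pytest.fixture(scope="session")
def e_mass(sean, sean_boundaries):
    curves = mnm.maxima_along_shifted_db(sean, sean_boundaries,
                                         duration=1600.0, transient_ms=400.0)
    return mnm.fit_parametrization(curves, "E", spec=sean)


@pytest.fixture(scope="session")
def couplet(e_mass, i_mass):
    """Nominal-coupling network configuration at Δν_K = 0."""
    return mnm.NetworkConfig(e_param=e_mass, i_param=i_mass)
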