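import math

import pytest

import fptiming as fp


@pytest.fixture
def unregulated():
    """Constitutive production calibrated to the gamma law: alpha = x*/t*."""
    return fp.unregulated_system(15, 1.0)


@pytest.fixture
def activator_h1():
    """Accumulating activator with k t* = 20, K = 15, H = 1 (illustrative
    deterministic-dynamics parameter set)."""
    return fp.SystemSpec(
        regulator=fp.RegulatorSpec(k=20.0),
        regulation=fp.RegulationSpec(sign="activator", alpha=0.0, K=15.0, H=1.0),
        x_star=15,
        t_star=1.0,
    )


@pytest.fixture
def repressor_h1():
    """Diminishing repressor with N = 15, mu t* = 2.75, K = 2.6, H = 1."""
    return fp.SystemSpec(
        regulator=fp.RegulatorSpec(mu=2.75, n0=15),
        regulation=fp.RegulationSpec(sign="repressor", alpha=0.0, K=2.6, H=1.0),
        x_star=15,
        t_star=1.0,
    )


@pytest.fixture
def activator_h3():
    """Cooperative activator (H = 3) at K = 10, k t* = 20."""
    return fp.SystemSpec(
        regulator=fp.RegulatorSpec(k=20.0),
        regulation=fp.RegulationSpec(sign="activator", alpha=0.0, K=10.0, H=3.0),
        x_star=15,
        t_star=1.0,
    )


@pytest.fixture
def step_activator():
    """Step-limit (H -> inf) activator, switch at K = 10 with k t* = 20."""
    return fp.SystemSpec(
        regulator=fp.RegulatorSpec(k=20.0),
        regulation=fp.RegulationSpec(sign="activator", alpha=0.0, K=10.0, H=math.inf),
        x_star=15,
        t_star=1.0,
    )
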