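import pytest

from plaqueswitch import ReducedParams, baseline_dimensional, baseline_dimensionless


@pytest.fixture(scope="session")
def p_dim():
    return baseline_dimensional()


@pytest.fixture(scope="session")
def p_base():
    return baseline_dimensionless()


@pytest.fixture(scope="session")
def rp():
    """Reduced submodel at the reference uptake rate Pi_c = 3."""
    return ReducedParams(Pi_c=3.0)
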