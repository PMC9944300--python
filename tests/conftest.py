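import pytest

from invbleb import reference_params
from invbleb.params import mmhg_to_pressure


@pytest.fixture(scope="session")
def ref():
    """Reference parameter set (R0=10, d=10, eps*=0.5, a=0.25, ...)."""
    return reference_params()


@pytest.fixture(scope="session")
def mm():
    """mmHg -> pN/um^2 converter."""
    return mmhg_to_pressure
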