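import pytest

from lungcea.parameters import load_parameter_set


@pytest.fixture(scope="session")
def base_params():
    """Packaged default parameter set (session-wide, treat as read-only)."""
    return load_parameter_set()


@pytest.fixture()
def params(base_params):
    """Mutable copy of the defaults for tests that substitute values."""
    return base_params.copy()
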