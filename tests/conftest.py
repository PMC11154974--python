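import pytest

from strokecea import load_parameters


@pytest.fixture(scope="session")
def base_params():
    """The bundled base-case parameter set (session-wide, read-only)."""
    return load_parameters()


@pytest.fixture()
def params(base_params):
    """A fresh mutable copy of the base-case parameters."""
    return base_params.copy()
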