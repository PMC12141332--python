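import pytest

from hearscreen.lifetable import default_life_table
from hearscreen.params import load_parameters


@pytest.fixture(scope="session")
def params():
    """The bundled baseline parameter set."""
    return load_parameters()


@pytest.fixture(scope="session")
def life_table():
    """The bundled calibrated life table fixture."""
    return default_life_table()
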