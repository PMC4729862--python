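import pytest

from tarpgate import balanced_scheme


@pytest.fixture(scope="session")
def no_tarp_wt():
    """Balanced TARP-less scheme at the wild-type proxy trial."""
    return balanced_scheme("noTARP", 7)


@pytest.fixture(scope="session")
def tarp_wt():
    """Balanced TARP scheme at the wild-type proxy trial."""
    return balanced_scheme("TARP", 7)


@pytest.fixture(scope="session")
def tarp_default():
    """Balanced TARP scheme at the published baseline rates (no trial)."""
    return balanced_scheme("TARP")
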