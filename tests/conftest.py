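import pytest

from lipospin.types import MembraneComposition


@pytest.fixture
def dmpc():
    return MembraneComposition("DMPC")


@pytest.fixture
def seeds():
    """Fixed seed list for multi-replicate statistical checks."""
    return list(range(50))
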