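import pytest

from _helpers import ring_molecule


@pytest.fixture
def benzene():
    return ring_molecule(6)


@pytest.fixture
def five_ring():
    """All-aromatic 5-cycle: odd total deficiency, no Kekule structure."""
    return ring_molecule(5)
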