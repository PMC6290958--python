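import numpy as np
import pytest

from npm1mrd import load_default_catalog, load_default_reference


@pytest.fixture(scope="session")
def ref():
    return load_default_reference()


@pytest.fixture(scope="session")
def catalog(ref):
    return load_default_catalog(ref)


@pytest.fixture(scope="session")
def type_a(catalog):
    return catalog.spec_for("type A")


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


class TinyRef:
    """Minimal reference stand-in for aligner oracle tests on short sequences
    (the packaged AmpliconReference enforces realistic amplicon lengths)."""

    def __init__(self, sequence, hotspot=None):
        self.sequence = sequence
        self.hotspot = hotspot or (0, len(sequence))
        self.coding_offset = 1
        self.name = "tiny"

    def __len__(self):
        return len(self.sequence)

    def in_hotspot(self, position0):
        return self.hotspot[0] <= position0 < self.hotspot[1]


@pytest.fixture
def tiny_ref_factory():
    return TinyRef
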