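import numpy as np
import pytest

from mitovar.fixtures import synthetic_reference
from mitovar.reference import MitoReference


@pytest.fixture(scope="session")
def ref():
    """Session-wide synthetic mitochondrial-sized reference (16,569 bp)."""
    return synthetic_reference()


@pytest.fixture(scope="session")
def tiny_ref():
    return MitoReference(sequence="ACGTACGTAA", name="tiny")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
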