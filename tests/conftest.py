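import numpy as np
import pytest

from recseq.genome import build_reference, default_genome_spec
from recseq.readproc import GenomeIndex


@pytest.fixture(scope="session")
def reference():
    return build_reference(default_genome_spec(0))


@pytest.fixture(scope="session")
def genome_index(reference):
    return GenomeIndex(reference)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
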