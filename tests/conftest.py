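import numpy as np
import pytest

from msatpair.ssr_scan import GenomeSequence
from msatpair.synthetic_data import _random_bases


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def background(rng):
    """1 kb of i.i.d. background at GC 0.5."""
    return _random_bases(rng, 1000, 0.5)


def make_seq(seq_id: str, s: str) -> GenomeSequence:
    return GenomeSequence(seq_id, s)
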