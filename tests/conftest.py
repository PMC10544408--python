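import numpy as np
import pytest
from hypothesis import settings

from mbenrich.counts import CountTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """A 20-sequence two-condition table with strictly positive counts."""
    letters = "ACDEFGHIKLMNPQRSTVWY"
    seqs = []
    while len(seqs) < 20:
        s = "".join(letters[i] for i in rng.integers(0, 20, 3))
        if s not in seqs:
            seqs.append(s)
    counts = rng.integers(1, 30, size=(20, 2))
    return CountTable(seqs, counts, alphabet="protein")


def random_protein_seqs(rng, n, L, unique=True):
    letters = "ACDEFGHIKLMNPQRSTVWY"
    out = []
    seen = set()
    while len(out) < n:
        s = "".join(letters[i] for i in rng.integers(0, 20, L))
        if unique and s in seen:
            continue
        seen.add(s)
        out.append(s)
    return out
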