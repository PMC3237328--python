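import numpy as np
import pytest

from comap.alignment import Alignment


def make_alignment(rows, target_index=0, ids=None):
    if ids is None:
        ids = [f"s{k}" for k in range(len(rows))]
    return Alignment(ids=ids, rows=list(rows), target_index=target_index)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_column_alignment():
    """21000 sequences, one column, each of the 21 symbols 1000 times."""
    from comap.alignment import ALPHABET

    rows = [c for c in ALPHABET for _ in range(1000)]
    return make_alignment(rows, target_index=0)
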