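import numpy as np
import pytest

from bnmiss import CategoricalTable, DirectedNetwork


def make_table(codes, names=None, n_levels=None, mask=None):
    """Small helper: build a table from a code matrix."""
    codes = np.asarray(codes)
    p = codes.shape[1]
    names = names or [chr(ord("A") + j) for j in range(p)]
    if n_levels is None:
        n_levels = [int(codes[:, j].max()) + 1 for j in range(p)]
    elif np.isscalar(n_levels):
        n_levels = [n_levels] * p
    levels = {n: [str(i) for i in range(k)] for n, k in zip(names, n_levels)}
    return CategoricalTable(names, levels, codes, mask)


@pytest.fixture
def toy_table():
    return make_table([[0, 1], [1, 0], [2, 1]], n_levels=[3, 2])


@pytest.fixture
def chain_net():
    """A -> B -> C over binary variables."""
    levels = {n: ["0", "1"] for n in "ABC"}
    return DirectedNetwork("ABC", {("A", "B"), ("B", "C")}, levels)
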