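import itertools

import numpy as np
import pytest

from mosaweak.matrix_io import CharacterMatrix, CharacterSettings, parse_tnt
from mosaweak.tree import Tree


@pytest.fixture
def toy_matrix():
    return parse_tnt("xread 3 4 A 010 B 011 C 110 D 1?0 ;")


@pytest.fixture
def quartet():
    return Tree.from_newick("((A,B),(C,D));")


def random_binary_matrix(rng, n_taxa, n_char, k=2):
    taxa = [chr(65 + i) for i in range(n_taxa)]
    cells = [[frozenset([int(rng.integers(k))]) for _ in range(n_char)]
             for _ in range(n_taxa)]
    return CharacterMatrix(taxa=taxa, cells=cells, n_char=n_char,
                           state_count=[k] * n_char)


def random_column_matrix(rng, n_taxa, k, allow_ambiguity=True):
    """Single-character matrix with optional multi-state cells."""
    taxa = [chr(65 + i) for i in range(n_taxa)]
    cells = []
    for _ in range(n_taxa):
        if allow_ambiguity:
            size = int(rng.integers(1, 3))
        else:
            size = 1
        states = rng.choice(k, size=size, replace=False)
        cells.append([frozenset(int(s) for s in states)])
    return CharacterMatrix(taxa=taxa, cells=cells, n_char=1, state_count=[k])


def brute_force_char_steps(tree, matrix, char0, ordered):
    """Minimum steps by enumerating every internal-state assignment."""
    k = matrix.state_count[char0]
    idx = {t: i for i, t in enumerate(matrix.taxa)}
    nodes = list(tree.postorder())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    cost = (lambda a, b: abs(a - b)) if ordered else (lambda a, b: int(a != b))
    best = float("inf")
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = {id(nd): s for nd, s in zip(internal, assign)}
        total = 0
        for nd in nodes:
            if nd.parent is None:
                continue
            b = st[id(nd.parent)]
            if nd.is_leaf():
                cell = matrix.cells[idx[nd.label]][char0]
                total += min(cost(a, b) for a in cell)
            else:
                total += cost(st[id(nd)], b)
        best = min(best, total)
    return best
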