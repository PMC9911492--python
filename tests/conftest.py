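import numpy as np
import pytest

import flatrank as fr
from flatrank import trees


@pytest.fixture
def quartet():
    """The six-vertex unrooted four-taxon tree ((1,2),(3,4))."""
    return fr.parse_newick("((1,2),(3,4));")


@pytest.fixture
def star4():
    """Four leaves on a single degree-four hub."""
    return fr.parse_newick("(a1,a2,b1,b2);")


@pytest.fixture
def caterpillar6():
    return fr.parse_newick("(((1,2),3),(4,(5,6)));")


def random_disjoint_vertex_subsets(tree, rng, max_part=3, leaves_only=False):
    """Seeded disjoint (A, B) with sizes in 1..max_part."""
    pool = tree.leaves() if leaves_only else tree.vertices
    size_a = int(rng.integers(1, max_part + 1))
    size_b = int(rng.integers(1, max_part + 1))
    total = min(size_a + size_b, len(pool))
    size_a = min(size_a, total - 1) or 1
    picks = [pool[i] for i in rng.permutation(len(pool))[:total]]
    return picks[:size_a], picks[size_a:]
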