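import numpy as np
import pytest

from netsi import BinaryNetwork, CommunityPartition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_cliques(size: int = 5) -> BinaryNetwork:
    """Two disconnected cliques of the given size."""
    from itertools import combinations

    edges = [
        (i, j)
        for block in (range(size), range(size, 2 * size))
        for i, j in combinations(block, 2)
    ]
    return BinaryNetwork(2 * size, np.array(edges), float(size - 1))


def random_network(n: int, p: float, rng: np.random.Generator) -> BinaryNetwork:
    A = np.triu(rng.random((n, n)) < p, 1)
    edges = np.argwhere(A)
    return BinaryNetwork(n, edges, 2.0 * len(edges) / n)


def enumerate_partitions(items):
    """All set partitions of a sequence (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in enumerate_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def partition_from_blocks(blocks, n) -> CommunityPartition:
    labels = np.empty(n, dtype=np.int64)
    for c, blk in enumerate(blocks):
        labels[list(blk)] = c
    return CommunityPartition(labels)
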