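"""Shared fixtures: the worked coding example and small tree/matrix helpers."""

from __future__ import annotations

import numpy as np
import pytest

from cognet.coding import to_binary_matrix
from cognet.distance import hamming_distances
from cognet.tree import PhyloTree
from cognet.wordlist import read_wordlist

# Worked coding example: seven manual alphabets coding the concept
# "g" into three cognate classes (4, 60, 328); two sources are dated.
WORKED_EXAMPLE_TSV = """\
ID\tDOCULECT\tCONCEPT\tNARROW_CONCEPT\tYEAR\tFORM\tCOGID
1\tAfghan SL\tg\tgaf\t\th328\t328
2\tBrazilian 1875\tg\tg\t1875\th60\t60
3\tFrench SL\tg\tg\t\th60\t60
4\tPakistan SL\tg\tgaf\t\th60\t60
5\tGreek SL\tg\tgamma\t\th4\t4
6\tRussian 1835\tg\tGamma\t1835\th4\t4
7\tRussian SL\tg\tGamma\t\th4\t4
"""

GROUP_RUSSIAN = frozenset({"Greek SL", "Russian 1835", "Russian SL"})
GROUP_FRENCH = frozenset({"Brazilian 1875", "French SL", "Pakistan SL"})


@pytest.fixture(scope="session")
def example_wordlist():
    return read_wordlist(WORKED_EXAMPLE_TSV)


@pytest.fixture(scope="session")
def example_matrix(example_wordlist):
    return to_binary_matrix(example_wordlist, missing_policy="zero")


@pytest.fixture(scope="session")
def example_distances(example_matrix):
    return hamming_distances(example_matrix, normalize=True)


def random_binary_tree(
    n: int, rng: np.random.Generator, blen=(0.1, 1.0), prefix: str = "T"
) -> PhyloTree:
    """Random unrooted binary tree with uniform branch lengths (a tree
    metric generator for consistency tests)."""
    t = PhyloTree()
    nodes = [t.new_node(f"{prefix}{i}") for i in range(n)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        u = t.new_node()
        t.add_edge(u, nodes[i], float(rng.uniform(*blen)))
        t.add_edge(u, nodes[j], float(rng.uniform(*blen)))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [u]
    t.add_edge(nodes[0], nodes[1], float(rng.uniform(*blen)))
    return t


def caterpillar(names, blen: float = 1.0) -> PhyloTree:
    """Caterpillar (ladder) tree over the given leaf names, in order."""
    t = PhyloTree()
    leaves = [t.new_node(n) for n in names]
    spine = [t.new_node() for _ in range(len(names) - 2)]
    t.add_edge(leaves[0], spine[0], blen)
    t.add_edge(leaves[1], spine[0], blen)
    for i in range(1, len(spine)):
        t.add_edge(spine[i - 1], spine[i], blen)
        t.add_edge(leaves[i + 1], spine[i], blen)
    t.add_edge(leaves[-1], spine[-1], blen)
    return t


def all_topologies(names) -> list[PhyloTree]:
    """Every unrooted binary topology over the names (exhaustive oracle).

    Built by recursive leaf insertion: 3 taxa -> 1 topology, 4 -> 3,
    5 -> 15, 6 -> 105.
    """
    base = PhyloTree()
    center = base.new_node()
    for name in names[:3]:
        base.add_edge(base.new_node(name), center)
    trees = [base]
    for name in names[3:]:
        nxt = []
        for t in trees:
            for (u, v) in t.edges():
                t2 = t.copy()
                w = t2.new_node()
                t2.remove_edge(u, v)
                t2.add_edge(w, u)
                t2.add_edge(w, v)
                t2.add_edge(w, t2.new_node(name))
                nxt.append(t2)
        trees = nxt
    return trees
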