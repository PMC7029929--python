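"""Distance- and parsimony-based tree inference.

Implements the two agglomerative distance methods used for bootstrap
replicate trees -- classical neighbor joining and its variance-weighted
refinement BioNJ -- plus small-parsimony scoring (Hartigan's generalization
of the Fitch algorithm, exact on multifurcating trees) and a deliberately
light parsimony tree search (seeded stepwise addition followed by one
nearest-neighbor-interchange pass) for "quick and dirty" parsimony
bootstrapping, where exactly one tree is kept per pseudo-replicate.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .coding import MISSING, BinaryMatrix
from .distance import DistanceMatrix, hamming_distances
from .errors import SizeError, ValidationError
from .tree import PhyloTree


# ---------------------------------------------------------------------------
# Neighbor joining / BioNJ
# ---------------------------------------------------------------------------


def _argmin_pair(Q: np.ndarray) -> tuple[int, int]:
    """Lowest (row, column) pair attaining the minimum of the upper triangle."""
    m = Q.shape[0]
    iu = np.triu_indices(m, k=1)
    k = int(np.argmin(Q[iu]))  # row-major => lowest index pair on ties
    return int(iu[0][k]), int(iu[1][k])


def _agglomerate(dm: DistanceMatrix, variance_weighted: bool) -> PhyloTree:
    n = dm.n
    if n < 3:
        raise SizeError(f"need >= 3 taxa, got {n}")
    t = PhyloTree()
    nodes = [t.new_node(name) for name in dm.taxa]
    D = dm.d.copy()
    V = D.copy() if variance_weighted else None

    while len(nodes) > 3:
        m = len(nodes)
        R = D.sum(axis=1)
        Q = (m - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = _argmin_pair(Q)

        dij = D[i, j]
        bi = 0.5 * dij + (R[i] - R[j]) / (2.0 * (m - 2))
        bj = dij - bi
        u = t.new_node()
        t.add_edge(u, nodes[i], max(bi, 0.0))
        t.add_edge(u, nodes[j], max(bj, 0.0))

        if variance_weighted:
            vij = V[i, j]
            if vij > 1e-12:
                mask = np.ones(m, dtype=bool)
                mask[[i, j]] = False
                lam = 0.5 + float(np.sum(V[j, mask] - V[i, mask])) / (
                    2.0 * (m - 2) * vij
                )
                lam = min(1.0, max(0.0, lam))
            else:
                lam = 0.5
            dnew = lam * D[i, :] + (1 - lam) * D[j, :] - lam * bi - (1 - lam) * bj
            vnew = lam * V[i, :] + (1 - lam) * V[j, :] - lam * (1 - lam) * vij
        else:
            dnew = 0.5 * (D[i, :] + D[j, :] - dij)
            vnew = None

        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.empty((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = dnew[keep]
        newD[:-1, -1] = dnew[keep]
        newD[-1, -1] = 0.0
        D = newD
        if variance_weighted:
            newV = np.empty((m - 1, m - 1))
            newV[:-1, :-1] = V[np.ix_(keep, keep)]
            newV[-1, :-1] = vnew[keep]
            newV[:-1, -1] = vnew[keep]
            newV[-1, -1] = 0.0
            V = newV
        nodes = [nodes[k] for k in keep] + [u]

    # final three nodes join at a central vertex (closed form)
    c = t.new_node()
    b0 = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    b1 = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    b2 = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, b in zip(nodes, (b0, b1, b2)):
        t.add_edge(c, node, max(b, 0.0))
    return t


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classical NJ (Saitou-Nei / Studier-Keppler form of the Q criterion).

    Ties in the Q criterion break toward the lowest (row, column) index
    pair; negative estimated branch lengths are clamped to 0 (splits cannot
    carry negative weight downstream).  On additive input the generating
    topology and branch lengths are recovered exactly.
    """
    return _agglomerate(dm, variance_weighted=False)


def bionj(dm: DistanceMatrix) -> PhyloTree:
    """BioNJ: NJ with variance-weighted distance reduction.

    Each agglomeration mixes the two reduced rows with the weight ``lambda``
    that minimizes the variance of the reduced distances (clamped to
    [0, 1]); variances are reduced alongside.  Selection, tie-breaking and
    clamping are as in :func:`neighbor_joining`; on additive input the
    topology coincides with NJ for every lambda.
    """
    return _agglomerate(dm, variance_weighted=True)


# ---------------------------------------------------------------------------
# Small parsimony (Hartigan / Fitch)
# ---------------------------------------------------------------------------


def fitch_length(t: PhyloTree, states: dict) -> int:
    """Minimum number of state changes of one multistate character on ``t``.

    ``states`` maps each leaf name to a state label or to a set of labels
    (ambiguity, e.g. coded variants).  Uses Hartigan's count-based upward
    pass, which computes the exact unit-cost parsimony score on arbitrarily
    multifurcating trees and is invariant under the rooting chosen here.

    Raises
    ------
    ValidationError
        If some leaf has no state.
    """
    leaves = t.leaves
    for u in leaves:
        if t.name_of(u) not in states:
            raise ValidationError(f"leaf {t.name_of(u)!r} has no state")
    if len(leaves) <= 1:
        return 0

    def leaf_set(u):
        s = states[t.name_of(u)]
        if isinstance(s, (set, frozenset)):
            return frozenset(s)
        return frozenset([s])

    if len(t.nodes) == 2:
        a, b = leaves
        return 0 if leaf_set(a) & leaf_set(b) else 1

    root = next(u for u in sorted(t.nodes) if u not in set(leaves))
    cost = 0
    up: dict[int, frozenset] = {}
    stack = [(root, None, False)]
    while stack:
        node, parent, done = stack.pop()
        children = [v for v in sorted(t.neighbors(node)) if v != parent]
        if not children:
            up[node] = leaf_set(node)
            continue
        if not done:
            stack.append((node, parent, True))
            for c in children:
                stack.append((c, node, False))
            continue
        counts: dict = {}
        for c in children:
            for s in up[c]:
                counts[s] = counts.get(s, 0) + 1
        if node in set(leaves):  # only possible if a named node were internal
            for s in leaf_set(node):
                counts[s] = counts.get(s, 0) + 1
        k = max(counts.values())
        cost += len(children) - k
        up[node] = frozenset(s for s, c in counts.items() if c == k)
    return cost


# ---------------------------------------------------------------------------
# Vectorized binary Fitch + quick parsimony search
# ---------------------------------------------------------------------------


def _leaf_masks(m: BinaryMatrix) -> dict[int, np.ndarray]:
    """Bit-mask encoding per taxon row: 0 -> bit0, 1 -> bit1, missing -> both."""
    masks = {}
    for i in range(m.n_taxa):
        row = m.cells[i]
        mask = np.where(row == 1, 2, 1).astype(np.uint8)
        mask[row == MISSING] = 3
        masks[i] = mask
    return masks


def _fitch_total(t: PhyloTree, masks_by_name: dict[str, np.ndarray]) -> int:
    """Total Fitch length over all characters of a binary matrix.

    ``t`` must be unrooted-binary (internal degree 3); it is rooted at its
    lowest-numbered leaf so every internal node has exactly two children,
    where the classical intersection/union pass is exact.
    """
    leaves = sorted(u for u in t.leaves if t.degree(u) > 0)
    root = leaves[0]
    nchar = len(next(iter(masks_by_name.values())))
    events = np.zeros(nchar, dtype=np.int64)
    down: dict[int, np.ndarray] = {}
    order: list[tuple[int, Optional[int]]] = []
    stack: list[tuple[int, Optional[int]]] = [(root, None)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for v in sorted(t.neighbors(node)):
            if v != parent:
                stack.append((v, node))
    leafset = set(leaves)
    for node, parent in reversed(order):
        if node in leafset:
            down[node] = masks_by_name[t.name_of(node)]
            continue
        children = [v for v in sorted(t.neighbors(node)) if v != parent]
        acc = down[children[0]]
        for c in children[1:]:
            inter = acc & down[c]
            empty = inter == 0
            events += empty
            acc = np.where(empty, acc | down[c], inter)
        down[node] = acc
    # fold the root leaf's own state in
    child = next(v for v in t.neighbors(root))
    inter = down[child] & masks_by_name[t.name_of(root)]
    events += inter == 0
    return int(events.sum())


def matrix_parsimony_length(t: PhyloTree, m: BinaryMatrix) -> int:
    """Parsimony length of a binary matrix on an unrooted binary tree."""
    masks = _leaf_masks(m)
    by_name = {m.taxa[i]: masks[i] for i in range(m.n_taxa)}
    return _fitch_total(t, by_name)


def _attach(t: PhyloTree, u: int, v: int, leaf: int) -> int:
    """Subdivide edge (u, v) with a new internal node carrying ``leaf``."""
    t.remove_edge(u, v)
    w = t.new_node()
    t.add_edge(w, u)
    t.add_edge(w, v)
    t.add_edge(w, leaf)
    return w

def _detach(t: PhyloTree, w: int, u: int, v: int, leaf: int) -> None:
    t.remove_edge(w, leaf)
    t.remove_node(w)
    t.add_edge(u, v)


def quick_mp_tree(m: BinaryMatrix, seed: int) -> PhyloTree:
    """One parsimony tree by seeded stepwise addition plus one NNI pass.

    Taxa are added in a seeded random order, each placed on the edge that
    minimizes the total Fitch length (ties -> first edge in deterministic
    enumeration order); a single sweep of nearest-neighbor interchanges over
    the internal edges then accepts strictly improving swaps.  Exactly one
    tree is returned and the result is a deterministic function of
    (matrix, seed).  Branch lengths are not estimated.
    """
    n = m.n_taxa
    if n < 4:
        raise SizeError(f"need >= 4 taxa for a parsimony search, got {n}")
    rng = np.random.default_rng(seed)
    order = [int(i) for i in rng.permutation(n)]
    masks = _leaf_masks(m)

    t = PhyloTree()
    leaf_node = {i: t.new_node(m.taxa[i]) for i in range(n)}
    by_name = {m.taxa[i]: masks[i] for i in range(n)}
    center = t.new_node()
    for i in order[:3]:
        t.add_edge(center, leaf_node[i])

    for i in order[3:]:
        leaf = leaf_node[i]
        best = None
        best_edge = None
        for (u, v) in t.edges():
            w = _attach(t, u, v, leaf)
            score = _fitch_total(t, by_name)
            _detach(t, w, u, v, leaf)
            if best is None or score < best:
                best = score
                best_edge = (u, v)
        _attach(t, best_edge[0], best_edge[1], leaf)

    # one NNI sweep
    current = _fitch_total(t, by_name)
    for (u, v) in t.internal_edges():
        if v not in t.neighbors(u):
            continue  # edge vanished in an earlier swap
        au = [x for x in sorted(t.neighbors(u)) if x != v]
        bv = [x for x in sorted(t.neighbors(v)) if x != u]
        if len(au) != 2 or len(bv) != 2:
            continue
        candidates = []
        for b in bv:
            alt = t.copy()
            alt.remove_edge(u, au[1])
            alt.remove_edge(v, b)
            alt.add_edge(u, b)
            alt.add_edge(v, au[1])
            candidates.append((_fitch_total(alt, by_name), alt))
        score, alt = min(candidates, key=lambda p: p[0])
        if score < current:
            t = alt
            current = score
    return t


def distance_tree(
    m: BinaryMatrix, method: str = "nj", normalize: bool = True
) -> PhyloTree:
    """Convenience: Hamming distances then NJ or BioNJ."""
    dm = hamming_distances(m, normalize=normalize)
    if method == "nj":
        return neighbor_joining(dm)
    if method == "bionj":
        return bionj(dm)
    raise ValueError(f"unknown distance method {method!r}")


__all__ = [
    "neighbor_joining",
    "bionj",
    "fitch_length",
    "matrix_parsimony_length",
    "quick_mp_tree",
    "distance_tree",
]
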