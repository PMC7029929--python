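"""Unrooted phylogenetic trees.

A light adjacency-based container tuned for the algorithmic work in this
package (agglomeration, NNI rearrangement, split extraction) rather than for
rich annotation.  Leaves carry taxon names; internal nodes are anonymous and
must have degree >= 3 (degree-2 nodes are suppressed on construction paths
that can create them).  Branch lengths are optional -- parsimony trees have
none.
"""

from __future__ import annotations

from typing import Iterable, Optional

import dendropy

from .errors import SizeError, ValidationError
from .splits import Split


class PhyloTree:
    """Unrooted tree over named leaves with optional branch lengths."""

    def __init__(self):
        self._adj: dict[int, dict[int, Optional[float]]] = {}
        self._leaf_name: dict[int, str] = {}
        self._next_id = 0

    # -- construction -----------------------------------------------------

    def new_node(self, name: Optional[str] = None) -> int:
        node = self._next_id
        self._next_id += 1
        self._adj[node] = {}
        if name is not None:
            self._leaf_name[node] = name
        return node

    def add_edge(self, u: int, v: int, length: Optional[float] = None) -> None:
        if u == v:
            raise ValidationError("self-loop")
        self._adj[u][v] = length
        self._adj[v][u] = length

    def remove_edge(self, u: int, v: int) -> None:
        del self._adj[u][v]
        del self._adj[v][u]

    def remove_node(self, u: int) -> None:
        for v in list(self._adj[u]):
            self.remove_edge(u, v)
        del self._adj[u]
        self._leaf_name.pop(u, None)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[int, int, Optional[float]]],
        leaf_names: dict[int, str],
    ) -> "PhyloTree":
        t = cls()
        nodes = {u for e in edges for u in e[:2]}
        remap = {}
        for node in sorted(nodes):
            remap[node] = t.new_node(leaf_names.get(node))
        for u, v, length in edges:
            t.add_edge(remap[u], remap[v], length)
        return t

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t._adj = {u: dict(nbrs) for u, nbrs in self._adj.items()}
        t._leaf_name = dict(self._leaf_name)
        t._next_id = self._next_id
        return t

    # -- basic queries -----------------------------------------------------

    @property
    def nodes(self) -> list[int]:
        return list(self._adj)

    @property
    def leaves(self) -> list[int]:
        return [u for u in self._adj if u in self._leaf_name]

    @property
    def taxa(self) -> list[str]:
        return [self._leaf_name[u] for u in sorted(self.leaves)]

    def name_of(self, node: int) -> str:
        return self._leaf_name[node]

    def leaf_node(self, name: str) -> int:
        for u, nm in self._leaf_name.items():
            if nm == name:
                return u
        raise KeyError(name)

    def degree(self, u: int) -> int:
        return len(self._adj[u])

    def neighbors(self, u: int) -> list[int]:
        return list(self._adj[u])

    def edge_length(self, u: int, v: int) -> Optional[float]:
        return self._adj[u][v]

    def set_edge_length(self, u: int, v: int, length: Optional[float]) -> None:
        self._adj[u][v] = length
        self._adj[v][u] = length

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in sorted(self._adj) for v in sorted(self._adj[u]) if u < v]

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v)
            for (u, v) in self.edges()
            if u not in self._leaf_name and v not in self._leaf_name
        ]

    def validate(self) -> None:
        """Check leaf/internal degree contracts."""
        for u in self._adj:
            deg = self.degree(u)
            if u in self._leaf_name:
                if deg > 1:
                    raise ValidationError(f"leaf {self._leaf_name[u]!r} has degree {deg}")
            elif deg == 2 and len(self._adj) > 2:
                raise ValidationError(f"internal node {u} has degree 2")

    # -- structure edits ---------------------------------------------------

    def suppress_degree_two(self) -> None:
        """Splice out internal degree-2 nodes, summing branch lengths."""
        changed = True
        while changed:
            changed = False
            for u in list(self._adj):
                if u in self._leaf_name or u not in self._adj:
                    continue
                if self.degree(u) == 2:
                    (a, la), (b, lb) = list(self._adj[u].items())
                    length = None if (la is None and lb is None) else (la or 0.0) + (lb or 0.0)
                    self.remove_node(u)
                    self.add_edge(a, b, length)
                    changed = True

    def prune_to(self, names: Iterable[str]) -> "PhyloTree":
        """Restriction of the tree to a subset of its taxa."""
        keep = set(names)
        t = self.copy()
        # iteratively strip unwanted leaves and resulting stubs
        changed = True
        while changed:
            changed = False
            for u in list(t._adj):
                if u not in t._adj:
                    continue
                deg = t.degree(u)
                if u in t._leaf_name and t._leaf_name[u] not in keep:
                    t.remove_node(u)
                    changed = True
                elif u not in t._leaf_name and deg <= 1:
                    t.remove_node(u)
                    changed = True
        t.suppress_degree_two()
        return t

    # -- splits ------------------------------------------------------------

    def side_of(self, u: int, v: int) -> frozenset:
        """Taxa on the *u* side of edge (u, v)."""
        seen = {v, u}
        stack = [u]
        names = []
        while stack:
            x = stack.pop()
            if x in self._leaf_name:
                names.append(self._leaf_name[x])
            for y in self._adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(names)

    def splits(self, include_trivial: bool = False) -> set[Split]:
        """Bipartitions induced by the edges (weights = branch lengths)."""
        universe = frozenset(self._leaf_name.values())
        out = set()
        for (u, v) in self.edges():
            side = self.side_of(u, v)
            if not side or side == universe:
                continue
            s = Split(
                side_a=side,
                side_b=universe - side,
                weight=self._adj[u][v] or 0.0,
            )
            if include_trivial or not s.is_trivial:
                out.add(s)
        return out

    # -- metrics -----------------------------------------------------------

    def distance_matrix(self):
        """Leaf-to-leaf path-length matrix (requires branch lengths)."""
        import numpy as np

        from .distance import DistanceMatrix

        leaves = sorted(self.leaves)
        names = [self._leaf_name[u] for u in leaves]
        index = {u: i for i, u in enumerate(leaves)}
        n = len(leaves)
        d = np.zeros((n, n))
        for src in leaves:
            dist = {src: 0.0}
            stack = [src]
            while stack:
                x = stack.pop()
                for y, length in self._adj[x].items():
                    if y not in dist:
                        dist[y] = dist[x] + (length or 0.0)
                        stack.append(y)
            for u in leaves:
                d[index[src], index[u]] = dist[u]
        d = (d + d.T) / 2.0
        return DistanceMatrix(names, d)

    # -- Newick ------------------------------------------------------------

    def _newick_label(self, name: str) -> str:
        import re

        if re.search(r"[\s'():;,\[\]]", name):
            return "'" + name.replace("'", "''") + "'"
        return name

    def to_newick(self) -> str:
        """Deterministic Newick string (10 significant digits on lengths).

        The tree is written rooted at the internal node adjacent to the
        lowest-numbered leaf (or at a leaf for 1-2 taxon trees); child order
        follows node numbering.
        """
        if not self._adj:
            raise SizeError("empty tree")
        leaves = sorted(self.leaves)
        if len(self._adj) == 1:
            return self._newick_label(self._leaf_name[leaves[0]]) + ";"
        first = leaves[0]
        root = next(iter(self._adj[first])) if len(self._adj) > 2 else first

        def fmt(length: Optional[float]) -> str:
            return "" if length is None else f":{length:.10g}"

        def write(node: int, parent: Optional[int]) -> str:
            children = [v for v in sorted(self._adj[node]) if v != parent]
            if not children:
                return self._newick_label(self._leaf_name[node])
            parts = [write(c, node) + fmt(self._adj[node][c]) for c in children]
            label = self._newick_label(self._leaf_name[node]) if node in self._leaf_name else ""
            return "(" + ",".join(parts) + ")" + label

        return write(root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse one Newick tree (via dendropy) into an unrooted tree.

        A degree-2 root (rooted binary input) is suppressed so the result
        satisfies the internal-degree contract.
        """
        dt = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        t = cls()
        mapping: dict = {}
        for node in dt.preorder_node_iter():
            name = node.taxon.label if node.taxon is not None else None
            mapping[node] = t.new_node(name)
            if node.parent_node is not None:
                t.add_edge(
                    mapping[node.parent_node], mapping[node], node.edge.length
                )
        t.suppress_degree_two()
        return t

    def __repr__(self):
        return f"PhyloTree({len(self.leaves)} leaves, {len(self._adj)} nodes)"


def tree_splits(t: PhyloTree) -> set[Split]:
    """Non-trivial bipartitions induced by a tree's internal edges."""
    return t.splits(include_trivial=False)


def write_tree_sample(trees: Iterable[PhyloTree]) -> str:
    """One Newick tree per line (interchange with external tree samplers)."""
    return "\n".join(t.to_newick() for t in trees) + "\n"


def read_tree_sample(text: str) -> list[PhyloTree]:
    return [
        PhyloTree.from_newick(line)
        for line in text.strip().splitlines()
        if line.strip()
    ]


__all__ = ["PhyloTree", "tree_splits", "write_tree_sample", "read_tree_sample"]
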