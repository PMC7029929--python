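"""Nonparametric bootstrap over characters and support consensus networks.

Characters (matrix columns) are resampled with replacement to the original
character count; each pseudo-replicate yields one tree under the chosen
optimality criterion (distance-based NJ/BioNJ, or the quick parsimony
search).  Split support is the fraction of replicate trees containing the
exact bipartition.  A *support consensus network* (CNet) keeps every split
whose bootstrap frequency reaches a cutoff; above 0.5 the retained splits
are necessarily pairwise compatible (a tree), below it the system may be
multidimensional and is deliberately left without a circular ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Literal, Optional

import numpy as np

from .coding import BinaryMatrix
from .distance import hamming_distances
from .errors import SizeError, UndefinedDistanceError, ValidationError
from .inference import bionj, neighbor_joining, quick_mp_tree
from .splits import Split, SplitSystem
from .tree import PhyloTree, tree_splits
from .util import derive_seed

logger = logging.getLogger(__name__)

Method = Literal["nj", "bionj", "mp"]


@dataclass
class TreeSample:
    """A bootstrap (or externally produced) sample of replicate trees."""

    trees: list[PhyloTree]
    method: str
    seed: Optional[int] = None
    n_skipped: int = 0

    def __post_init__(self):
        taxa = None
        for t in self.trees:
            cur = sorted(t.taxa)
            if taxa is None:
                taxa = cur
            elif cur != taxa:
                raise ValidationError("trees in a sample must share one taxon set")

    @property
    def n_reps(self) -> int:
        return len(self.trees)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.trees[0].taxa) if self.trees else []

    @classmethod
    def from_newick(cls, text: str, method: str = "external") -> "TreeSample":
        """Ingest an externally produced multi-tree Newick file (one tree per
        line), e.g. a likelihood bootstrap sample; no external tool is run."""
        from .tree import read_tree_sample

        return cls(trees=read_tree_sample(text), method=method)


def bootstrap_matrices(
    m: BinaryMatrix, n_reps: int, seed: int
) -> Iterator[BinaryMatrix]:
    """Seeded stream of column-resampled pseudo-replicate matrices."""
    if m.n_characters < 1:
        raise SizeError("need >= 1 character to resample")
    rng = np.random.default_rng(seed)
    c = m.n_characters
    for _ in range(int(n_reps)):
        yield m.resample_columns(rng.integers(0, c, size=c))


def bootstrap_trees(
    m: BinaryMatrix,
    method: Method,
    n_reps: int,
    seed: int,
    normalize: bool = True,
) -> TreeSample:
    """Bootstrap a matrix and infer one tree per pseudo-replicate.

    Each replicate draws its own seed from the master seed, so individual
    replicates can be reproduced in isolation.  Replicates whose resampled
    matrix leaves some taxon pair with no comparable character (possible
    under the ``missing`` coding policy) are skipped with a logged warning;
    the skip count is reported on the returned sample.
    """
    if method in ("nj", "bionj") and m.n_taxa < 3:
        raise SizeError("distance methods need >= 3 taxa")
    if method == "mp" and m.n_taxa < 4:
        raise SizeError("parsimony search needs >= 4 taxa")
    trees = []
    skipped = 0
    rep_seeds = [derive_seed(seed, f"{method}:rep{i}") for i in range(int(n_reps))]
    for i, rep in enumerate(bootstrap_matrices(m, n_reps, seed)):
        try:
            if method == "nj":
                trees.append(neighbor_joining(hamming_distances(rep, normalize)))
            elif method == "bionj":
                trees.append(bionj(hamming_distances(rep, normalize)))
            elif method == "mp":
                trees.append(quick_mp_tree(rep, seed=rep_seeds[i]))
            else:
                raise ValueError(f"unknown method {method!r}")
        except UndefinedDistanceError as exc:
            skipped += 1
            logger.warning("replicate %d skipped: %s", i, exc)
    return TreeSample(trees=trees, method=method, seed=seed, n_skipped=skipped)


def split_support(sample: TreeSample, s: Split) -> float:
    """Fraction of replicate trees whose splits contain the exact bipartition."""
    if not sample.trees:
        raise SizeError("empty tree sample")
    if set(sample.taxa) != set(s.taxa):
        raise ValidationError("split is not over the sample's taxon set")
    hits = sum(1 for t in sample.trees if s in tree_splits(t))
    return hits / len(sample.trees)


def consensus_network(
    sample: TreeSample,
    cutoff: float = 0.15,
    weights: Literal["frequency", "mean_length"] = "frequency",
) -> SplitSystem:
    """Support consensus network: splits at bootstrap frequency >= cutoff.

    Support and (by default) weight are the frequency; ``mean_length``
    instead averages the inducing branch lengths over the trees containing
    the split (falling back to frequency when no lengths exist, as for
    parsimony trees).  No circular ordering is claimed for the result.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValidationError(f"cutoff {cutoff} outside (0, 1]")
    if not sample.trees:
        raise SizeError("empty tree sample")
    n = len(sample.trees)
    counts: dict[frozenset, int] = {}
    lengths: dict[frozenset, list[float]] = {}
    rep: dict[frozenset, Split] = {}
    for t in sample.trees:
        for s in tree_splits(t):
            k = s.key()
            counts[k] = counts.get(k, 0) + 1
            rep.setdefault(k, s)
            if s.weight:
                lengths.setdefault(k, []).append(s.weight)
    out = []
    for k, c in sorted(
        counts.items(), key=lambda kv: (-kv[1], sorted(map(sorted, kv[0])))
    ):
        freq = c / n
        if freq < cutoff:
            continue
        if weights == "mean_length" and lengths.get(k):
            w = float(np.mean(lengths[k]))
        else:
            w = freq
        out.append(rep[k].replaced(weight=w, support=freq))
    return SplitSystem(taxa=sample.taxa, splits=out, cycle=None)


__all__ = [
    "TreeSample",
    "bootstrap_matrices",
    "bootstrap_trees",
    "split_support",
    "consensus_network",
]
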