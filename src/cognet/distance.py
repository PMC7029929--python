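"""Pairwise Hamming dissimilarities between taxa of a binary matrix."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coding import MISSING, BinaryMatrix
from .errors import SizeError, UndefinedDistanceError, ValidationError


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    taxa: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValidationError(f"distance block shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("distance matrix diagonal is not zero")
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("distance matrix has non-finite entries")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])

    def subset(self, taxa) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(list(taxa), self.d[np.ix_(idx, idx)].copy())


def hamming_distances(m: BinaryMatrix, normalize: bool = True) -> DistanceMatrix:
    """Simple (Hamming) pairwise distances from a binary character matrix.

    Missing cells are handled by pairwise deletion: only characters scored in
    *both* taxa are compared.  With ``normalize`` (the default, matching the
    convention of distance software on standard-coded characters) the
    mismatch count is divided by the number of comparable characters;
    otherwise the raw count is returned.

    Raises
    ------
    UndefinedDistanceError
        If some pair of taxa shares no comparable character.
    SizeError
        Fewer than 2 taxa or no characters.
    """
    if m.n_taxa < 2:
        raise SizeError(f"need >= 2 taxa, got {m.n_taxa}")
    if m.n_characters < 1:
        raise SizeError("need >= 1 character")
    X = m.cells
    valid = X != MISSING  # (n, c)
    # Comparable-character counts and mismatch counts via float matmuls.
    V = valid.astype(np.float64)
    comparable = V @ V.T
    ones = (X == 1).astype(np.float64)
    zeros = ((X == 0) & valid).astype(np.float64)
    mismatches = ones @ zeros.T + zeros @ ones.T

    n = m.n_taxa
    iu = np.triu_indices(n, k=1)
    bad = comparable[iu] == 0
    if np.any(bad):
        k = int(np.argmax(bad))
        i, j = int(iu[0][k]), int(iu[1][k])
        raise UndefinedDistanceError(m.taxa[i], m.taxa[j])
    if normalize:
        d = np.where(comparable > 0, mismatches / np.maximum(comparable, 1), 0.0)
    else:
        d = mismatches
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    return DistanceMatrix(list(m.taxa), d)


def write_phylip(dm: DistanceMatrix, precision: int = 10) -> str:
    """Square PHYLIP distance matrix (relaxed names: spaces become ``_``)."""
    lines = [f"{dm.n}"]
    names = [t.replace(" ", "_") for t in dm.taxa]
    width = max(10, max(len(n) for n in names) + 2)
    for i, name in enumerate(names):
        row = "  ".join(f"{v:.{precision}f}" for v in dm.d[i])
        lines.append(f"{name:<{width}}{row}")
    return "\n".join(lines) + "\n"


__all__ = ["DistanceMatrix", "hamming_distances", "write_phylip"]
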