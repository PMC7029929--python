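"""Weighted split systems (sets of taxon bipartitions) and Splits-NEXUS IO.

A *split* is a bipartition of the taxon set; every edge of an unrooted tree
induces one, and split networks generalize trees by displaying weighted
collections of possibly incompatible splits.  A split system is *circular*
when there is one circular ordering of the taxa such that every split's
sides are contiguous arcs -- exactly the class NeighborNet produces and the
class a planar splits graph can draw.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import FormatError, ValidationError


@dataclass(frozen=True)
class Split:
    """A bipartition with an optional weight and bootstrap support.

    ``side_a`` is kept as constructed (callers typically put the group of
    interest there); equality and hashing consider only the unordered
    bipartition, never weight or support.
    """

    side_a: frozenset
    side_b: frozenset
    weight: float = 0.0
    support: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "side_a", frozenset(self.side_a))
        object.__setattr__(self, "side_b", frozenset(self.side_b))
        if not self.side_a or not self.side_b:
            raise ValidationError("both sides of a split must be non-empty")
        if self.side_a & self.side_b:
            raise ValidationError("split sides overlap")
        if self.support is not None and not (0.0 <= self.support <= 1.0):
            raise ValidationError(f"support {self.support} outside [0, 1]")

    @property
    def taxa(self) -> frozenset:
        return self.side_a | self.side_b

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) == 1

    def key(self) -> frozenset:
        """Hashable identity of the bipartition (unordered pair of sides)."""
        return frozenset((self.side_a, self.side_b))

    def side_with(self, taxon) -> frozenset:
        if taxon in self.side_a:
            return self.side_a
        if taxon in self.side_b:
            return self.side_b
        raise KeyError(taxon)

    def separates(self, x, y) -> bool:
        return (x in self.side_a) != (y in self.side_a)

    def __eq__(self, other):
        if not isinstance(other, Split):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self):
        return hash(self.key())

    def replaced(self, **kw) -> "Split":
        params = dict(
            side_a=self.side_a, side_b=self.side_b, weight=self.weight,
            support=self.support,
        )
        params.update(kw)
        return Split(**params)


def compatible(s: Split, t: Split) -> bool:
    """Two splits are compatible iff some pair of opposite sides is disjoint
    (they can occur as edges of one tree)."""
    return (
        not (s.side_a & t.side_a)
        or not (s.side_a & t.side_b)
        or not (s.side_b & t.side_a)
        or not (s.side_b & t.side_b)
    )


@dataclass
class SplitSystem:
    """An ordered taxon set with a list of splits and an optional cycle.

    When ``cycle`` is present every split must be an arc of it (checked by
    :meth:`is_circular`); consensus networks legitimately omit the cycle
    since their split sets may be non-planar.
    """

    taxa: list
    splits: list[Split] = field(default_factory=list)
    cycle: Optional[list] = None

    def __post_init__(self):
        universe = frozenset(self.taxa)
        seen = set()
        for s in self.splits:
            if s.taxa != universe:
                raise ValidationError(
                    f"split {sorted(s.side_a)}|{sorted(s.side_b)} does not "
                    "cover the taxon set"
                )
            if s.key() in seen:
                raise ValidationError(f"duplicate split {sorted(s.side_a)}")
            seen.add(s.key())
        if self.cycle is not None and sorted(self.cycle) != sorted(self.taxa):
            raise ValidationError("cycle is not a permutation of the taxa")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def nontrivial(self) -> list[Split]:
        return [s for s in self.splits if not s.is_trivial]

    def find(self, side: Iterable) -> Optional[Split]:
        side = frozenset(side)
        for s in self.splits:
            if s.side_a == side or s.side_b == side:
                return s
        return None

    def is_circular(self) -> bool:
        """Exhaustively check every split is a contiguous arc of the cycle."""
        if self.cycle is None:
            return False
        pos = {t: i for i, t in enumerate(self.cycle)}
        n = len(self.cycle)
        for s in self.splits:
            side = s.side_a if len(s.side_a) <= len(s.side_b) else s.side_b
            idx = sorted(pos[t] for t in side)
            k = len(idx)
            ok = False
            for start in range(k):
                # arc starting at idx[start], wrapping around
                rot = idx[start:] + [i + n for i in idx[:start]]
                if rot[-1] - rot[0] == k - 1:
                    ok = True
                    break
            if not ok:
                return False
        return True

    def fitted_distance(self, x, y) -> float:
        return sum(s.weight for s in self.splits if s.separates(x, y))


# ---------------------------------------------------------------------------
# Splits-NEXUS IO (the format standard splits viewers read)
# ---------------------------------------------------------------------------


def _quote(label: str) -> str:
    label = str(label)
    if re.search(r"[\s'();,\[\]]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_splits_nexus(s: SplitSystem) -> str:
    """Serialize a split system in Splits-NEXUS form.

    Taxa block with 1-based TAXLABELS; Splits block with DIMENSIONS,
    FORMAT (``confidences=yes`` iff any split carries support), a CYCLE line
    when a circular ordering is recorded, and a MATRIX whose rows list each
    split's side containing taxon 1 as 1-based indices after the weight
    (and confidence).  write -> read -> write is byte-identical.
    """
    if not s.taxa:
        raise ValidationError("refusing to write an empty taxon set")
    has_conf = any(sp.support is not None for sp in s.splits)
    index = {t: i + 1 for i, t in enumerate(s.taxa)}
    first = s.taxa[0]

    lines = ["#nexus", "", "BEGIN Taxa;"]
    lines.append(f"DIMENSIONS ntax={len(s.taxa)};")
    lines.append("TAXLABELS")
    for i, t in enumerate(s.taxa, 1):
        lines.append(f"[{i}] {_quote(t)}")
    lines.append(";")
    lines.append("END; [Taxa]")
    lines.append("")
    lines.append("BEGIN Splits;")
    lines.append(f"DIMENSIONS ntax={len(s.taxa)} nsplits={len(s.splits)};")
    conf = "yes" if has_conf else "no"
    lines.append(f"FORMAT labels=no weights=yes confidences={conf};")
    if s.cycle is not None:
        lines.append("CYCLE " + " ".join(str(index[t]) for t in s.cycle) + ";")
    lines.append("MATRIX")
    for k, sp in enumerate(s.splits, 1):
        side = sp.side_with(first)
        ids = sorted(index[t] for t in side)
        row = f"[{k}, size={min(len(sp.side_a), len(sp.side_b))}]\t{sp.weight:.10g}"
        if has_conf:
            row += f"\t{0.0 if sp.support is None else sp.support:.10g}"
        row += "\t" + " ".join(str(i) for i in ids) + ","
        lines.append(row)
    lines.append(";")
    lines.append("END; [Splits]")
    return "\n".join(lines) + "\n"


def read_splits_nexus(text: str) -> SplitSystem:
    """Parse the Splits-NEXUS dialect emitted by :func:`write_splits_nexus`."""
    if not text.lstrip().lower().startswith("#nexus"):
        raise FormatError("not a NEXUS file")
    tax_m = re.search(r"TAXLABELS(.*?);", text, re.S | re.I)
    if not tax_m:
        raise FormatError("no TAXLABELS found")
    taxa = []
    for line in tax_m.group(1).strip().splitlines():
        line = re.sub(r"^\[\d+\]\s*", "", line.strip())
        if not line:
            continue
        if line.startswith("'"):
            taxa.append(line[1:-1].replace("''", "'"))
        else:
            taxa.append(line)

    has_conf = bool(
        re.search(r"confidences\s*=\s*yes", text, re.I)
    )
    cycle = None
    cyc_m = re.search(r"CYCLE\s+([\d\s]+);", text, re.I)
    if cyc_m:
        cycle = [taxa[int(i) - 1] for i in cyc_m.group(1).split()]

    mat_m = re.search(r"MATRIX(.*?);", text, re.S | re.I)
    if not mat_m:
        raise FormatError("no MATRIX found")
    universe = frozenset(taxa)
    splits = []
    for line in mat_m.group(1).strip().splitlines():
        line = line.strip().rstrip(",")
        line = re.sub(r"^\[[^\]]*\]\s*", "", line)
        if not line:
            continue
        fields = line.split()
        weight = float(fields[0])
        if has_conf:
            support: Optional[float] = float(fields[1])
            ids = [int(x) for x in fields[2:]]
        else:
            support = None
            ids = [int(x) for x in fields[1:]]
        side = frozenset(taxa[i - 1] for i in ids)
        splits.append(
            Split(side_a=side, side_b=universe - side, weight=weight, support=support)
        )
    return SplitSystem(taxa=taxa, splits=splits, cycle=cycle)


def write_splits_tsv(s: SplitSystem) -> str:
    """One split per row: side-a members (pipe-joined), weight, support."""
    lines = ["SIDE_A\tWEIGHT\tSUPPORT"]
    for sp in s.splits:
        side = sorted(sp.side_with(s.taxa[0]))
        sup = "" if sp.support is None else f"{sp.support:.6g}"
        lines.append(f"{'|'.join(map(str, side))}\t{sp.weight:.10g}\t{sup}")
    return "\n".join(lines) + "\n"


__all__ = [
    "Split",
    "SplitSystem",
    "compatible",
    "write_splits_nexus",
    "read_splits_nexus",
    "write_splits_tsv",
]
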