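"""Analysis layer: time filtering, group support tables, character mapping.

This is where the networks are interrogated: which taxa existed in a given
period, how robust each proposed group's defining split is under the
bootstrap, which concepts carry the signal for a split, and how many state
changes a concept minimally requires on a given tree (its tree-realized
median-network change count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .bootstrap import bootstrap_trees, split_support
from .coding import MISSING, BinaryMatrix, Character
from .distance import hamming_distances  # noqa: F401  (re-export convenience)
from .errors import EmptySelectionError, ValidationError
from .inference import fitch_length
from .splits import Split
from .tree import PhyloTree
from .util import derive_seed
from .wordlist import Wordlist


@dataclass(frozen=True)
class PeriodFilter:
    """Inclusive year window plus a flag for undated (contemporary) taxa.

    A taxon is kept when its year lies in [min_year, max_year] (missing
    bounds are open), or when it is undated and ``include_contemporary``.
    A taxon's year is the year of its entries (taxa are doculects: one
    source, one date).
    """

    min_year: Optional[int] = None
    max_year: Optional[int] = None
    include_contemporary: bool = True

    def __post_init__(self):
        if (
            self.min_year is not None
            and self.max_year is not None
            and self.min_year > self.max_year
        ):
            raise ValidationError("min_year > max_year")

    def admits(self, year: Optional[int]) -> bool:
        if year is None:
            return self.include_contemporary
        if self.min_year is not None and year < self.min_year:
            return False
        if self.max_year is not None and year > self.max_year:
            return False
        return True


#: Named presets for the three time windows of the stacked-network analysis:
#: everything up to 1840; later historical sources (1808 to the end of the
#: twentieth century); and the modern layer (from 1950, plus contemporary).
PERIOD_PRESETS: dict[str, PeriodFilter] = {
    "pre1840": PeriodFilter(max_year=1840, include_contemporary=False),
    "mid1808_1999": PeriodFilter(min_year=1808, max_year=1999,
                                 include_contemporary=False),
    "post1950": PeriodFilter(min_year=1950, include_contemporary=True),
}


def filter_by_period(wl: Wordlist, f: PeriodFilter) -> Wordlist:
    """Restrict a wordlist to the taxa a period filter admits.

    Raises :class:`EmptySelectionError` when nothing survives.
    """
    years: dict[str, Optional[int]] = {}
    for e in wl.entries:
        years.setdefault(e.taxon, e.year)
        if e.year is not None:
            years[e.taxon] = e.year
    keep = {t for t in wl.taxa if f.admits(years[t])}
    if not keep:
        raise EmptySelectionError(f"period filter {f} admits no taxa")
    return wl.subset_taxa(keep)


@dataclass(frozen=True)
class GroupDefinition:
    """A named candidate group (taxon subset) whose defining split is tested."""

    name: str
    members: frozenset

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValidationError(f"group {self.name!r} has no members")

    def split_against(self, taxa: Sequence[str]) -> Split:
        rest = frozenset(taxa) - self.members
        if not self.members <= frozenset(taxa):
            missing = sorted(self.members - frozenset(taxa))
            raise ValidationError(f"group {self.name!r} members not in matrix: {missing}")
        if len(self.members) < 2 or not rest:
            raise ValidationError(
                f"group {self.name!r} does not define a non-trivial split"
            )
        return Split(side_a=self.members, side_b=rest)


def read_groups(text: str) -> list[GroupDefinition]:
    """Parse the plain-text group config: ``name: taxon, taxon, ...`` per line.

    Blank lines and ``#`` comments are ignored.
    """
    groups = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValidationError(f"malformed group line (no colon): {line!r}")
        name, members = line.split(":", 1)
        groups.append(
            GroupDefinition(
                name=name.strip(),
                members=frozenset(
                    m.strip() for m in members.split(",") if m.strip()
                ),
            )
        )
    return groups


def group_support_table(
    m: BinaryMatrix,
    groups: Iterable[GroupDefinition],
    methods: Sequence[str] = ("nj", "bionj", "mp"),
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap support (percent) for each group's defining bipartition.

    One bootstrap sample is drawn per method (seed derived from the master
    seed and the method name via :func:`cognet.util.derive_seed`); every
    group's split is then scored against the same sample, so table cells are
    exactly ``100 * split_support`` for that sample.  Rows: groups; columns:
    ``members`` plus one ``BS_<method>`` column per method.
    """
    groups = list(groups)
    splits = {g.name: g.split_against(m.taxa) for g in groups}
    data: dict[str, list] = {"group": [], "members": []}
    for g in groups:
        data["group"].append(g.name)
        data["members"].append(", ".join(sorted(g.members)))
    for method in methods:
        sample = bootstrap_trees(
            m, method, n_reps=n_reps, seed=derive_seed(seed, f"bs:{method}")
        )
        data[f"BS_{method}"] = [
            100.0 * split_support(sample, splits[g.name]) for g in groups
        ]
    return pd.DataFrame(data)


def concept_support(
    m: BinaryMatrix,
    s: Split,
    mode: Literal["exact", "compatible"] = "exact",
    side: Literal["a", "either"] = "a",
) -> list[Character]:
    """Characters whose 1-scored taxa back a split.

    ``exact``: the character's 1-taxa equal the queried side (``side_a`` as
    the split was constructed -- put the group of interest there -- or
    either side with ``side="either"``), after excluding taxa whose cell is
    missing.  ``compatible``: the 1-taxa are a non-empty subset of the
    queried side.  Characters with no 1-scored taxon never support anything.
    """
    out = []
    for j, ck in enumerate(m.characters):
        col = m.cells[:, j]
        ones = {t for t, v in zip(m.taxa, col) if v == 1}
        valid = {t for t, v in zip(m.taxa, col) if v != MISSING}
        if not ones:
            continue
        sides = [s.side_a] if side == "a" else [s.side_a, s.side_b]
        for target in sides:
            target_valid = target & valid
            if mode == "exact":
                hit = ones == target_valid and bool(target_valid)
            else:
                hit = ones <= target_valid
            if hit:
                out.append(ck)
                break
    return out


def min_changes_per_concept(
    wl: Wordlist, concept: str, t: PhyloTree
) -> int:
    """Minimum number of cognate-class changes a concept needs on a tree.

    The concept's states are the CogIDs of each taxon's form(s); taxa not
    attesting the concept are pruned from the tree first.  The count is the
    exact small-parsimony (Fitch/Hartigan) score of the multistate character
    -- the tree-realized reading of a median-network change count.  A taxon
    with several coded variants contributes an ambiguous state set.
    """
    if concept not in wl.concepts:
        raise ValidationError(f"unknown concept {concept!r}")
    states: dict[str, frozenset] = {}
    for e in wl.entries:
        if e.concept == concept:
            states.setdefault(e.taxon, frozenset())
            states[e.taxon] = states[e.taxon] | {e.cogid}
    attesting = [name for name in t.taxa if name in states]
    if len(attesting) <= 1:
        return 0
    pruned = t.prune_to(attesting) if set(attesting) != set(t.taxa) else t
    return fitch_length(pruned, states)


def support_table_tsv(table: pd.DataFrame) -> str:
    """Serialize a group-support table as TSV (supports to one decimal)."""
    out = table.copy()
    for col in out.columns:
        if col.startswith("BS_"):
            out[col] = out[col].map(lambda v: f"{v:.1f}")
    return out.to_csv(sep="\t", index=False)


__all__ = [
    "PeriodFilter",
    "PERIOD_PRESETS",
    "filter_by_period",
    "GroupDefinition",
    "read_groups",
    "group_support_table",
    "concept_support",
    "min_changes_per_concept",
    "support_table_tsv",
]
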