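"""Binarization of cognate-coded wordlists and NEXUS character-matrix IO.

Each distinct (concept, CogID) pair attested anywhere in the wordlist becomes
one binary character: a taxon scores 1 when it has a form of that concept in
that cognate class, 0 when it has a form of the concept in a *different*
class.  Taxa that do not attest the concept at all score 0 under the ``zero``
policy (the convention used for standard-coded matrices, where absence is
treated as plain mismatch) or ``?`` under the ``missing`` policy (absence
carries no signal; distances then use pairwise deletion).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import FormatError, ValidationError
from .wordlist import Wordlist, validate_wordlist

#: Cell value encoding missing data in the integer matrix.
MISSING = -1

Character = tuple[str, int]  # (concept, cogid)


@dataclass
class BinaryMatrix:
    """Taxa x binary characters, cells in {1, 0, MISSING}.

    ``characters[j]`` maps column ``j`` back to its (concept, cogid)
    descriptor.  ``cells`` is an int8 array of shape (len(taxa),
    len(characters)).
    """

    taxa: list[str]
    characters: list[Character]
    cells: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.taxa), len(self.characters)):
            raise ValidationError(
                f"cell block shape {self.cells.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def row(self, taxon: str) -> np.ndarray:
        return self.cells[self.taxa.index(taxon)]

    def column(self, character: Character) -> np.ndarray:
        return self.cells[:, self.characters.index(character)]

    def ones_of(self, character: Character) -> set[str]:
        """Taxa scored 1 for the character."""
        col = self.column(character)
        return {t for t, v in zip(self.taxa, col) if v == 1}

    def resample_columns(self, indices) -> "BinaryMatrix":
        """Column-resampled copy (bootstrap pseudo-replicate); duplicate
        descriptors are kept as-is."""
        indices = np.asarray(indices, dtype=int)
        return BinaryMatrix(
            taxa=list(self.taxa),
            characters=[self.characters[i] for i in indices],
            cells=self.cells[:, indices].copy(),
        )


def to_binary_matrix(
    wl: Wordlist,
    missing_policy: Literal["zero", "missing"] = "zero",
    allow_variants: bool = False,
) -> BinaryMatrix:
    """Binarize a wordlist.

    Column order is deterministic: concepts in first-appearance order, then
    CogIDs ascending within each concept.  For every concept a taxon attests,
    exactly one of that concept's columns is 1 (unless ``allow_variants``,
    when each coded variant's column is 1).  Concepts a taxon does not attest
    are scored per ``missing_policy``.

    Raises
    ------
    ValidationError
        If the wordlist fails its hard validation rules (and
        ``allow_variants`` is not set to accept duplicate slots).
    """
    report = validate_wordlist(wl)
    if report.errors and not allow_variants:
        raise ValidationError(
            f"wordlist has {len(report.errors)} validation error(s); "
            f"first: {report.errors[0]}"
        )

    taxa = wl.taxa
    concepts = wl.concepts
    chars: list[Character] = []
    for c in concepts:
        cogids = sorted({e.cogid for e in wl.entries if e.concept == c})
        chars.extend((c, k) for k in cogids)
    char_index = {ck: j for j, ck in enumerate(chars)}
    taxon_index = {t: i for i, t in enumerate(taxa)}
    concept_cols: dict[str, list[int]] = {}
    for j, (c, _) in enumerate(chars):
        concept_cols.setdefault(c, []).append(j)

    fill = 0 if missing_policy == "zero" else MISSING
    cells = np.full((len(taxa), len(chars)), fill, dtype=np.int8)
    # Any attested concept gets its full column block set to 0 first ...
    attested = {(e.taxon, e.concept) for e in wl.entries}
    for (t, c) in attested:
        cells[taxon_index[t], concept_cols[c]] = 0
    # ... then the attested cognate classes flip to 1.
    for e in wl.entries:
        cells[taxon_index[e.taxon], char_index[(e.concept, e.cogid)]] = 1
    return BinaryMatrix(taxa=taxa, characters=chars, cells=cells)


# ---------------------------------------------------------------------------
# NEXUS characters IO
# ---------------------------------------------------------------------------

_NEEDS_QUOTE = re.compile(r"[\s'()\[\]{}/\\,;:=*\"`+<>-]")


def _nexus_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _char_label(char: Character) -> str:
    concept, cogid = char
    return f"{concept}_{cogid}"


def write_nexus_characters(m: BinaryMatrix) -> str:
    """Serialize a binary matrix as a standard-datatype NEXUS file.

    Taxa and Characters blocks; symbols "01", missing "?", no interleaving.
    Character labels encode the (concept, cogid) descriptor as
    ``<concept>_<cogid>`` so that ``read_nexus_characters`` round-trips the
    descriptor list; write -> read -> write is byte-identical.
    """
    if m.n_taxa == 0 or m.n_characters == 0:
        raise ValidationError("refusing to write an empty matrix")
    lines = ["#NEXUS", "", "BEGIN TAXA;"]
    lines.append(f"    DIMENSIONS NTAX={m.n_taxa};")
    lines.append("    TAXLABELS")
    for t in m.taxa:
        lines.append(f"        {_nexus_label(t)}")
    lines.append("    ;")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN CHARACTERS;")
    lines.append(f"    DIMENSIONS NCHAR={m.n_characters};")
    lines.append('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;')
    lines.append("    CHARSTATELABELS")
    pieces = [
        f"        {j + 1} {_nexus_label(_char_label(ck))}"
        for j, ck in enumerate(m.characters)
    ]
    lines.append(",\n".join(pieces))
    lines.append("    ;")
    lines.append("    MATRIX")
    width = max(len(_nexus_label(t)) for t in m.taxa) + 2
    for i, t in enumerate(m.taxa):
        states = "".join(
            "?" if v == MISSING else str(int(v)) for v in m.cells[i]
        )
        lines.append(f"        {_nexus_label(t):<{width}}{states}")
    lines.append("    ;")
    lines.append("END;")
    return "\n".join(lines) + "\n"


def _unquote(token: str) -> str:
    token = token.strip()
    if token.startswith("'") and token.endswith("'"):
        return token[1:-1].replace("''", "'")
    return token


def read_nexus_characters(text: str) -> BinaryMatrix:
    """Parse the NEXUS dialect emitted by :func:`write_nexus_characters`."""
    if not text.lstrip().upper().startswith("#NEXUS"):
        raise FormatError("not a NEXUS file (missing #NEXUS header)")

    taxlabels_m = re.search(r"TAXLABELS(.*?);", text, re.S | re.I)
    if not taxlabels_m:
        raise FormatError("no TAXLABELS found")
    taxa = [_unquote(tok) for tok in _tokenize(taxlabels_m.group(1))]

    chars: list[Character] = []
    csl_m = re.search(r"CHARSTATELABELS(.*?);", text, re.S | re.I)
    if csl_m:
        for piece in csl_m.group(1).split(","):
            piece = piece.strip()
            if not piece:
                continue
            _, label = piece.split(None, 1)
            label = _unquote(label)
            concept, cogid = label.rsplit("_", 1)
            chars.append((concept, int(cogid)))

    matrix_m = re.search(r"MATRIX(.*?);", text, re.S | re.I)
    if not matrix_m:
        raise FormatError("no MATRIX block found")
    rows = []
    row_taxa = []
    for line in matrix_m.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            end = line.index("'", 1)
            while line[end : end + 2] == "''":
                end = line.index("'", end + 2)
            name = _unquote(line[: end + 1])
            states = line[end + 1 :].strip()
        else:
            name, states = line.split(None, 1)
        row_taxa.append(name)
        rows.append(
            [MISSING if ch == "?" else int(ch) for ch in states.strip()]
        )
    if row_taxa != taxa:
        raise FormatError("MATRIX taxon order disagrees with TAXLABELS")
    cells = np.array(rows, dtype=np.int8)
    if not chars:
        chars = [("char", j + 1) for j in range(cells.shape[1])]
    return BinaryMatrix(taxa=taxa, characters=chars, cells=cells)


def _tokenize(blob: str) -> list[str]:
    """Split a NEXUS token list, honoring single-quoted labels."""
    tokens = []
    i, n = 0, len(blob)
    while i < n:
        ch = blob[i]
        if ch.isspace():
            i += 1
        elif ch == "'":
            j = i + 1
            while j < n:
                if blob[j] == "'" and blob[j : j + 2] != "''":
                    break
                j += 2 if blob[j] == "'" else 1
            tokens.append(blob[i : j + 1])
            i = j + 1
        else:
            j = i
            while j < n and not blob[j].isspace():
                j += 1
            tokens.append(blob[i:j])
            i = j
    return tokens


__all__ = [
    "MISSING",
    "Character",
    "BinaryMatrix",
    "to_binary_matrix",
    "write_nexus_characters",
    "read_nexus_characters",
]
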