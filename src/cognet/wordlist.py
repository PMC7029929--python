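"""Cognate-coded wordlists.

A wordlist is the tabular primary data of a comparative study: one row per
documented form, identified by a *doculect* (taxon), a *concept* (the
cross-alphabet comparison slot, e.g. letter "g"), optionally the *narrow
concept* (the grapheme actually represented), a publication *year* for
historical sources (blank = contemporary), an opaque *form* transcription,
and a *CogID* -- the numeric identifier of the similarity class the form was
assigned to.  Forms sharing a CogID within a concept are treated as cognate
and become one binary character downstream.

The on-disk format is the tab-separated, UTF-8, header-first dialect used by
EDICTOR/LingPy-style tooling; column names are configurable.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import FormatError
from .util import first_appearance_order

#: Default header names, in canonical column order.
DEFAULT_COLUMNS = {
    "id": "ID",
    "taxon": "DOCULECT",
    "concept": "CONCEPT",
    "narrow_concept": "NARROW_CONCEPT",
    "year": "YEAR",
    "form": "FORM",
    "cogid": "COGID",
}

#: Plausibility window for publication years of historical sources (CE).
YEAR_RANGE = (1500, 2100)


@dataclass(frozen=True)
class Entry:
    """One coded form: a (taxon, concept) slot filled with a CogID."""

    id: str
    taxon: str
    concept: str
    cogid: int
    narrow_concept: str = ""
    year: Optional[int] = None
    form: str = ""

    def __post_init__(self):
        if not self.taxon:
            raise ValueError(f"entry {self.id!r}: empty taxon")
        if not self.concept:
            raise ValueError(f"entry {self.id!r}: empty concept")
        if self.cogid < 1:
            raise ValueError(f"entry {self.id!r}: cogid must be >= 1, got {self.cogid}")
        if self.year is not None and not (YEAR_RANGE[0] <= self.year <= YEAR_RANGE[1]):
            raise ValueError(
                f"entry {self.id!r}: year {self.year} outside plausible range {YEAR_RANGE}"
            )

    @property
    def is_historical(self) -> bool:
        return self.year is not None


@dataclass
class Wordlist:
    """An ordered collection of entries with derived taxon/concept orders.

    ``taxa`` and ``concepts`` are exactly the distinct values occurring in
    ``entries``, in order of first appearance; they are recomputed whenever
    the entry list is replaced.
    """

    entries: list[Entry] = field(default_factory=list)

    @property
    def taxa(self) -> list[str]:
        return first_appearance_order(e.taxon for e in self.entries)

    @property
    def concepts(self) -> list[str]:
        return first_appearance_order(e.concept for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def subset_taxa(self, keep: Iterable[str]) -> "Wordlist":
        keep = set(keep)
        return Wordlist([e for e in self.entries if e.taxon in keep])

    def entries_for(self, taxon: str, concept: str) -> list[Entry]:
        return [e for e in self.entries if e.taxon == taxon and e.concept == concept]


@dataclass
class ValidationReport:
    """Outcome of the soft/hard rule checks on a wordlist.

    ``errors`` are violations of hard rules (the wordlist cannot be coded
    into a binary matrix); ``warnings`` flag suspicious but legal patterns.
    Each item is ``(entry_id, rule, message)``.
    """

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _resolve_columns(header: list[str], columns: Optional[dict] = None) -> dict:
    """Map logical field names to header indices; error on missing mandatory ones."""
    names = dict(DEFAULT_COLUMNS)
    if columns:
        names.update(columns)
    index = {}
    for fieldname, colname in names.items():
        try:
            index[fieldname] = header.index(colname)
        except ValueError:
            index[fieldname] = None
    for mandatory in ("taxon", "concept", "cogid"):
        if index[mandatory] is None:
            raise FormatError(
                f"mandatory column {names[mandatory]!r} (field {mandatory!r}) "
                f"missing from header {header}"
            )
    return index


def read_wordlist(source, columns: Optional[dict] = None) -> Wordlist:
    """Read a wordlist from TSV text, a file path, or an open text handle.

    The first row must be a header containing at least the taxon, concept and
    CogID columns (names configurable via ``columns``, a mapping from logical
    field -- ``taxon``, ``concept``, ``cogid``, ``narrow_concept``, ``year``,
    ``form``, ``id`` -- to header name).  An empty year cell marks a
    contemporary source.  Row order is preserved.

    Raises
    ------
    FormatError
        If a mandatory column is missing, or any row has a non-integer CogID
        or year (the message carries the 1-based data row number).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\t" not in text and "\n" not in text:
            with open(text, "r", encoding="utf-8") as fh:
                text = fh.read()

    reader = csv.reader(io.StringIO(text), delimiter="\t")
    rows = [row for row in reader if row and any(cell.strip() for cell in row)]
    if not rows:
        raise FormatError("empty input: no header row")
    header = [h.strip() for h in rows[0]]
    idx = _resolve_columns(header, columns)

    def cell(row, fieldname, default=""):
        i = idx[fieldname]
        if i is None or i >= len(row):
            return default
        return row[i].strip()

    entries = []
    problems = []
    for rownum, row in enumerate(rows[1:], start=1):
        raw_cogid = cell(row, "cogid")
        raw_year = cell(row, "year")
        try:
            cogid = int(raw_cogid)
        except ValueError:
            problems.append(f"row {rownum}: non-integer cogid {raw_cogid!r}")
            continue
        year: Optional[int] = None
        if raw_year:
            try:
                year = int(raw_year)
            except ValueError:
                problems.append(f"row {rownum}: non-integer year {raw_year!r}")
                continue
        try:
            entries.append(
                Entry(
                    id=cell(row, "id") or str(rownum),
                    taxon=cell(row, "taxon"),
                    concept=cell(row, "concept"),
                    narrow_concept=cell(row, "narrow_concept"),
                    year=year,
                    form=cell(row, "form"),
                    cogid=cogid,
                )
            )
        except ValueError as exc:
            problems.append(f"row {rownum}: {exc}")
    if problems:
        raise FormatError("; ".join(problems))
    return Wordlist(entries)


def write_wordlist(wl: Wordlist, columns: Optional[dict] = None) -> str:
    """Serialize a wordlist back to the TSV dialect ``read_wordlist`` accepts.

    ``read_wordlist(write_wordlist(wl))`` reproduces the wordlist content
    exactly (entry order, years, forms, CogIDs).
    """
    names = dict(DEFAULT_COLUMNS)
    if columns:
        names.update(columns)
    order = ["id", "taxon", "concept", "narrow_concept", "year", "form", "cogid"]
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow([names[f] for f in order])
    for e in wl.entries:
        writer.writerow(
            [
                e.id,
                e.taxon,
                e.concept,
                e.narrow_concept,
                "" if e.year is None else str(e.year),
                e.form,
                str(e.cogid),
            ]
        )
    return buf.getvalue()


def validate_wordlist(wl: Wordlist) -> ValidationReport:
    """Run structural checks; problems are reported, never raised.

    Hard rules (errors):
      * no two entries may fill the same (taxon, narrow-concept) slot --
        duplicate variants must be explicitly allowed downstream
        (``to_binary_matrix(..., allow_variants=True)``).

    Soft rules (warnings):
      * a CogID shared across different concepts (legal -- CogIDs are only
        unique within a concept in some codings -- but worth flagging);
      * empty form strings.
    """
    report = ValidationReport()
    slot_seen: dict[tuple[str, str], str] = {}
    cogid_concepts: dict[int, set[str]] = {}
    cogid_first: dict[int, str] = {}
    for e in wl.entries:
        slot = (e.taxon, e.narrow_concept or e.concept)
        if slot in slot_seen:
            report.errors.append(
                (
                    e.id,
                    "duplicate-slot",
                    f"taxon {e.taxon!r} already has an entry (id {slot_seen[slot]!r}) "
                    f"for narrow concept {slot[1]!r}",
                )
            )
        else:
            slot_seen[slot] = e.id
        cogid_concepts.setdefault(e.cogid, set()).add(e.concept)
        cogid_first.setdefault(e.cogid, e.id)
        if not e.form:
            report.warnings.append((e.id, "empty-form", "entry has no form string"))
    for cogid, concepts in sorted(cogid_concepts.items()):
        if len(concepts) > 1:
            report.warnings.append(
                (
                    cogid_first[cogid],
                    "cogid-across-concepts",
                    f"cogid {cogid} appears under concepts {sorted(concepts)}",
                )
            )
    return report


__all__ = [
    "DEFAULT_COLUMNS",
    "Entry",
    "Wordlist",
    "ValidationReport",
    "read_wordlist",
    "write_wordlist",
    "validate_wordlist",
]
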