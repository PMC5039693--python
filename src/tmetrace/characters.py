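"""Tympanic-middle-ear character coding.

The anuran tympanic middle ear (TME) is a chain of three structures, from
lateral to medial: tympanic membrane (TM), tympanic annulus (TA), columella
(CO). Across anurans their presence/absence follows a strict lateral–medial
dependency: a lateral structure occurs only where the next medial one does.
This module encodes that dependency as completion rules over three-valued
(present / absent / unknown) scorings:

  (1) CO absent  => TA absent and TM absent
  (2) TA absent  => TM absent          (CO may still be present)
  (3) TM present => TA present and CO present
  (4) TA present => CO present

Rules fire only from *known* states; unknowns are filled, never overridden.
Contradictory scorings (e.g. TM present with CO absent) are rejected.

Binary encoding convention, repo-wide: 0 = absent, 1 = present, '?' = unknown.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from typing import Literal

__all__ = [
    "PRESENT",
    "ABSENT",
    "UNKNOWN",
    "StructureTriple",
    "CharacterMatrix",
    "InconsistentScoringError",
    "CharacterTableError",
    "complete_triple",
    "extract_binary",
    "read_character_table",
]

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"
_STATES = (PRESENT, ABSENT, UNKNOWN)

Structure = Literal["TM", "TA", "CO"]


class InconsistentScoringError(ValueError):
    """A scoring violates the lateral-medial dependency."""


class CharacterTableError(ValueError):
    """Malformed character-table input."""


@dataclass(frozen=True)
class StructureTriple:
    """Presence/absence/unknown of TM, TA, CO for one taxon."""

    taxon: str
    tm: str = UNKNOWN
    ta: str = UNKNOWN
    co: str = UNKNOWN

    def __post_init__(self) -> None:
        for name in ("tm", "ta", "co"):
            if getattr(self, name) not in _STATES:
                raise ValueError(f"{name}={getattr(self, name)!r} not in {_STATES}")

    def is_complete(self) -> bool:
        return self == complete_triple(self)


def complete_triple(raw: StructureTriple) -> StructureTriple:
    """Minimal completion of a scoring under the dependency rules.

    Returns the unique triple in which every state forced by rules (1)-(4)
    is filled in; states not forced by any rule stay as given. Idempotent,
    and monotone: a known state is never changed, only unknowns are filled.

    Raises
    ------
    InconsistentScoringError
        If the given known states contradict a rule, e.g. TM present while
        CO absent (violates rule 3) or TA present while CO absent (rule 4).
    """
    tm, ta, co = raw.tm, raw.ta, raw.co

    # contradictions among known states
    if tm == PRESENT and ta == ABSENT:
        raise InconsistentScoringError(
            f"{raw.taxon}: TM present with TA absent violates rule (3): "
            "presence of the membrane implies presence of the annulus"
        )
    if tm == PRESENT and co == ABSENT:
        raise InconsistentScoringError(
            f"{raw.taxon}: TM present with CO absent violates rule (3): "
            "presence of the membrane implies presence of the columella"
        )
    if ta == PRESENT and co == ABSENT:
        raise InconsistentScoringError(
            f"{raw.taxon}: TA present with CO absent violates rule (4): "
            "presence of the annulus implies presence of the columella"
        )

    # forward fills; each rule fires only from a known antecedent
    if co == ABSENT:  # rule (1)
        ta = ABSENT
        tm = ABSENT
    if ta == ABSENT:  # rule (2); CO deliberately untouched
        tm = ABSENT
    if tm == PRESENT:  # rule (3)
        ta = PRESENT
        co = PRESENT
    if ta == PRESENT:  # rule (4)
        co = PRESENT

    return replace(raw, tm=tm, ta=ta, co=co)


@dataclass
class CharacterMatrix:
    """Completed scorings for a set of taxa, with per-row provenance."""

    rows: list[StructureTriple] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [r.taxon for r in self.rows]
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise CharacterTableError(f"duplicate taxa: {dups}")

    def taxa(self) -> list[str]:
        return [r.taxon for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows)


def extract_binary(matrix: CharacterMatrix, structure: Structure) -> dict[str, object]:
    """Per-taxon binary states for one structure: 0 absent, 1 present, '?' unknown."""
    attr = {"TM": "tm", "TA": "ta", "CO": "co"}[structure]
    code = {PRESENT: 1, ABSENT: 0, UNKNOWN: "?"}
    return {r.taxon: code[getattr(r, attr)] for r in matrix.rows}


_TOKENS = {
    "1": PRESENT,
    "present": PRESENT,
    "p": PRESENT,
    "0": ABSENT,
    "absent": ABSENT,
    "a": ABSENT,
    "?": UNKNOWN,
    "unknown": UNKNOWN,
    "-": UNKNOWN,
}


def _parse_token(token: str, line: int, column: str) -> str:
    t = token.strip().lower()
    if t not in _TOKENS:
        raise CharacterTableError(f"line {line}: unknown state token {token!r} in column {column}")
    return _TOKENS[t]


def read_character_table(
    source: str,
) -> tuple[CharacterMatrix, list[StructureTriple], list[tuple[int, str]]]:
    """Read a TSV character table (columns: taxon, TM, TA, CO) and complete it.

    ``source`` is a file path or raw TSV text. Returns the completed matrix,
    the rows that the completion rules altered, and an inconsistency report
    of ``(line_number, message)`` for rows rejected as contradictory
    (rejected rows are excluded from the matrix).
    """
    if "\t" in source or "\n" in source:
        text = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    rows = [row for row in reader if row and any(cell.strip() for cell in row)]
    if not rows:
        raise CharacterTableError("empty character table")
    header = [h.strip().lower() for h in rows[0]]
    required = ["taxon", "tm", "ta", "co"]
    if header[: len(required)] != required:
        raise CharacterTableError(
            f"expected header columns {required}, got {rows[0][:4]}"
        )

    completed: list[StructureTriple] = []
    altered: list[StructureTriple] = []
    report: list[tuple[int, str]] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(rows[1:], start=2):
        if len(row) < 4:
            raise CharacterTableError(f"line {i}: expected 4 columns, got {len(row)}")
        taxon = row[0].strip()
        if not taxon:
            raise CharacterTableError(f"line {i}: empty taxon name")
        if taxon in seen:
            raise CharacterTableError(
                f"line {i}: duplicate taxon {taxon!r} (first at line {seen[taxon]})"
            )
        seen[taxon] = i
        raw = StructureTriple(
            taxon,
            _parse_token(row[1], i, "TM"),
            _parse_token(row[2], i, "TA"),
            _parse_token(row[3], i, "CO"),
        )
        try:
            full = complete_triple(raw)
        except InconsistentScoringError as exc:
            report.append((i, str(exc)))
            continue
        if full != raw:
            altered.append(full)
        completed.append(full)

    if not completed:
        raise CharacterTableError("no valid rows in character table")
    return CharacterMatrix(completed), altered, report
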