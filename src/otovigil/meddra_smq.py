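"""MedDRA preferred terms and Standardized MedDRA Query (SMQ) membership.

An SMQ is a curated set of preferred terms (PTs) defining one medical
condition of interest; the narrow scope keeps only highly specific terms.
The package ships the 56-term narrow SMQ for hearing impairment as a
two-column fixture.  Matching is by 8-digit numeric PT code, with a
case-insensitive exact term fallback; never substring or fuzzy.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .report_store import ReportCollection, Role, SafetyReport

__all__ = [
    "PtEntry",
    "SmqScope",
    "SmqDefinition",
    "load_smq",
    "packaged_hearing_smq",
    "report_matches_smq",
    "pt_breakdown",
]

HEARING_SMQ_RESOURCE = "hearing_impairment_smq_narrow.csv"


class SmqScope(enum.Enum):
    NARROW = "narrow"
    BROAD = "broad"


@dataclass(frozen=True, slots=True)
class PtEntry:
    """One MedDRA preferred term: 8-digit numeric code plus display term."""

    code: int
    term: str

    def __post_init__(self) -> None:
        if not self.term:
            raise ValueError("PT term must be non-empty")
        if not (10_000_000 <= self.code <= 99_999_999):
            raise ValueError(f"PT code {self.code} is not an 8-digit code")


@dataclass(frozen=True)
class SmqDefinition:
    """A named SMQ: a set of member PTs with narrow or broad scope."""

    name: str
    scope: SmqScope
    members: frozenset[PtEntry]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("SMQ must have at least one member PT")
        codes = [m.code for m in self.members]
        if len(codes) != len(set(codes)):
            raise ValueError("duplicate PT codes in SMQ members")

    @property
    def codes(self) -> frozenset[int]:
        return frozenset(m.code for m in self.members)

    def term_of(self, code: int) -> str | None:
        for m in self.members:
            if m.code == code:
                return m.term
        return None

    def lookup_term(self, term: str) -> PtEntry | None:
        """Case-insensitive exact term match (fallback when codes are absent)."""
        t = term.strip().lower()
        for m in self.members:
            if m.term.lower() == t:
                return m
        return None


def load_smq(
    path: str | Path,
    name: str = "hearing impairment",
    scope: SmqScope = SmqScope.NARROW,
    delimiter: str = ",",
) -> SmqDefinition:
    """Load an SMQ definition from a two-column (term, code) delimited file.

    Raises on malformed or duplicate codes, naming the offending line/code.
    """
    members: list[PtEntry] = []
    seen: dict[int, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None or {"term", "code"} - set(reader.fieldnames):
            raise ValueError(f"{path}: expected header with 'term' and 'code' columns")
        for lineno, row in enumerate(reader, start=2):
            code_txt = (row["code"] or "").strip()
            if not code_txt.isdigit() or len(code_txt) != 8:
                raise ValueError(f"{path}:{lineno}: malformed PT code {code_txt!r} (need 8 digits)")
            code = int(code_txt)
            if code in seen:
                raise ValueError(f"{path}:{lineno}: duplicate PT code {code} ({seen[code]!r})")
            term = (row["term"] or "").strip()
            seen[code] = term
            members.append(PtEntry(code, term))
    return SmqDefinition(name=name, scope=scope, members=frozenset(members))


def packaged_hearing_smq() -> SmqDefinition:
    """The packaged 56-term narrow SMQ of hearing impairment."""
    ref = resources.files("otovigil.data").joinpath(HEARING_SMQ_RESOURCE)
    with resources.as_file(ref) as path:
        return load_smq(path)


def report_matches_smq(report: SafetyReport, smq: SmqDefinition) -> bool:
    """True iff any of the report's reaction PT codes is an SMQ member.

    Counting unit is the report: several member PTs on one report still
    classify it once at the SMQ level."""
    return not report.reaction_pts.isdisjoint(smq.codes)


def pt_breakdown(
    collection: ReportCollection,
    drug_name: str,
    smq: SmqDefinition,
    min_n: int | None = 3,
) -> list[tuple[PtEntry, int]]:
    """Per-PT report counts for a drug's primary-suspect reports.

    Counts, for each SMQ member PT, the number of deduplicated reports that
    name ``drug_name`` as primary suspect and carry that PT.  Sorted by
    descending count (ties by term); entries with count < ``min_n`` are
    dropped when the filter is on (``min_n=None`` disables it).
    """
    by_code = {m.code: m for m in smq.members}
    counts: dict[int, int] = {}
    for r in collection:
        if not r.has_drug_with_role(drug_name, Role.PRIMARY_SUSPECT):
            continue
        for code in r.reaction_pts & smq.codes:
            counts[code] = counts.get(code, 0) + 1
    items = [(by_code[c], n) for c, n in counts.items() if min_n is None or n >= min_n]
    items.sort(key=lambda it: (-it[1], it[0].term))
    return items
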