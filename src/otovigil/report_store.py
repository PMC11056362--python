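"""Ingestion and curation of FAERS-style spontaneous adverse-event reports.

A spontaneous report links one or more drugs (each with a reporter-assigned
role code) to one or more adverse events coded as MedDRA preferred terms
(PTs).  Reports arrive split across four delimited tables in the FAERS
quarterly style — demographics, drugs, reactions, outcomes — joined on a
report identifier.  The same clinical case can appear several times under
one case identifier (the legacy "ISR number"); deduplication keeps one
version per case.  Downstream disproportionality analysis operates on the
deduplicated, report-level collection.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable

__all__ = [
    "Role",
    "Sex",
    "Outcome",
    "DrugEntry",
    "SafetyReport",
    "ReportCollection",
    "LoadLog",
    "read_reports",
    "write_reports",
    "deduplicate",
    "filter_primary_suspect",
    "normalize_drug_name",
]


class Role(enum.Enum):
    """Drug role codes: the reporter's attribution of causal suspicion."""

    PRIMARY_SUSPECT = "PS"
    SECONDARY_SUSPECT = "SS"
    CONCOMITANT = "C"
    INTERACTING = "I"


class Sex(enum.Enum):
    MALE = "M"
    FEMALE = "F"
    UNKNOWN = "UNK"


class Outcome(enum.Enum):
    """FAERS report-level seriousness outcome codes."""

    HOSPITALIZATION = "HO"
    DISABILITY = "DS"
    LIFE_THREATENING = "LT"
    DEATH = "DE"
    REQUIRED_INTERVENTION = "RI"
    OTHER = "OT"


_ROLE_BY_CODE = {r.value: r for r in Role}
_SEX_BY_CODE = {"M": Sex.MALE, "F": Sex.FEMALE}
_OUTCOME_BY_CODE = {o.value: o for o in Outcome}

#: Common salt/ester suffixes stripped during generic-name normalization.
DEFAULT_SALT_SUFFIXES: tuple[str, ...] = (
    "citrate",
    "hydrochloride",
    "hcl",
    "sodium",
    "calcium",
    "sulfate",
    "sulphate",
    "mesylate",
    "tartrate",
)


def normalize_drug_name(
    name: str,
    synonym_map: dict[str, str] | None = None,
    salt_suffixes: Iterable[str] = DEFAULT_SALT_SUFFIXES,
) -> str:
    """Normalize a drug name: lowercase, trim, strip a trailing salt word,
    then apply an explicit synonym map.  No fuzzy matching."""
    s = " ".join(name.strip().lower().split())
    parts = s.split(" ")
    if len(parts) > 1 and parts[-1] in set(salt_suffixes):
        s = " ".join(parts[:-1])
    if synonym_map:
        s = synonym_map.get(s, s)
    return s


@dataclass(frozen=True, slots=True)
class DrugEntry:
    """One drug row of a report: normalized generic name plus role code."""

    drug_name: str
    role: Role
    dose_text: str | None = None
    indication_pt: str | None = None

    def __post_init__(self) -> None:
        if not self.drug_name:
            raise ValueError("drug_name must be non-empty after normalization")


@dataclass(slots=True)
class SafetyReport:
    """One spontaneous report: drugs, reaction PTs, demographics, outcomes.

    ``age_years`` and ``country`` use ``None`` as an explicit unknown marker;
    unknown values are never encoded as 0 or a sentinel number.
    """

    report_id: str
    case_id: str
    drugs: list[DrugEntry]
    reaction_pts: frozenset[int]
    age_years: float | None = None
    sex: Sex = Sex.UNKNOWN
    country: str | None = None
    year: int = 0
    outcomes: frozenset[Outcome] = frozenset()

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ValueError(f"report {self.report_id}: at least one drug required")
        if not self.reaction_pts:
            raise ValueError(f"report {self.report_id}: at least one reaction required")
        if self.age_years is not None and not (0 <= self.age_years <= 120):
            raise ValueError(f"report {self.report_id}: age {self.age_years} outside [0, 120]")

    def has_drug_with_role(self, drug_name: str, role: Role) -> bool:
        return any(d.drug_name == drug_name and d.role is role for d in self.drugs)

    def primary_suspects(self) -> set[str]:
        return {d.drug_name for d in self.drugs if d.role is Role.PRIMARY_SUSPECT}


@dataclass
class ReportCollection:
    """An in-memory set of validated reports with unique report_ids."""

    reports: list[SafetyReport]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.reports]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate report_id in collection")

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)


@dataclass
class LoadLog:
    """Plain-text accounting of every row skipped or report dropped at load."""

    lines: list[str] = field(default_factory=list)

    def record(self, reason: str) -> None:
        self.lines.append(reason)

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.lines) + ("\n" if self.lines else ""))


_DIALECT_DELIMS = {"dollar_delimited": "$", "comma_delimited": ","}


def _open_table(path: str | Path, delim: str) -> list[dict[str, str]]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input table not found: {p}")
    with open(p, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            return []
        return [dict(row) for row in reader]


def _require_columns(rows_path: str, header: Iterable[str], needed: Iterable[str]) -> None:
    missing = set(needed) - set(header)
    if missing:
        raise ValueError(f"{rows_path}: required column(s) missing from header: {sorted(missing)}")


def read_reports(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    outc_path: str | Path,
    dialect: str = "dollar_delimited",
    synonym_map: dict[str, str] | None = None,
    log: LoadLog | None = None,
) -> ReportCollection:
    """Join the four FAERS-style tables into a ReportCollection.

    One SafetyReport is built per distinct report_id in the demographics
    table.  Drug, reaction, and outcome rows attach by report_id; orphan rows
    (key absent from demographics) are skipped with a log line, and reports
    ending up with no parsable drug or reaction are dropped and logged.
    """
    if dialect not in _DIALECT_DELIMS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECT_DELIMS)}")
    delim = _DIALECT_DELIMS[dialect]
    log = log if log is not None else LoadLog()

    demo_rows = _open_table(demo_path, delim)
    drug_rows = _open_table(drug_path, delim)
    reac_rows = _open_table(reac_path, delim)
    outc_rows = _open_table(outc_path, delim)

    if demo_rows:
        _require_columns(str(demo_path), demo_rows[0].keys(), ["report_id", "case_id"])
    if drug_rows:
        _require_columns(str(drug_path), drug_rows[0].keys(), ["report_id", "drug_name", "role_code"])
    if reac_rows:
        _require_columns(str(reac_path), reac_rows[0].keys(), ["report_id"])
        if "pt_code" not in reac_rows[0] and "pt_term" not in reac_rows[0]:
            raise ValueError(f"{reac_path}: reaction table needs a pt_code or pt_term column")
    if outc_rows:
        _require_columns(str(outc_path), outc_rows[0].keys(), ["report_id", "outcome_code"])

    known_ids = {row["report_id"] for row in demo_rows}

    drugs_by_id: dict[str, list[DrugEntry]] = {}
    for i, row in enumerate(drug_rows, start=2):
        rid = row["report_id"]
        if rid not in known_ids:
            log.record(f"drug row {i}: orphan report_id {rid!r}, skipped")
            continue
        role = _ROLE_BY_CODE.get((row.get("role_code") or "").strip().upper())
        name = normalize_drug_name(row.get("drug_name") or "", synonym_map)
        if role is None or not name:
            log.record(f"drug row {i}: unparseable role/name, skipped")
            continue
        drugs_by_id.setdefault(rid, []).append(
            DrugEntry(name, role, row.get("dose") or None, row.get("indication") or None)
        )

    reacs_by_id: dict[str, set[int]] = {}
    for i, row in enumerate(reac_rows, start=2):
        rid = row["report_id"]
        if rid not in known_ids:
            log.record(f"reaction row {i}: orphan report_id {rid!r}, skipped")
            continue
        code_txt = (row.get("pt_code") or "").strip()
        if code_txt:
            try:
                code = int(code_txt)
            except ValueError:
                log.record(f"reaction row {i}: non-numeric pt_code {code_txt!r}, skipped")
                continue
        else:
            log.record(f"reaction row {i}: missing pt_code, skipped")
            continue
        reacs_by_id.setdefault(rid, set()).add(code)

    outcomes_by_id: dict[str, set[Outcome]] = {}
    for i, row in enumerate(outc_rows, start=2):
        rid = row["report_id"]
        if rid not in known_ids:
            log.record(f"outcome row {i}: orphan report_id {rid!r}, skipped")
            continue
        out = _OUTCOME_BY_CODE.get((row.get("outcome_code") or "").strip().upper())
        if out is None:
            log.record(f"outcome row {i}: unknown outcome code, skipped")
            continue
        outcomes_by_id.setdefault(rid, set()).add(out)

    reports: list[SafetyReport] = []
    seen: set[str] = set()
    for row in demo_rows:
        rid = row["report_id"]
        if rid in seen:
            log.record(f"demographics: repeated report_id {rid!r}, kept first occurrence")
            continue
        seen.add(rid)
        drugs = drugs_by_id.get(rid, [])
        reacs = reacs_by_id.get(rid, set())
        if not drugs:
            log.record(f"report {rid}: no parsable drug entry, dropped")
            continue
        if not reacs:
            log.record(f"report {rid}: no parsable reaction, dropped")
            continue
        age_txt = (row.get("age") or "").strip()
        age: float | None = None
        if age_txt:
            try:
                age = float(age_txt)
            except ValueError:
                log.record(f"report {rid}: unparseable age {age_txt!r}, set unknown")
            else:
                if not (0 <= age <= 120):
                    log.record(f"report {rid}: age {age} outside [0, 120], set unknown")
                    age = None
        year_txt = (row.get("year") or "").strip()
        try:
            year = int(year_txt) if year_txt else 0
        except ValueError:
            log.record(f"report {rid}: unparseable year {year_txt!r}, set 0")
            year = 0
        reports.append(
            SafetyReport(
                report_id=rid,
                case_id=(row.get("case_id") or rid).strip(),
                drugs=drugs,
                reaction_pts=frozenset(reacs),
                age_years=age,
                sex=_SEX_BY_CODE.get((row.get("sex") or "").strip().upper(), Sex.UNKNOWN),
                country=(row.get("country") or "").strip() or None,
                year=year,
                outcomes=frozenset(outcomes_by_id.get(rid, set())),
            )
        )
    return ReportCollection(reports, provenance=f"read_reports({demo_path})")


def write_reports(
    collection: ReportCollection,
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    outc_path: str | Path,
    dialect: str = "dollar_delimited",
) -> None:
    """Write a collection back to the four-table delimited layout.

    Inverse of :func:`read_reports` for clean data (round-trip safe)."""
    delim = _DIALECT_DELIMS[dialect]

    def _writer(path, header):
        fh = open(path, "w", newline="")
        w = csv.writer(fh, delimiter=delim)
        w.writerow(header)
        return fh, w

    fh_demo, w_demo = _writer(demo_path, ["report_id", "case_id", "age", "sex", "country", "year"])
    fh_drug, w_drug = _writer(drug_path, ["report_id", "drug_name", "role_code", "dose", "indication"])
    fh_reac, w_reac = _writer(reac_path, ["report_id", "pt_code"])
    fh_outc, w_outc = _writer(outc_path, ["report_id", "outcome_code"])
    try:
        for r in collection:
            sex_code = r.sex.value if r.sex is not Sex.UNKNOWN else ""
            age_txt = "" if r.age_years is None else repr(r.age_years)
            w_demo.writerow([r.report_id, r.case_id, age_txt, sex_code, r.country or "", r.year])
            for d in r.drugs:
                w_drug.writerow([r.report_id, d.drug_name, d.role.value, d.dose_text or "", d.indication_pt or ""])
            for code in sorted(r.reaction_pts):
                w_reac.writerow([r.report_id, code])
            for out in sorted(r.outcomes, key=lambda o: o.value):
                w_outc.writerow([r.report_id, out.value])
    finally:
        for fh in (fh_demo, fh_drug, fh_reac, fh_outc):
            fh.close()


def deduplicate(collection: ReportCollection) -> ReportCollection:
    """Keep exactly one report per case_id: the lexicographically greatest
    report_id, standing in for the most recent case version."""
    best: dict[str, SafetyReport] = {}
    for r in collection:
        cur = best.get(r.case_id)
        if cur is None or r.report_id > cur.report_id:
            best[r.case_id] = r
    kept = [r for r in collection if best[r.case_id] is r]
    return ReportCollection(kept, provenance=collection.provenance + " | dedup")


def filter_primary_suspect(collection: ReportCollection, drug_name: str) -> ReportCollection:
    """Reports where ``drug_name`` carries the primary-suspect role."""
    kept = [r for r in collection if r.has_drug_with_role(drug_name, Role.PRIMARY_SUSPECT)]
    return ReportCollection(kept, provenance=collection.provenance + f" | PS:{drug_name}")


def filter_predicate(collection: ReportCollection, pred: Callable[[SafetyReport], bool], label: str = "filter") -> ReportCollection:
    """Generic report-level filter used by the pipeline (e.g. SMQ membership)."""
    return ReportCollection([r for r in collection if pred(r)], provenance=collection.provenance + f" | {label}")
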