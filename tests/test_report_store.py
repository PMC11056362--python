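"""Ingestion, deduplication and role filtering of spontaneous reports."""

import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otovigil.report_store import (
    DrugEntry,
    LoadLog,
    ReportCollection,
    Role,
    SafetyReport,
    deduplicate,
    filter_primary_suspect,
    normalize_drug_name,
    read_reports,
    write_reports,
)

from conftest import make_report

DEMO_HEADER = "report_id$case_id$age$sex$country$year"
DRUG_HEADER = "report_id$drug_name$role_code$dose$indication"
REAC_HEADER = "report_id$pt_code"
OUTC_HEADER = "report_id$outcome_code"


def _write_tables(tmp_path, demo, drug, reac, outc):
    paths = {}
    for name, header, rows in (
        ("demo", DEMO_HEADER, demo),
        ("drug", DRUG_HEADER, drug),
        ("reac", REAC_HEADER, reac),
        ("outc", OUTC_HEADER, outc),
    ):
        p = tmp_path / f"{name}.txt"
        p.write_text("\n".join([header, *rows]) + "\n")
        paths[name] = p
    return paths


@pytest.fixture
def four_table_fixture(tmp_path):
    """3 demographics rows, 5 drug rows, 4 reaction rows, hand-joined."""
    return _write_tables(
        tmp_path,
        demo=[
            "r1$c1$63$M$US$2015",
            "r2$c2$$F$CA$2019",
            "r3$c3$41$$$2008",
        ],
        drug=[
            "r1$Sildenafil$PS$100 mg, once$erectile dysfunction",
            "r1$warfarin$C$$",
            "r2$Tadalafil$PS$$",
            "r3$sildenafil citrate$SS$$",
            "r3$furosemide$PS$$",
        ],
        reac=[
            "r1$10043882",
            "r1$10048865",
            "r2$10043882",
            "r3$90000001",
        ],
        outc=["r1$HO", "r2$DS", "r2$OT"],
    )


class TestReadReports:
    def test_hand_joined_fixture(self, four_table_fixture):
        f = four_table_fixture
        coll = read_reports(f["demo"], f["drug"], f["reac"], f["outc"])
        assert len(coll) == 3
        by_id = {r.report_id: r for r in coll}
        r1 = by_id["r1"]
        assert [d.drug_name for d in r1.drugs] == ["sildenafil", "warfarin"]
        assert r1.drugs[0].role is Role.PRIMARY_SUSPECT
        assert r1.drugs[0].dose_text == "100 mg, once"
        assert r1.reaction_pts == {10043882, 10048865}
        assert r1.age_years == 63 and r1.year == 2015
        r2 = by_id["r2"]
        assert r2.age_years is None  # explicit unknown, never 0
        assert len(r2.outcomes) == 2
        r3 = by_id["r3"]
        # salt suffix stripped during normalization
        assert {d.drug_name for d in r3.drugs} == {"sildenafil", "furosemide"}

    def test_empty_reaction_file_drops_all_reports(self, tmp_path, four_table_fixture):
        f = four_table_fixture
        f["reac"].write_text(REAC_HEADER + "\n")
        log = LoadLog()
        coll = read_reports(f["demo"], f["drug"], f["reac"], f["outc"], log=log)
        assert len(coll) == 0
        assert sum("no parsable reaction" in ln for ln in log.lines) == 3

    def test_orphan_drug_row_skipped_and_logged(self, four_table_fixture):
        f = four_table_fixture
        with open(f["drug"], "a") as fh:
            fh.write("r99$ghostdrug$PS$$\n")
        log = LoadLog()
        coll = read_reports(f["demo"], f["drug"], f["reac"], f["outc"], log=log)
        assert len(coll) == 3
        assert sum("orphan" in ln for ln in log.lines) == 1

    def test_missing_file_fatal(self, four_table_fixture, tmp_path):
        f = four_table_fixture
        with pytest.raises(FileNotFoundError):
            read_reports(tmp_path / "nope.txt", f["drug"], f["reac"], f["outc"])

    def test_missing_join_key_fatal(self, four_table_fixture):
        f = four_table_fixture
        f["demo"].write_text("ident$case_id$age\nr1$c1$63\n")
        with pytest.raises(ValueError, match="report_id"):
            read_reports(f["demo"], f["drug"], f["reac"], f["outc"])

    def test_round_trip(self, four_table_fixture, tmp_path):
        f = four_table_fixture
        coll = read_reports(f["demo"], f["drug"], f["reac"], f["outc"])
        out = tmp_path / "rt"
        out.mkdir()
        paths = [out / n for n in ("demo.txt", "drug.txt", "reac.txt", "outc.txt")]
        write_reports(coll, *paths)
        coll2 = read_reports(*paths)
        assert coll.reports == coll2.reports


class TestDeduplicate:
    def test_keeps_greatest_report_id(self):
        coll = ReportCollection([
            make_report("A1", case_id="case"),
            make_report("A2", case_id="case"),
        ])
        kept = deduplicate(coll)
        assert [r.report_id for r in kept] == ["A2"]

    def test_identity_on_distinct_cases(self):
        coll = ReportCollection([make_report(f"r{i}") for i in range(5)])
        assert deduplicate(coll).reports == coll.reports

    def test_ten_reports_seven_cases(self):
        reports = [make_report(f"r{i}", case_id=f"c{i}") for i in range(7)]
        reports += [make_report(f"r{i}x", case_id=f"c{i}") for i in range(3)]
        assert len(deduplicate(ReportCollection(reports))) == 7

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.text(string.ascii_lowercase, min_size=1, max_size=3),
                              st.text(string.ascii_lowercase, min_size=1, max_size=2)),
                    min_size=1, max_size=30, unique_by=lambda t: t[0]))
    def test_idempotent_and_case_preserving(self, id_pairs):
        coll = ReportCollection([make_report(rid, case_id=cid) for rid, cid in id_pairs])
        once = deduplicate(coll)
        assert deduplicate(once).reports == once.reports
        assert {r.case_id for r in once} == {r.case_id for r in coll}
        assert len(once) <= len(coll)


class TestFilterPrimarySuspect:
    def test_role_and_membership_rules(self):
        coll = ReportCollection([
            make_report("r1", drugs=[("x", Role.CONCOMITANT)]),  # excluded: wrong role
            make_report("r2", drugs=[("x", Role.PRIMARY_SUSPECT), ("x", Role.CONCOMITANT)]),
            make_report("r3", drugs=[("y", Role.PRIMARY_SUSPECT)]),
            make_report("r4", drugs=[("x", Role.PRIMARY_SUSPECT)]),
            make_report("r5", drugs=[("x", Role.SECONDARY_SUSPECT)]),
            make_report("r6", drugs=[("z", Role.PRIMARY_SUSPECT), ("x", Role.INTERACTING)]),
        ])
        kept = filter_primary_suspect(coll, "x")
        # r2 counted once despite two x entries
        assert [r.report_id for r in kept] == ["r2", "r4"]


class TestValidation:
    def test_report_requires_drug_and_reaction(self):
        with pytest.raises(ValueError):
            SafetyReport("r", "c", drugs=[], reaction_pts=frozenset({1}))
        with pytest.raises(ValueError):
            make_report("r", pts=[])

    def test_age_bounds(self):
        with pytest.raises(ValueError):
            make_report("r", age=150.0)

    def test_duplicate_report_id_rejected(self):
        with pytest.raises(ValueError):
            ReportCollection([make_report("r1"), make_report("r1", case_id="other")])

    def test_empty_drug_name_rejected(self):
        with pytest.raises(ValueError):
            DrugEntry("", Role.CONCOMITANT)


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("  Sildenafil  ", "sildenafil"),
        ("SILDENAFIL CITRATE", "sildenafil"),
        ("rosuvastatin calcium", "rosuvastatin"),
        ("viagra", "sildenafil"),  # via synonym map below
    ],
)
def test_normalize_drug_name(raw, expected):
    assert normalize_drug_name(raw, synonym_map={"viagra": "sildenafil"}) == expected
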