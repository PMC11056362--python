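import pytest

from otovigil.meddra_smq import packaged_hearing_smq
from otovigil.report_store import (
    DrugEntry,
    Outcome,
    ReportCollection,
    Role,
    SafetyReport,
    Sex,
)


@pytest.fixture(scope="session")
def hearing_smq():
    return packaged_hearing_smq()


def make_report(
    report_id,
    case_id=None,
    drugs=(("drugx", Role.PRIMARY_SUSPECT),),
    pts=(10043882,),
    age=None,
    sex=Sex.UNKNOWN,
    country=None,
    year=2015,
    outcomes=(),
):
    """Terse report builder for hand-constructed fixtures."""
    return SafetyReport(
        report_id=report_id,
        case_id=case_id or report_id,
        drugs=[DrugEntry(n, r) if isinstance(n, str) else n for n, r in drugs],
        reaction_pts=frozenset(pts),
        age_years=age,
        sex=sex,
        country=country,
        year=year,
        outcomes=frozenset(outcomes),
    )


@pytest.fixture
def six_report_collection():
    """The hand-enumerated 2x2 fixture: drug X vs event E1 (code 111).

    X-primary+E1; X-primary+E2; Y-primary+E1; Y-primary+E2; Y-primary+E1;
    Y-primary (X concomitant)+E1  ->  a=1 b=3 c=1 d=1.
    """
    E1, E2 = 90000111, 90000222
    return ReportCollection([
        make_report("r1", drugs=[("x", Role.PRIMARY_SUSPECT)], pts=[E1]),
        make_report("r2", drugs=[("x", Role.PRIMARY_SUSPECT)], pts=[E2]),
        make_report("r3", drugs=[("y", Role.PRIMARY_SUSPECT)], pts=[E1]),
        make_report("r4", drugs=[("y", Role.PRIMARY_SUSPECT)], pts=[E2]),
        make_report("r5", drugs=[("y", Role.PRIMARY_SUSPECT)], pts=[E1]),
        make_report("r6", drugs=[("y", Role.PRIMARY_SUSPECT), ("x", Role.CONCOMITANT)], pts=[E1]),
    ])


OUTCOME_CODES = {o.value: o for o in Outcome}
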