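"""Drug-event 2×2 contingency tables and frequentist/Bayesian signal scores.

Disproportionality analysis asks whether a drug-event pair is reported more
often than expected from the background of all other reports.  For a
deduplicated report collection the 2×2 table is

    a  reports with the suspect drug (primary suspect) and the event
    b  reports with the event under other drugs
    c  reports with the suspect drug and other events
    d  reports with other drugs and other events

Three classical scores are computed, each with its own positivity rule:

* Reporting odds ratio  ROR = (a/b)/(c/d), with a 95% CI symmetric on the
  log scale, exp(ln ROR ± 1.96·s), s = sqrt(1/a + 1/b + 1/c + 1/d).
  Positive when the CI lower bound exceeds 1 and a ≥ 2.
* Proportional reporting ratio  PRR = (a/(a+c)) / (b/(b+d)), paired with
  the Pearson χ² of the table.  Positive when PRR ≥ 2, χ² ≥ 4 and a ≥ 3.
* BCPNN information component  IC = log2[ a·N / ((a+c)(a+b)) ], the
  log-scale observed-to-expected co-reporting ratio, with the lower 95%
  limit IC025 evaluated multiplicatively as exp(ln IC − 1.96·s) (see
  ``ic_mode``).  Positive when IC025 > 0.

A pair is a signal when any of the three rules fires.  Zero cells are
handled by the Haldane–Anscombe correction (+0.5 to all four cells) for the
ratio estimators; χ² always stays on the raw counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

from .report_store import ReportCollection, Role, SafetyReport

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "build_contingency",
    "compute_ror",
    "compute_prr",
    "compute_ic",
    "evaluate_signal",
]

Z975 = 1.96  # conventional two-sided 95% normal quantile, as printed

Chi2Mode = Literal["all_cells", "a_cell_only"]
IcMode = Literal["multiplicative", "ic_minus_2sd"]


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Report-level 2×2 counts for one drug-event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n_total == 0:
            raise ValueError("contingency table must have N_total > 0")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def event_margin(self) -> int:
        return self.a + self.b

    @property
    def drug_margin(self) -> int:
        return self.a + self.c

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def corrected(self) -> tuple[float, float, float, float]:
        """Haldane–Anscombe cells: +0.5 everywhere if any cell is zero."""
        if self.has_zero_cell():
            return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)
        return (float(self.a), float(self.b), float(self.c), float(self.d))


@dataclass(frozen=True, slots=True)
class SignalResult:
    """All three disproportionality scores and their positivity flags."""

    n: int
    ror: float
    ror_ci: tuple[float, float]
    prr: float
    chi2: float
    ic: float
    ic025: float  # NaN when not evaluable (ic <= 0 under multiplicative mode)
    zero_corrected: bool
    degenerate_chi2: bool
    ror_positive: bool
    prr_positive: bool
    bcpnn_positive: bool

    @property
    def positive(self) -> bool:
        return self.ror_positive or self.prr_positive or self.bcpnn_positive


def build_contingency(
    collection: ReportCollection,
    drug_name: str,
    event_predicate: Callable[[SafetyReport], bool],
) -> ContingencyTable:
    """Count the four cells over a deduplicated collection.

    Drug exposure means the primary-suspect role only; the comparator for b
    and d is every other report in the collection.  The four cells always
    partition the collection.
    """
    if len(collection) == 0:
        raise ValueError("cannot build a contingency table from an empty collection")
    a = b = c = d = 0
    for r in collection:
        drug = r.has_drug_with_role(drug_name, Role.PRIMARY_SUSPECT)
        event = event_predicate(r)
        if drug and event:
            a += 1
        elif event:
            b += 1
        elif drug:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def compute_ror(table: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with its log-symmetric 95% CI."""
    a, b, c, d = table.corrected()
    ror = (a / b) / (c / d)
    s = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-Z975 * s), ror * math.exp(Z975 * s)


def compute_prr(table: ContingencyTable, chi2_mode: Chi2Mode = "all_cells") -> tuple[float, float]:
    """Proportional reporting ratio and the table's Pearson χ².

    PRR uses the Haldane-corrected cells when any raw cell is zero; χ² is
    always computed on the raw counts (expected counts from the margins, no
    continuity correction).  A zero margin makes χ² degenerate: reported 0.
    """
    a, b, c, d = table.corrected()
    prr = (a / (a + c)) / (b / (b + d))
    chi2 = pearson_chi2(table, chi2_mode)
    return prr, chi2


def pearson_chi2(table: ContingencyTable, mode: Chi2Mode = "all_cells") -> float:
    """Pearson χ² on the raw table; 0 for a degenerate (zero-margin) table.

    ``a_cell_only`` restricts the (O−E)²/E sum to the a-cell, a literal
    reading of the single-cell expected-count shorthand some reports print.
    """
    n = table.n_total
    rows = (table.event_margin, table.c + table.d)
    cols = (table.drug_margin, table.b + table.d)
    if 0 in rows or 0 in cols:
        return 0.0
    obs = ((table.a, table.b), (table.c, table.d))
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            chi2 += (obs[i][j] - e) ** 2 / e
            if mode == "a_cell_only":
                return chi2
    return chi2


def compute_ic(table: ContingencyTable, ic_mode: IcMode = "multiplicative") -> tuple[float, float]:
    """Information component and its lower 95% limit.

    The default ``multiplicative`` mode evaluates IC025 = exp(ln IC − 1.96·s)
    — the same log-scale shrinkage the ROR interval uses, applied to the IC
    point value; it is only defined for IC > 0, so for IC ≤ 0 the limit is
    returned as NaN (not evaluable, and never positive).  ``ic_minus_2sd``
    instead returns IC − 1.96·s on the log2 scale, defined for any IC.
    """
    a, b, c, d = table.corrected()
    n = a + b + c + d
    ic = math.log2(a * n / ((a + c) * (a + b)))
    s = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    if ic_mode == "ic_minus_2sd":
        return ic, ic - Z975 * s
    if ic <= 0:
        return ic, math.nan
    return ic, ic * math.exp(-Z975 * s)


def evaluate_signal(
    table: ContingencyTable,
    chi2_mode: Chi2Mode = "all_cells",
    ic_mode: IcMode = "multiplicative",
) -> SignalResult:
    """Score one table with all three algorithms and the positivity rules.

    The co-occurrence count N in the rules is the a-cell.  A pair is an
    overall signal if any one algorithm meets its criteria.
    """
    n = table.a
    ror, lo, hi = compute_ror(table)
    prr, chi2 = compute_prr(table, chi2_mode)
    ic, ic025 = compute_ic(table, ic_mode)
    degenerate = (table.event_margin == 0 or table.drug_margin == 0
                  or table.b + table.d == 0 or table.c + table.d == 0)
    return SignalResult(
        n=n,
        ror=ror,
        ror_ci=(lo, hi),
        prr=prr,
        chi2=chi2,
        ic=ic,
        ic025=ic025,
        zero_corrected=table.has_zero_cell(),
        degenerate_chi2=degenerate,
        ror_positive=(lo > 1.0 and n >= 2),
        prr_positive=(prr >= 2.0 and chi2 >= 4.0 and n >= 3),
        bcpnn_positive=(not math.isnan(ic025) and ic025 > 0.0),
    )
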