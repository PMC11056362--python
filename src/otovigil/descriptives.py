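"""Cohort characteristic tables for drug-specific adverse-event cohorts.

Stratified counts with percentages of the full cohort (unknowns included in
the denominator), age mean ± sample SD over known ages, and ranked top-k
tallies of dose strings, indication PTs and co-reported medicines.
Percentages are rounded half-up to 2 decimals so printed tables are
platform-stable.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .report_store import ReportCollection, Role, Sex

__all__ = ["CohortSummary", "percentage", "summarize_cohort", "summarize_drug_context"]

AGE_STRATA = ("<=44", "45-59", "60-74", ">=75", "unknown")
YEAR_PERIODS = ("2003-2007", "2008-2012", "2013-2017", "2018-2023", "other")


def percentage(count: int, denom: int) -> float:
    """100·count/denom rounded half-up to 2 decimals; 0.0 for an empty cohort."""
    if denom == 0:
        return 0.0
    pct = Decimal(count) * 100 / Decimal(denom)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _age_stratum(age: float | None) -> str:
    if age is None:
        return "unknown"
    if age < 45:
        return "<=44"
    if age < 60:
        return "45-59"
    if age < 75:
        return "60-74"
    return ">=75"


def _year_period(year: int) -> str:
    if 2003 <= year <= 2007:
        return "2003-2007"
    if 2008 <= year <= 2012:
        return "2008-2012"
    if 2013 <= year <= 2017:
        return "2013-2017"
    if 2018 <= year <= 2023:
        return "2018-2023"
    return "other"


@dataclass
class CohortSummary:
    """Clinical-characteristics summary of one drug's event cohort."""

    drug_name: str
    n_total: int
    age_strata: dict[str, int]
    age_mean: float | None
    age_sd: float | None
    sex_counts: dict[str, int]
    country_counts: dict[str, int]
    year_period_counts: dict[str, int]
    percentages: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table mirroring a characteristics-table layout."""
        rows = []
        for block, counts in (
            ("age", self.age_strata),
            ("sex", self.sex_counts),
            ("country", self.country_counts),
            ("year_period", self.year_period_counts),
        ):
            for stratum, n in counts.items():
                rows.append(
                    {
                        "drug": self.drug_name,
                        "block": block,
                        "stratum": stratum,
                        "count": n,
                        "pct": self.percentages.get(block, {}).get(stratum, percentage(n, self.n_total)),
                    }
                )
        rows.append({"drug": self.drug_name, "block": "age_mean_sd", "stratum": "mean",
                     "count": self.n_total, "pct": self.age_mean})
        rows.append({"drug": self.drug_name, "block": "age_mean_sd", "stratum": "sd",
                     "count": self.n_total, "pct": self.age_sd})
        return pd.DataFrame(rows)


def summarize_cohort(collection: ReportCollection, drug_name: str) -> CohortSummary:
    """Summarize an already deduplicated, event- and drug-filtered cohort.

    Age bins: <=44 means age < 45; then 45–59, 60–74, >=75, unknown.  Mean
    and SD (sample, n−1) use known ages only.  Every percentage uses the
    full cohort size as denominator.
    """
    n_total = len(collection)
    age_counts = {s: 0 for s in AGE_STRATA}
    sex_counts = {"male": 0, "female": 0, "unknown": 0}
    country_counts: dict[str, int] = {}
    year_counts = {p: 0 for p in YEAR_PERIODS}
    known_ages: list[float] = []
    for r in collection:
        age_counts[_age_stratum(r.age_years)] += 1
        if r.age_years is not None:
            known_ages.append(r.age_years)
        sex_counts[{Sex.MALE: "male", Sex.FEMALE: "female", Sex.UNKNOWN: "unknown"}[r.sex]] += 1
        country_counts[r.country or "unknown"] = country_counts.get(r.country or "unknown", 0) + 1
        year_counts[_year_period(r.year)] += 1
    mean = statistics.fmean(known_ages) if known_ages else None
    sd = statistics.stdev(known_ages) if len(known_ages) >= 2 else None
    summary = CohortSummary(
        drug_name=drug_name,
        n_total=n_total,
        age_strata=age_counts,
        age_mean=mean,
        age_sd=sd,
        sex_counts=sex_counts,
        country_counts=dict(sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))),
        year_period_counts=year_counts,
    )
    summary.percentages = {
        "age": {s: percentage(c, n_total) for s, c in age_counts.items()},
        "sex": {s: percentage(c, n_total) for s, c in sex_counts.items()},
        "country": {s: percentage(c, n_total) for s, c in summary.country_counts.items()},
        "year_period": {s: percentage(c, n_total) for s, c in year_counts.items()},
    }
    return summary


def summarize_drug_context(
    collection: ReportCollection, drug_name: str, k: int = 10
) -> dict[str, list[tuple[str, int]]]:
    """Top-k dose strings, indication PTs and co-reported drugs for a cohort.

    Counts are per report; the co-medication list excludes the analyzed
    drug's own primary-suspect entries.  Ties rank alphabetically.
    """
    dose: dict[str, int] = {}
    indication: dict[str, int] = {}
    co_drugs: dict[str, int] = {}
    for r in collection:
        seen_dose: set[str] = set()
        seen_ind: set[str] = set()
        seen_co: set[str] = set()
        for d in r.drugs:
            if d.drug_name == drug_name and d.role is Role.PRIMARY_SUSPECT:
                if d.dose_text:
                    seen_dose.add(d.dose_text)
                if d.indication_pt:
                    seen_ind.add(d.indication_pt)
            else:
                seen_co.add(d.drug_name)
        for v in seen_dose:
            dose[v] = dose.get(v, 0) + 1
        for v in seen_ind:
            indication[v] = indication.get(v, 0) + 1
        for v in seen_co:
            co_drugs[v] = co_drugs.get(v, 0) + 1

    def top(d: dict[str, int]) -> list[tuple[str, int]]:
        return sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))[:k]

    return {"dose": top(dose), "indication": top(indication), "co_medication": top(co_drugs)}
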