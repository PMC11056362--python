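"""Seriousness-outcome rates per drug and cross-drug comparisons.

For each seriousness outcome (hospitalization, disability, life-threatening,
death, required intervention) the per-drug reporting rate is the fraction of
the drug's event cohort carrying that outcome code.  Rates are compared
across drugs with an omnibus Pearson χ² on the drugs × {outcome, none}
table, and pairwise 2×2 tests — Fisher's exact (two-sided, sum of all
table probabilities ≤ the observed one) when any expected cell is 5 or
less, Pearson's χ² otherwise — under a Bonferroni correction over the
pairwise tests of that outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .report_store import Outcome, ReportCollection

__all__ = ["PairwiseTest", "OutcomeComparison", "outcome_rates", "compare_outcome"]

#: Outcomes compared across drugs ("other" is not a seriousness category).
SERIOUS_OUTCOMES = (
    Outcome.HOSPITALIZATION,
    Outcome.DISABILITY,
    Outcome.LIFE_THREATENING,
    Outcome.DEATH,
    Outcome.REQUIRED_INTERVENTION,
)


@dataclass(frozen=True, slots=True)
class PairwiseTest:
    drug_i: str
    drug_j: str
    raw_p: float
    adjusted_p: float
    test_used: str  # "pearson_chi2" | "fisher_exact"


@dataclass(frozen=True)
class OutcomeComparison:
    outcome: Outcome
    per_drug: dict[str, tuple[int, int, float]]  # drug -> (n_with, n_total, rate)
    omnibus_p: float
    pairwise: list[PairwiseTest]


def _outcome_count(collection: ReportCollection, outcome: Outcome) -> int:
    return sum(1 for r in collection if outcome in r.outcomes)


def outcome_rates(collections_by_drug: dict[str, ReportCollection]) -> pd.DataFrame:
    """Per-drug, per-outcome reporting rates as a tidy table.

    A report with several outcome codes counts once in each category.
    Drugs with an empty cohort get NaN rates and are excluded from
    comparisons downstream.
    """
    rows = []
    for drug, coll in collections_by_drug.items():
        n_total = len(coll)
        for outcome in SERIOUS_OUTCOMES:
            n_with = _outcome_count(coll, outcome)
            rate = n_with / n_total if n_total > 0 else float("nan")
            rows.append({"drug": drug, "outcome": outcome.name.lower(),
                         "n_with_outcome": n_with, "n_total": n_total, "rate": rate})
    return pd.DataFrame(rows)


def _pairwise_2x2(x1: int, n1: int, x2: int, n2: int) -> tuple[float, str]:
    """Two-sided p for a 2×2 outcome table; Fisher when any expected cell ≤ 5."""
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    n = table.sum()
    if n == 0 or (colsum == 0).any() or (rowsum == 0).any():
        return 1.0, "fisher_exact"
    expected = rowsum @ colsum / n
    if (expected <= 5).any():
        return float(stats.fisher_exact(table, alternative="two-sided")[1]), "fisher_exact"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p), "pearson_chi2"


def compare_outcome(
    outcome: Outcome,
    collections_by_drug: dict[str, ReportCollection],
    alpha: float = 0.05,
) -> OutcomeComparison:
    """Compare one outcome's rates across drugs.

    Drugs with an empty cohort are excluded and the Bonferroni factor is the
    number of pairwise tests actually performed.  ``adjusted_p`` is
    min(1, raw_p × factor); significance is judged at ``alpha`` on the
    adjusted value by the caller.
    """
    usable = {d: c for d, c in collections_by_drug.items() if len(c) > 0}
    if len(usable) < 2:
        raise ValueError("need at least two drugs with non-empty cohorts")
    per_drug: dict[str, tuple[int, int, float]] = {}
    for d, c in usable.items():
        x, n = _outcome_count(c, outcome), len(c)
        per_drug[d] = (x, n, x / n)

    counts = np.array([[x, n - x] for x, n, _ in per_drug.values()])
    if counts[:, 0].sum() == 0 or counts[:, 1].sum() == 0:
        omnibus_p = 1.0  # no variation in the outcome column
    else:
        omnibus_p = float(stats.chi2_contingency(counts, correction=False)[1])

    pairs = list(combinations(sorted(usable), 2))
    factor = len(pairs)
    pairwise = []
    for di, dj in pairs:
        xi, ni, _ = per_drug[di]
        xj, nj, _ = per_drug[dj]
        raw_p, test = _pairwise_2x2(xi, ni, xj, nj)
        pairwise.append(PairwiseTest(di, dj, raw_p, min(1.0, raw_p * factor), test))
    return OutcomeComparison(outcome=outcome, per_drug=per_drug, omnibus_p=omnibus_p, pairwise=pairwise)
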