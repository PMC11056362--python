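#!/usr/bin/env python
"""Cohort characteristics and outcome-rate comparisons on the synthetic study.

Prints the per-drug clinical-characteristics summary (age strata with
percentages of the full cohort, sex, countries, reporting periods) and the
cross-drug outcome comparisons with Bonferroni-adjusted pairwise tests;
writes the corresponding tables under results/.
"""

from pathlib import Path

import pandas as pd

from otovigil.pipeline import StudyConfig, run_study
from otovigil.synthetic import default_config

ROOT = Path(__file__).resolve().parent.parent
SEED = 20240428

config = StudyConfig(
    synth=default_config(n_reports=50_000, seed=SEED),
    drugs=["sildenafil", "tadalafil", "vardenafil", "avanafil"],
)
result = run_study(config)

out = ROOT / "results"
out.mkdir(exist_ok=True)

tab3 = pd.concat([c.to_frame() for c in result.cohorts.values()], ignore_index=True)
tab3.to_csv(out / "03_cohort_characteristics.csv", index=False)
for drug, cohort in result.cohorts.items():
    mean = f"{cohort.age_mean:.1f}" if cohort.age_mean is not None else "-"
    sd = f"{cohort.age_sd:.1f}" if cohort.age_sd is not None else "-"
    print(f"\n{drug}: n={cohort.n_total}, age mean±SD {mean}±{sd}")
    for stratum, n in cohort.age_strata.items():
        print(f"  age {stratum:8s} {n:4d} ({cohort.percentages['age'][stratum]:.2f}%)")

result.outcome_rate_table.to_csv(out / "03_outcome_rates.csv", index=False)
print("\noutcome rates per drug:")
print(result.outcome_rate_table.round(3).to_string(index=False))

rows = []
for name, comp in result.outcome_comparisons.items():
    print(f"\n{name}: omnibus p = {comp.omnibus_p:.3g}")
    for pw in comp.pairwise:
        sig = "*" if pw.adjusted_p < 0.05 else " "
        print(f"  {pw.drug_i} vs {pw.drug_j}: raw p={pw.raw_p:.3g}, adjusted={pw.adjusted_p:.3g} ({pw.test_used}){sig}")
        rows.append({"outcome": name, "pair": f"{pw.drug_i}|{pw.drug_j}", "raw_p": pw.raw_p,
                     "adjusted_p": pw.adjusted_p, "test": pw.test_used})
pd.DataFrame(rows).to_csv(out / "03_outcome_tests.csv", index=False)
print("\ntables written under results/")
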