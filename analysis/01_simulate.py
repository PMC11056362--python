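#!/usr/bin/env python
"""Generate the synthetic study dataset.

Draws the stock four-drug collection (50,000 reports, seed 20240428) with
planted hearing-impairment rate ratios, writes the four FAERS-style tables
under scratch/synthetic_study/ (regenerable, not a deliverable), and a
small summary of the generated collection under results/.
"""

from pathlib import Path

import pandas as pd

from otovigil.report_store import deduplicate
from otovigil.synthetic import default_config, generate, truth_table, write_faers_tables

ROOT = Path(__file__).resolve().parent.parent
SEED = 20240428

config = default_config(n_reports=50_000, seed=SEED)
log: list[str] = []
coll = generate(config, log=log)
dedup = deduplicate(coll)
print(f"generated {len(coll)} report rows -> {len(dedup)} deduplicated cases")
for line in log:
    print("  generation:", line)

paths = write_faers_tables(coll, ROOT / "scratch" / "synthetic_study")
print("wrote tables:", ", ".join(str(p) for p in paths.values()))
config.to_yaml(ROOT / "scratch" / "synthetic_study" / "config.yaml")

tt = truth_table(config)
out = ROOT / "results"
out.mkdir(exist_ok=True)
tt.to_csv(out / "01_generative_truth.csv", index=False)
print("\nplanted ground truth (per drug-event pair):")
print(tt[["drug", "term", "rr_nominal", "expected_a", "true_ror"]].to_string(index=False))

summary = pd.DataFrame([{
    "n_rows": len(coll),
    "n_cases": len(dedup),
    "n_duplicates": len(coll) - len(dedup),
    "seed": SEED,
}])
summary.to_csv(out / "01_dataset_summary.csv", index=False)
print("\nsummary written to results/01_dataset_summary.csv")
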