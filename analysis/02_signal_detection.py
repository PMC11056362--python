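#!/usr/bin/env python
"""Run the disproportionality study on the synthetic dataset.

Reads the four tables written by 01_simulate.py (regenerating them if
absent), runs the full pipeline — dedup, SMQ classification, 2×2 tables,
ROR / PRR+χ² / BCPNN-IC with positivity criteria, per-PT breakdown (N ≥ 3)
— and writes the signal tables under results/.  The planted rate ratios
(2.9–6.5) should surface as positive signals for every drug with enough
co-occurrences.
"""

from pathlib import Path

from otovigil.pipeline import StudyConfig, run_study, smq_signal_frame, write_study_outputs
from otovigil.synthetic import default_config, generate, write_faers_tables

ROOT = Path(__file__).resolve().parent.parent
SEED = 20240428
DATA = ROOT / "scratch" / "synthetic_study"

if not (DATA / "demo.txt").exists():
    print("dataset missing; regenerating (same seed as 01_simulate.py)")
    write_faers_tables(generate(default_config(n_reports=50_000, seed=SEED)), DATA)

config = StudyConfig(
    demo_path=str(DATA / "demo.txt"),
    drug_path=str(DATA / "drug.txt"),
    reac_path=str(DATA / "reac.txt"),
    outc_path=str(DATA / "outc.txt"),
    drugs=["sildenafil", "tadalafil", "vardenafil", "avanafil"],
)
result = run_study(config)

for stage, n in result.stage_counts.items():
    print(f"{stage:32s} rows={n}")

frame = smq_signal_frame(result)
print("\nSMQ-level signal strength (hearing impairment, narrow):")
print(frame[["drug", "n", "prr", "chi2", "ror", "ror_ci_low", "ror_ci_high", "ic", "ic025", "positive"]]
      .round(2).to_string(index=False))

written = write_study_outputs(result, ROOT / "results" / "02_study", seed=SEED)
print(f"\nwrote {len(written)} files under results/02_study/")
for drug, df in result.pt_signals.items():
    if not df.empty:
        print(f"\nper-PT signals for {drug} (N >= 3):")
        print(df[["pt_term", "n", "prr", "ror", "ic025", "positive"]].round(2).to_string(index=False))
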