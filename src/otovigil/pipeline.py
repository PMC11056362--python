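"""End-to-end study orchestration: load → dedup → classify → score → report.

The study is a single linear pipeline over a spontaneous-report collection:
read the four FAERS-style tables (or generate a synthetic collection),
deduplicate by case, then for each analyzed drug build the SMQ-level 2×2
table and signal scores, a per-PT signal table (N ≥ 3 by default), a
clinical-characteristics summary with context tallies, and cross-drug
outcome-rate comparisons.  Every stage logs its row count into a
machine-readable run manifest so each dropped report is attributable.
"""

from __future__ import annotations

import json
import math
import shutil
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import descriptives, disproportionality, meddra_smq, outcome_analysis, report_store
from .disproportionality import Chi2Mode, IcMode, SignalResult
from .meddra_smq import SmqDefinition
from .report_store import LoadLog, ReportCollection
from .synthetic import SynthConfig, generate

__all__ = ["StudyConfig", "StudyResult", "StageError", "run_study", "write_study_outputs"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the exit message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class StudyConfig(BaseModel):
    # exactly one input route: the four tables, or a synthetic config
    demo_path: str | None = None
    drug_path: str | None = None
    reac_path: str | None = None
    outc_path: str | None = None
    dialect: str = "dollar_delimited"
    synth: SynthConfig | None = None

    smq_path: str | None = None  # None -> packaged hearing-impairment narrow SMQ
    drugs: list[str] = Field(min_length=1)
    chi2_mode: Chi2Mode = "all_cells"
    ic_mode: IcMode = "multiplicative"
    pt_min_n: int | None = 3
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    top_k: int = 10


@dataclass
class StudyResult:
    config: StudyConfig
    smq: SmqDefinition
    smq_signals: dict[str, SignalResult]
    smq_tables: dict[str, disproportionality.ContingencyTable]
    pt_signals: dict[str, pd.DataFrame]
    cohorts: dict[str, descriptives.CohortSummary]
    context: dict[str, dict[str, list[tuple[str, int]]]]
    outcome_rate_table: pd.DataFrame
    outcome_comparisons: dict[str, outcome_analysis.OutcomeComparison]
    stage_counts: dict[str, int]
    warnings: list[str] = dc_field(default_factory=list)
    load_log: LoadLog = dc_field(default_factory=LoadLog)


def _load_collection(config: StudyConfig, log: LoadLog, warnings: list[str]) -> ReportCollection:
    if config.synth is not None:
        gen_log: list[str] = []
        coll = generate(config.synth, log=gen_log)
        warnings.extend(gen_log)
        return coll
    paths = (config.demo_path, config.drug_path, config.reac_path, config.outc_path)
    if any(p is None for p in paths):
        raise ValueError("either all four table paths or a synthetic config must be given")
    return report_store.read_reports(*paths, dialect=config.dialect, log=log)


def run_study(config: StudyConfig) -> StudyResult:
    """Execute all stages in order; any stage error is fatal with its name."""
    warnings: list[str] = []
    load_log = LoadLog()
    counts: dict[str, int] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc

    coll = stage("read", lambda: _load_collection(config, load_log, warnings))
    counts["read"] = len(coll)
    coll = stage("dedup", lambda: report_store.deduplicate(coll))
    counts["dedup"] = len(coll)
    smq = stage("smq_load", lambda: meddra_smq.load_smq(config.smq_path)
                if config.smq_path else meddra_smq.packaged_hearing_smq())

    def in_smq(report):
        return meddra_smq.report_matches_smq(report, smq)

    smq_signals: dict[str, SignalResult] = {}
    smq_tables: dict[str, disproportionality.ContingencyTable] = {}
    pt_signals: dict[str, pd.DataFrame] = {}
    cohorts: dict[str, descriptives.CohortSummary] = {}
    context: dict[str, dict] = {}
    cohort_colls: dict[str, ReportCollection] = {}

    for drug in config.drugs:
        ps = stage(f"filter:{drug}", lambda d=drug: report_store.filter_primary_suspect(coll, d))
        counts[f"primary_suspect:{drug}"] = len(ps)
        if len(ps) == 0:
            warnings.append(f"drug {drug!r} absent from the collection; sections left empty")
        cohort = report_store.filter_predicate(ps, in_smq, label="smq")
        counts[f"smq_cohort:{drug}"] = len(cohort)
        cohort_colls[drug] = cohort

        def signal(d=drug):
            table = disproportionality.build_contingency(coll, d, in_smq)
            return table, disproportionality.evaluate_signal(table, config.chi2_mode, config.ic_mode)

        smq_tables[drug], smq_signals[drug] = stage(f"signal:{drug}", signal)

        def per_pt(d=drug):
            rows = []
            for entry, n in meddra_smq.pt_breakdown(coll, d, smq, min_n=config.pt_min_n):
                t = disproportionality.build_contingency(coll, d, lambda r, c=entry.code: c in r.reaction_pts)
                s = disproportionality.evaluate_signal(t, config.chi2_mode, config.ic_mode)
                rows.append({
                    "drug": d, "pt_code": entry.code, "pt_term": entry.term, "n": n,
                    "prr": s.prr, "chi2": s.chi2, "ror": s.ror,
                    "ror_ci_low": s.ror_ci[0], "ror_ci_high": s.ror_ci[1],
                    "ic": s.ic, "ic025": s.ic025, "positive": s.positive,
                })
            return pd.DataFrame(rows, columns=["drug", "pt_code", "pt_term", "n", "prr", "chi2", "ror",
                                               "ror_ci_low", "ror_ci_high", "ic", "ic025", "positive"])

        pt_signals[drug] = stage(f"pt_breakdown:{drug}", per_pt)
        cohorts[drug] = stage(f"descriptives:{drug}", lambda d=drug, c=cohort: descriptives.summarize_cohort(c, d))
        context[drug] = stage(f"context:{drug}",
                              lambda d=drug, c=cohort: descriptives.summarize_drug_context(c, d, k=config.top_k))

    rate_table = stage("outcome_rates", lambda: outcome_analysis.outcome_rates(cohort_colls))
    comparisons: dict[str, outcome_analysis.OutcomeComparison] = {}
    usable = {d: c for d, c in cohort_colls.items() if len(c) > 0}
    if len(usable) >= 2:
        for outcome in outcome_analysis.SERIOUS_OUTCOMES:
            comparisons[outcome.name.lower()] = stage(
                f"compare:{outcome.name.lower()}",
                lambda o=outcome: outcome_analysis.compare_outcome(o, usable, alpha=config.alpha),
            )
    else:
        warnings.append("fewer than two non-empty cohorts; outcome comparisons skipped")

    return StudyResult(
        config=config, smq=smq, smq_signals=smq_signals, smq_tables=smq_tables,
        pt_signals=pt_signals, cohorts=cohorts, context=context,
        outcome_rate_table=rate_table, outcome_comparisons=comparisons,
        stage_counts=counts, warnings=warnings, load_log=load_log,
    )


def _fmt2(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{x:.2f}" if isinstance(x, float) else str(x)


def smq_signal_frame(result: StudyResult) -> pd.DataFrame:
    rows = []
    for drug, s in result.smq_signals.items():
        t = result.smq_tables[drug]
        rows.append({
            "drug": drug, "a": t.a, "b": t.b, "c": t.c, "d": t.d, "n": s.n,
            "prr": s.prr, "chi2": s.chi2, "ror": s.ror,
            "ror_ci_low": s.ror_ci[0], "ror_ci_high": s.ror_ci[1],
            "ic": s.ic, "ic025": s.ic025,
            "ror_positive": s.ror_positive, "prr_positive": s.prr_positive,
            "bcpnn_positive": s.bcpnn_positive, "positive": s.positive,
            "zero_corrected": s.zero_corrected,
        })
    return pd.DataFrame(rows)


def write_study_outputs(result: StudyResult, out_dir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Write all result tables plus the run manifest; partial outputs are
    removed if any write fails.  Machine tables keep full precision; the
    ``*_display`` variants round to 2 decimals."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        tab3 = pd.concat([c.to_frame() for c in result.cohorts.values()], ignore_index=True) \
            if result.cohorts else pd.DataFrame()
        _write_pair(tab3, out, "table3_characteristics", written)

        ctx_rows = [
            {"drug": drug, "block": block, "value": value, "count": n}
            for drug, blocks in result.context.items()
            for block, items in blocks.items()
            for value, n in items
        ]
        _write_pair(pd.DataFrame(ctx_rows, columns=["drug", "block", "value", "count"]),
                    out, "table4_context", written)
        _write_pair(smq_signal_frame(result), out, "table5_smq_signals", written)
        pt_frames = [df for df in result.pt_signals.values() if not df.empty]
        _write_pair(pd.concat(pt_frames, ignore_index=True) if pt_frames
                    else next(iter(result.pt_signals.values()), pd.DataFrame()),
                    out, "table6_pt_signals", written)
        _write_pair(result.outcome_rate_table, out, "fig2_outcomes", written)

        pw_rows = [
            {"outcome": name, "omnibus_p": comp.omnibus_p, "drug_i": pw.drug_i, "drug_j": pw.drug_j,
             "raw_p": pw.raw_p, "adjusted_p": pw.adjusted_p, "test": pw.test_used,
             "significant": pw.adjusted_p < result.config.alpha}
            for name, comp in result.outcome_comparisons.items()
            for pw in comp.pairwise
        ]
        _write_pair(pd.DataFrame(pw_rows, columns=["outcome", "omnibus_p", "drug_i", "drug_j",
                                                   "raw_p", "adjusted_p", "test", "significant"]),
                    out, "fig2_outcome_tests", written)

        manifest = {
            "config": json.loads(result.config.model_dump_json()),
            "seed": seed if seed is not None else (result.config.synth.seed if result.config.synth else None),
            "stage_counts": result.stage_counts,
            "warnings": result.warnings,
            "outputs": sorted(p.name for p in written.values()),
        }
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written["manifest"] = mpath
        lpath = out / "run.log"
        result.load_log.write(lpath)
        written["load_log"] = lpath
    except Exception:
        for p in written.values():
            p.unlink(missing_ok=True)
        if not any(out.iterdir()):
            shutil.rmtree(out, ignore_errors=True)
        raise
    return written


def _write_pair(df: pd.DataFrame, out: Path, name: str, written: dict[str, Path]) -> None:
    machine = out / f"{name}.csv"
    df.to_csv(machine, index=False)
    written[name] = machine
    display = out / f"{name}_display.csv"
    df.map(_fmt2).to_csv(display, index=False) if not df.empty else df.to_csv(display, index=False)
    written[f"{name}_display"] = display


def plot_outcome_rates(result: StudyResult, path: str | Path) -> None:
    """Presentation-only bar chart of per-drug outcome rates."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.outcome_rate_table
    if df.empty:
        return
    pivot = df.pivot(index="outcome", columns="drug", values="rate")
    ax = pivot.plot.bar(figsize=(8, 4.5), rot=20)
    ax.set_ylabel("reporting rate")
    ax.set_title("Seriousness outcomes by drug")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)
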