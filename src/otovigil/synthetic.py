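"""Synthetic spontaneous-report generator with known ground truth.

Emulates the structure of a FAERS extract — many drugs and events per
report, role codes with one primary suspect, case-level near-duplicates,
partially missing demographics, seriousness outcome codes — under a simple
generative model: each report draws one primary-suspect drug from declared
marginals (remaining mass goes to a background-drug pool), then each
declared event PT independently with probability

    q(drug, event) = min(1, baseline(event) × rr(drug, event)),

where ``rr`` is the planted relative reporting ratio (1 = no signal).
Events are conditionally independent given the drug, which is all the
marginal 2×2 structure downstream recovery tests need.  Every report also
carries one background (non-declared) reaction PT so the at-least-one-
reaction invariant holds without disturbing declared-pair cell counts.

Randomness is counter-based: one Philox stream per (seed, field), with the
report index as the counter, so enlarging ``n_reports`` appends reports
without reshuffling earlier ones.  Identical seeds give identical
collections.

:func:`truth_table` returns the closed-form expected cell proportions and
the implied true ROR/PRR/IC for every declared pair, for parameter-recovery
tests against the estimates.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import special, stats
from pydantic import BaseModel, Field, model_validator

from .report_store import (
    DrugEntry,
    Outcome,
    ReportCollection,
    Role,
    SafetyReport,
    Sex,
    write_reports,
)

__all__ = ["DrugSpec", "EventSpec", "Demographics", "SynthConfig", "generate", "truth_table", "default_config"]

BACKGROUND_PT_BASE = 90_000_000  # filler reaction codes, disjoint from MedDRA-style 10xxxxxx

_FIELD = {name: i for i, name in enumerate(
    ["drug", "bg_drug", "events", "filler_pt", "co_count", "co_which", "age", "age_miss",
     "sex", "sex_miss", "country", "year", "outcomes", "dup", "dup_country", "dose", "indication"]
)}


class DrugSpec(BaseModel):
    name: str
    marginal: float = Field(ge=0.0, le=1.0)  # P(report's primary suspect is this drug)


class EventSpec(BaseModel):
    pt_code: int
    term: str
    baseline: float = Field(gt=0.0, le=1.0)  # per-report inclusion probability under rr=1


class Demographics(BaseModel):
    age_mean: float = 60.0
    age_sd: float = 12.0
    male_fraction: float = Field(default=0.85, ge=0.0, le=1.0)
    countries: dict[str, float] = Field(
        default_factory=lambda: {"US": 0.80, "CA": 0.05, "GB": 0.04, "BR": 0.02, "JP": 0.02, "OTHER": 0.07}
    )


class SynthConfig(BaseModel):
    """All knobs of the generator; defaults emulate a desk-scale FAERS slice."""

    n_reports: int = Field(default=50_000, gt=0)
    drugs: list[DrugSpec]
    background_drug_pool: int = Field(default=100, gt=0)
    events: list[EventSpec]
    planted_rr: dict[str, dict[int, float]] = Field(default_factory=dict)  # drug -> pt_code -> rr
    co_drug_rate: float = Field(default=1.5, ge=0.0)
    demographics: dict[str, Demographics] = Field(default_factory=lambda: {"default": Demographics()})
    year_range: tuple[int, int] = (2003, 2023)
    outcome_probs: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {"default": {"HO": 0.08, "DS": 0.10, "LT": 0.02, "DE": 0.03, "RI": 0.05, "OT": 0.50}}
    )
    dose_options: dict[str, list[str]] = Field(default_factory=dict)
    indication_options: dict[str, list[str]] = Field(default_factory=dict)
    p_missing_age: float = Field(default=0.40, ge=0.0, le=1.0)
    p_missing_sex: float = Field(default=0.05, ge=0.0, le=1.0)
    p_duplicate: float = Field(default=0.10, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SynthConfig":
        total = sum(d.marginal for d in self.drugs)
        if total > 1.0 + 1e-12:
            raise ValueError(f"drug marginals sum to {total} > 1")
        names = {d.name for d in self.drugs}
        codes = {e.pt_code for e in self.events}
        for drug, per_event in self.planted_rr.items():
            if drug not in names:
                raise ValueError(f"planted_rr references undeclared drug {drug!r}")
            for code, rr in per_event.items():
                if code not in codes:
                    raise ValueError(f"planted_rr references undeclared event {code}")
                if rr < 0:
                    raise ValueError("planted rate ratios must be >= 0")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (lo, hi) with lo <= hi")
        return self

    def rr(self, drug: str, pt_code: int) -> float:
        return self.planted_rr.get(drug, {}).get(pt_code, 1.0)

    def effective_q(self, drug: str, event: EventSpec) -> float:
        """Per-report event probability after clamping at 1."""
        return min(1.0, event.baseline * self.rr(drug, event.pt_code))

    def demographics_for(self, drug: str) -> Demographics:
        return self.demographics.get(drug, self.demographics.get("default", Demographics()))

    def outcome_probs_for(self, drug: str) -> dict[str, float]:
        return self.outcome_probs.get(drug, self.outcome_probs.get("default", {}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False))


def default_config(**overrides) -> SynthConfig:
    """The stock study-like configuration: four PDE5-inhibitor-style drugs
    with planted hearing-event rate ratios in the range the class shows,
    over a 100-drug background universe."""
    base = dict(
        drugs=[
            DrugSpec(name="sildenafil", marginal=0.030),
            DrugSpec(name="tadalafil", marginal=0.020),
            DrugSpec(name="vardenafil", marginal=0.006),
            DrugSpec(name="avanafil", marginal=0.0008),
        ],
        events=[
            EventSpec(pt_code=10043882, term="Tinnitus", baseline=0.004),
            EventSpec(pt_code=10048865, term="Hypoacusis", baseline=0.003),
            EventSpec(pt_code=10011878, term="Deafness", baseline=0.002),
            EventSpec(pt_code=10048812, term="Deafness unilateral", baseline=0.0008),
            EventSpec(pt_code=10061373, term="Sudden hearing loss", baseline=0.0006),
        ],
        planted_rr={
            "sildenafil": {10043882: 2.9, 10048865: 2.9, 10011878: 2.9, 10048812: 2.9, 10061373: 2.9},
            "tadalafil": {10043882: 3.5, 10048865: 3.5, 10011878: 3.5, 10048812: 3.5, 10061373: 3.5},
            "vardenafil": {10043882: 3.2, 10048865: 3.2, 10011878: 3.2, 10048812: 3.2, 10061373: 3.2},
            "avanafil": {10043882: 6.5, 10048865: 6.5, 10011878: 6.5, 10048812: 6.5, 10061373: 6.5},
        },
        dose_options={
            "sildenafil": ["100 mg, once", "20 mg, tid", "50 mg, once"],
            "tadalafil": ["20 mg, once", "5 mg, once", "40 mg, once"],
            "vardenafil": ["10 mg, once", "20 mg, once", "5 mg, once"],
            "avanafil": ["100 mg, once", "200 mg, once"],
            "default": ["10 mg, once", "20 mg, once"],
        },
        indication_options={
            "default": ["erectile dysfunction", "pulmonary arterial hypertension", "hypertension"],
        },
    )
    base.update(overrides)
    return SynthConfig(**base)


def _rng(seed: int, field: str) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=[np.uint64(seed), np.uint64(_FIELD[field])]))


def _uniform(seed: int, field: str, size) -> np.ndarray:
    """Counter-stable uniforms: value k depends only on (seed, field, k).

    All other distributions are derived from these by inverse CDF, so
    enlarging ``n_reports`` appends draws without disturbing earlier ones
    (rejection samplers would consume a variable number of raws per value).
    """
    return _rng(seed, field).random(size)


def _choice_idx(u: np.ndarray, n_options: int) -> np.ndarray:
    return np.minimum((u * n_options).astype(np.int64), n_options - 1)


def generate(config: SynthConfig, log: list[str] | None = None) -> ReportCollection:
    """Draw a collection of exactly ``n_reports`` logical reports (plus
    near-duplicate copies per ``p_duplicate``), byte-identical per seed."""
    n = config.n_reports
    seed = config.seed
    drug_names = [d.name for d in config.drugs]
    marginals = np.array([d.marginal for d in config.drugs])
    cum = np.cumsum(marginals)
    n_events = len(config.events)

    # primary-suspect drug per report; mass beyond the declared marginals
    # falls to a numbered background-drug pool
    u_drug = _uniform(seed, "drug", n)
    drug_idx = np.searchsorted(cum, u_drug, side="right")  # == len(drugs) -> background
    bg_idx = _choice_idx(_uniform(seed, "bg_drug", n), config.background_drug_pool)

    # per-report event inclusion with planted rate ratios
    q = np.empty((len(drug_names) + 1, n_events))
    for i, name in enumerate(drug_names):
        for j, ev in enumerate(config.events):
            raw = ev.baseline * config.rr(name, ev.pt_code)
            if raw > 1.0 and log is not None:
                log.append(f"clamped infeasible probability {raw:.3f} for ({name}, {ev.pt_code})")
            q[i, j] = min(1.0, raw)
    q[len(drug_names)] = [ev.baseline for ev in config.events]  # background drugs: rr = 1
    u_events = _uniform(seed, "events", (n, n_events))
    included = u_events < q[drug_idx]

    filler_pt = BACKGROUND_PT_BASE + 1 + _choice_idx(_uniform(seed, "filler_pt", n), 500)

    u_co = _uniform(seed, "co_count", n)
    co_counts = np.minimum(stats.poisson.ppf(u_co, config.co_drug_rate).astype(np.int64), 8) \
        if config.co_drug_rate > 0 else np.zeros(n, dtype=np.int64)
    co_which = _choice_idx(_uniform(seed, "co_which", (n, 8)), config.background_drug_pool)

    # demographics, drawn per report from the per-drug parameters
    demos = [config.demographics_for(name) for name in drug_names]
    demos.append(config.demographics_for("default"))
    age_mean = np.array([d.age_mean for d in demos])[drug_idx]
    age_sd = np.array([d.age_sd for d in demos])[drug_idx]
    z = special.ndtri(np.clip(_uniform(seed, "age", n), 1e-12, 1 - 1e-12))
    age = np.clip(z * age_sd + age_mean, 18.0, 100.0)
    age_missing = _uniform(seed, "age_miss", n) < config.p_missing_age
    male_frac = np.array([d.male_fraction for d in demos])[drug_idx]
    is_male = _uniform(seed, "sex", n) < male_frac
    sex_missing = _uniform(seed, "sex_miss", n) < config.p_missing_sex

    country_labels = sorted({c for d in demos for c in d.countries})
    cprob = np.zeros((len(demos), len(country_labels)))
    for i, d in enumerate(demos):
        total = sum(d.countries.values())
        for j, c in enumerate(country_labels):
            cprob[i, j] = d.countries.get(c, 0.0) / total
    ccum = np.cumsum(cprob, axis=1)
    u_country = _uniform(seed, "country", n)
    country_idx = (u_country[:, None] >= ccum[drug_idx]).sum(axis=1)
    country_idx = np.minimum(country_idx, len(country_labels) - 1)

    y0, y1 = config.year_range
    year = y0 + _choice_idx(_uniform(seed, "year", n), y1 - y0 + 1)

    outcome_codes = [o.value for o in Outcome]
    oprob = np.zeros((len(demos), len(outcome_codes)))
    for i, name in enumerate(drug_names + ["default"]):
        probs = config.outcome_probs_for(name)
        for j, code in enumerate(outcome_codes):
            oprob[i, j] = probs.get(code, 0.0)
    u_out = _uniform(seed, "outcomes", (n, len(outcome_codes)))
    has_outcome = u_out < oprob[drug_idx]

    is_dup = _uniform(seed, "dup", n) < config.p_duplicate
    dup_country_idx = _choice_idx(_uniform(seed, "dup_country", n), len(country_labels))

    u_dose = _uniform(seed, "dose", n)
    u_ind = _uniform(seed, "indication", n)

    outcome_members = list(Outcome)
    bg_drug_cache = {i: DrugEntry(f"backdrug-{i:03d}", Role.CONCOMITANT) for i in range(config.background_drug_pool)}
    bg_primary_cache = {i: DrugEntry(f"backdrug-{i:03d}", Role.PRIMARY_SUSPECT) for i in range(config.background_drug_pool)}
    primary_cache: dict[tuple, DrugEntry] = {}
    event_codes = np.array([ev.pt_code for ev in config.events])

    reports: list[SafetyReport] = []
    for i in range(n):
        di = drug_idx[i]
        if di < len(drug_names):
            name = drug_names[di]
            doses = config.dose_options.get(name) or config.dose_options.get("default") or [None]
            inds = config.indication_options.get(name) or config.indication_options.get("default") or [None]
            dose = doses[int(u_dose[i] * len(doses))]
            ind = inds[int(u_ind[i] * len(inds))]
            key = (name, dose, ind)
            primary = primary_cache.get(key)
            if primary is None:
                primary = primary_cache[key] = DrugEntry(name, Role.PRIMARY_SUSPECT, dose, ind)
        else:
            primary = bg_primary_cache[bg_idx[i]]
        drugs = [primary]
        for k in range(co_counts[i]):
            co = bg_drug_cache[co_which[i, k]]
            if co.drug_name != primary.drug_name:
                drugs.append(co)
        pts = frozenset(event_codes[included[i]].tolist()) | {int(filler_pt[i])}
        outs = frozenset(o for j, o in enumerate(outcome_members) if has_outcome[i, j])
        base = SafetyReport(
            report_id=f"R{i:08d}-1",
            case_id=f"C{i:08d}",
            drugs=drugs,
            reaction_pts=pts,
            age_years=None if age_missing[i] else round(float(age[i]), 1),
            sex=Sex.UNKNOWN if sex_missing[i] else (Sex.MALE if is_male[i] else Sex.FEMALE),
            country=country_labels[country_idx[i]],
            year=int(year[i]),
            outcomes=outs,
        )
        reports.append(base)
        if is_dup[i]:
            # near-duplicate: same case, later version, country possibly perturbed
            dup = SafetyReport(
                report_id=f"R{i:08d}-2",
                case_id=base.case_id,
                drugs=drugs,
                reaction_pts=pts,
                age_years=base.age_years,
                sex=base.sex,
                country=country_labels[dup_country_idx[i]],
                year=base.year,
                outcomes=outs,
            )
            reports.append(dup)
    return ReportCollection(reports, provenance=f"synthetic(seed={seed}, n={n})")


def truth_table(config: SynthConfig) -> pd.DataFrame:
    """Closed-form expected 2×2 cell proportions and true ROR/PRR/IC for
    every declared (drug, event) pair under the generative model.

    Cell proportions refer to the deduplicated collection (duplicates are
    exact copies at the case level, so they do not change proportions).
    Clamped probabilities enter as their effective (clamped) values,
    matching what :func:`generate` actually draws.
    """
    p_bg = 1.0 - sum(d.marginal for d in config.drugs)
    rows = []
    for ev in config.events:
        # event probability marginalized over the primary-suspect drug
        p_event_by_drug = {d.name: config.effective_q(d.name, ev) for d in config.drugs}
        p_event_any = sum(d.marginal * p_event_by_drug[d.name] for d in config.drugs) + p_bg * ev.baseline
        for d in config.drugs:
            qa = p_event_by_drug[d.name]
            pa = d.marginal * qa
            pc = d.marginal * (1.0 - qa)
            pb = p_event_any - pa
            pd_cell = 1.0 - pa - pb - pc
            # a clamped probability of 1 empties the c cell: true ROR diverges
            ror = math.inf if pc == 0 else (pa / pb) / (pc / pd_cell)
            prr = (pa / (pa + pc)) / (pb / (pb + pd_cell))
            ic = math.log2(pa / ((pa + pb) * (pa + pc)))
            rows.append({
                "drug": d.name, "pt_code": ev.pt_code, "term": ev.term,
                "rr_nominal": config.rr(d.name, ev.pt_code),
                "rr_effective": qa / ev.baseline,
                "p_a": pa, "p_b": pb, "p_c": pc, "p_d": pd_cell,
                "expected_a": config.n_reports * pa,
                "true_ror": ror, "true_prr": prr, "true_ic": ic,
            })
    return pd.DataFrame(rows)


def write_faers_tables(collection: ReportCollection, out_dir: str | Path, dialect: str = "dollar_delimited") -> dict[str, Path]:
    """Emit the four FAERS-style tables so the full reader path is exercised."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.txt" for name in ("demo", "drug", "reac", "outc")}
    write_reports(collection, paths["demo"], paths["drug"], paths["reac"], paths["outc"], dialect=dialect)
    return paths
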