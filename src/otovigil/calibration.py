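"""Seeded replicate experiments on synthetic data: coverage, calibration,
and end-to-end planted-signal recovery.

These are the package's own statistical self-checks.  Each experiment
generates independent synthetic collections under a known generative truth
and measures a frequency over replicates:

* :func:`ror_ci_coverage` — how often the estimated 95% ROR confidence
  interval covers the generative true ROR (nominally ~95%);
* :func:`null_prr_criterion_rate` — how often a *null* pair (planted rate
  ratio 1) satisfies the full PRR positivity rule (PRR ≥ 2, χ² ≥ 4, N ≥ 3);
  a well-calibrated rule fires rarely under the null;
* :func:`planted_signal_detection_rate` — how often a strongly planted pair
  is flagged an overall signal by the any-of-three-algorithms rule after a
  full generate → dedup → classify → score pipeline pass.

Replicate seeds derive from a root seed via SeedSequence spawning, so each
experiment is reproducible from one integer.
"""

from __future__ import annotations

import numpy as np

from .disproportionality import build_contingency, compute_ror, evaluate_signal
from .report_store import deduplicate
from .synthetic import DrugSpec, EventSpec, SynthConfig, generate, truth_table

__all__ = [
    "ror_ci_coverage",
    "null_prr_criterion_rate",
    "planted_signal_detection_rate",
    "pair_config",
]

_PT = 10043882  # Tinnitus: the experiments' stand-in suspect event


def _child_seeds(seed: int, n: int) -> list[int]:
    # keep spawned seeds in the signed-32-bit range for portability
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n, dtype=np.uint64)]


def pair_config(
    rr: float,
    n_reports: int,
    seed: int,
    drug_marginal: float = 0.2,
    baseline: float = 0.03,
) -> SynthConfig:
    """A two-drug, one-event configuration: 'suspect' carries the planted
    rate ratio, 'comparator' stays at the null."""
    return SynthConfig(
        n_reports=n_reports,
        drugs=[DrugSpec(name="suspect", marginal=drug_marginal),
               DrugSpec(name="comparator", marginal=drug_marginal)],
        background_drug_pool=50,
        events=[EventSpec(pt_code=_PT, term="Tinnitus", baseline=baseline)],
        planted_rr={"suspect": {_PT: rr}} if rr != 1.0 else {},
        p_duplicate=0.05,
        seed=seed,
    )


def _pair_table(config: SynthConfig, drug: str):
    coll = deduplicate(generate(config))
    return build_contingency(coll, drug, lambda r: _PT in r.reaction_pts)


def ror_ci_coverage(rr: float = 5.0, n_reports: int = 1500, n_replicates: int = 500, seed: int = 0) -> float:
    """Percent of replicates whose 95% ROR CI covers the generative truth."""
    hits = 0
    for s in _child_seeds(seed, n_replicates):
        config = pair_config(rr, n_reports, s)
        truth = truth_table(config).set_index("drug").loc["suspect", "true_ror"]
        _, lo, hi = compute_ror(_pair_table(config, "suspect"))
        hits += lo <= truth <= hi
    return 100.0 * hits / n_replicates


def null_prr_criterion_rate(n_reports: int = 2000, n_replicates: int = 500, seed: int = 0) -> float:
    """Percent of null pairs meeting the full PRR rule (PRR ≥ 2, χ² ≥ 4, N ≥ 3).

    Both drugs are null (rate ratio 1) with expected co-occurrence count
    ≥ 20, so each replicate contributes two pair evaluations.
    """
    fired = total = 0
    for s in _child_seeds(seed, n_replicates):
        config = pair_config(1.0, n_reports, s)
        coll = deduplicate(generate(config))
        for drug in ("suspect", "comparator"):
            table = build_contingency(coll, drug, lambda r: _PT in r.reaction_pts)
            fired += evaluate_signal(table).prr_positive
            total += 1
    return 100.0 * fired / total


def planted_signal_detection_rate(
    rr: float = 6.0,
    n_reports: int = 20_000,
    n_replicates: int = 100,
    seed: int = 0,
    drug_marginal: float = 0.04,
    baseline: float = 0.004,
) -> float:
    """Percent of replicates flagging the planted pair by any algorithm."""
    flagged = 0
    for s in _child_seeds(seed, n_replicates):
        config = pair_config(rr, n_reports, s, drug_marginal=drug_marginal, baseline=baseline)
        table = _pair_table(config, "suspect")
        flagged += evaluate_signal(table).positive
    return 100.0 * flagged / n_replicates
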