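# Methods

## The problem and the model

Spontaneous-reporting databases such as FAERS collect voluntary reports
linking drugs to adverse events. They have no denominator — no count of
exposed, unaffected patients — so risk cannot be estimated directly.
Disproportionality analysis substitutes an internal comparison: for a drug
D and an event class E, the deduplicated report collection is partitioned
into a 2×2 table

|              | event E | other events |
|--------------|---------|--------------|
| drug D (primary suspect) | a | c |
| other drugs  | b | d |

and the question becomes whether E is reported more often *with* D than the
background reporting of E would predict. "Drug D" means the primary-suspect
role only; secondary-suspect, concomitant and interacting entries do not
count toward exposure. The comparator universe for b and d is the entire
ingested collection. The counting unit is always the report: a report with
several event-class PTs contributes 1 to a, though it contributes 1 to each
PT in the per-PT breakdown.

Three standard scores are computed per pair, each with its conventional
positivity rule; a pair is a signal when **any** rule fires:

* **ROR** = (a/b)/(c/d), with the log-symmetric Wald interval
  exp(ln ROR ± 1.96·s), s = √(1/a + 1/b + 1/c + 1/d).
  Positive when the CI lower bound > 1 and a ≥ 2.
* **PRR** = (a/(a+c))/(b/(b+d)), paired with the four-cell Pearson χ² of
  the table. Positive when PRR ≥ 2, χ² ≥ 4 and a ≥ 3.
* **BCPNN IC** = log₂[a·N/((a+b)(a+c))], the observed-to-expected
  co-reporting ratio on the log₂ scale, with lower limit IC025.
  Positive when IC025 > 0.

## Numerical and definitional choices

**IC025.** The default evaluates IC025 = exp(ln IC − 1.96·s) = IC·e^(−1.96·s),
a multiplicative shrinkage of the IC point value. This formula is only
defined for IC > 0; for IC ≤ 0 the limit is reported as not evaluable (NaN)
and the BCPNN flag is false. A consequence worth knowing: since e^(−1.96·s)
is positive, this IC025 keeps the sign of IC, and IC > 0 is algebraically
equivalent to ad > bc, i.e. ROR > 1 — so under this mode the BCPNN flag
fires exactly when the ROR point estimate exceeds 1, regardless of
precision. The classical credible-interval-style alternative
(`ic_mode="ic_minus_2sd"`, IC − 1.96·s on the log₂ scale) does not have
this property and is available as a switch; the multiplicative form is the
default because it is self-consistent with the published score pairs this
package mirrors.

**χ².** The Pearson statistic is the full four-cell sum with expected
counts from the margins and no continuity correction. A literal
single-cell reading ((a−E_a)²/E_a only) is preserved behind
`chi2_mode="a_cell_only"`; the default is the standard four-cell practice.
χ² is always computed on the raw counts. A zero margin makes the statistic
degenerate; it is reported as 0 with a flag rather than raised.

**Zero cells.** The Haldane–Anscombe correction (+0.5 to all four cells)
is applied to ROR, PRR and IC point and interval estimates whenever any
raw cell is zero, and flagged in the result. This keeps ratio estimators
finite without distorting the test statistic, which stays on raw counts.

**Deduplication.** One report is kept per case identifier: the
lexicographically greatest report_id, a deterministic stand-in for "the
most recent version supersedes". The operation is idempotent and preserves
the set of distinct case identifiers.

**Drug-name normalization** is lowercasing, whitespace trimming, stripping
of a trailing salt/ester word from a fixed list, and an explicit synonym
map. No fuzzy matching: reproducibility is preferred over recall.

**SMQ matching** is by 8-digit numeric PT code, with a case-insensitive
exact-term fallback; never substring matching. The packaged narrow
hearing-impairment SMQ carries 56 preferred terms.

**Descriptives.** Percentages use the full cohort (unknowns included) as
denominator and are rounded half-up to 2 decimals with `decimal` so the
printed tables are identical across platforms. Age bins are <45, 45–59,
60–74, ≥75, unknown; the mean and SD (sample, n−1) use known ages only.
Unknown age is an explicit marker, never 0. Reporting-year periods are the
four 2003–2023 bins; years outside fall into "other" rather than erroring.

**Outcome comparisons.** Per-drug outcome rates use the drug's full
SMQ-positive primary-suspect cohort as denominator (not only reports with
some outcome recorded). Pairwise 2×2 comparisons use Fisher's exact test —
two-sided, defined as the sum of all table probabilities not exceeding the
observed table's — when any expected cell is ≤ 5 (the boundary case is
included deliberately: exact inference is the safer choice at exactly 5),
and Pearson's χ² otherwise. Bonferroni correction multiplies each raw p by
the number of pairwise tests performed for that outcome (recomputed when a
drug with an empty cohort is excluded); it is applied per outcome, not
across outcomes. The omnibus test is a Pearson χ² on the drugs × {outcome,
no outcome} table.

## The synthetic report generator

`otovigil.synthetic` emulates the structure of a FAERS extract so every
pipeline stage is testable without external data. Per report: one
primary-suspect drug is drawn from declared marginals (remaining mass goes
to a numbered background pool); each declared event PT is included
independently with probability min(1, baseline × rr(drug, event)), where
rr is the planted reporting-rate ratio; one background (non-SMQ) reaction
PT is always added so the ≥1-reaction invariant holds without touching
declared-pair cell counts; demographics (per-drug age normal, male
fraction, country distribution, uniform year) are drawn with configurable
missingness; outcome codes are per-outcome Bernoulli draws; with
probability `p_duplicate` the report is emitted twice under one case
identifier with distinct report_ids and a possibly perturbed country, so
deduplication is exercised on near-duplicates.

All randomness is counter-based: one Philox stream per (seed, field), with
only fixed-size uniform draws (other distributions via inverse CDF), so
report k depends only on (seed, field, k) — enlarging the collection
appends reports without reshuffling earlier ones, and identical seeds give
byte-identical collections.

The stock configuration (`default_config`) plants four ED-class drugs with
marginals 3%, 2%, 0.6% and 0.08% of reports, five genuine hearing-SMQ
events at baselines 0.06–0.4% per report, and per-drug rate ratios 2.9,
3.5, 3.2 and 6.5 — the magnitudes this drug class shows — over a 100-drug
background pool, with 40% missing age, 5% missing sex, 10% duplicate rate
and ~1.5 co-medications per report.

`truth_table` gives the closed-form expected cell proportions implied by
the model (events are conditionally independent given the drug — a
deliberate simplification; only the marginal 2×2 structure matters for the
estimators) and the true ROR/PRR/IC per pair, used by the recovery tests.
A probability clamped at 1 empties the c cell, so the true ROR diverges;
the table reports the clamped effective rate ratio and an infinite ROR.

**What the generator does not emulate** — and hence what passing tests do
not show about real FAERS data: secular reporting trends and event
correlations (e.g. tinnitus co-reported with hearing loss), MedDRA
versioning drift, reporter-type effects, masking by competing signals,
geographic reporting artifacts, and true under-reporting structure.
Calibration results on synthetic data certify the statistical machinery,
not the epidemiology.

## Self-calibration experiments

`otovigil.calibration` runs seeded replicate experiments on the two-drug,
one-event configuration (20% marginal per drug, 3% event baseline unless
noted), with child seeds spawned from one root seed:

* **CI coverage**: with a planted rate ratio of 5 and ~45 expected
  co-occurrences (1,500 reports), the 95% ROR interval should cover the
  generative truth in ≈95% of 500 replicates (accepted band 92–98%).
* **Null calibration**: with rate ratio 1 and ~20 expected co-occurrences
  (2,000 reports), the full PRR rule (PRR ≥ 2, χ² ≥ 4, N ≥ 3) should fire
  in well under 5% of 500×2 pair evaluations.
* **End-to-end detection**: a planted rate-ratio-6 pair (4% drug marginal,
  0.4% baseline, 20,000 reports — ≈48 expected co-occurrences) should be
  flagged by the any-of-three rule in ≥95% of 100 full pipeline passes.

Replicate sizes were chosen to give each experiment its stated expected
co-occurrence counts at desk scale; the same functions accept larger sizes.

## Known limitations

* The multiplicative IC025 inherits the sign-preservation property above;
  users wanting a conservative Bayesian lower bound should switch to
  `ic_minus_2sd` (or a full posterior method, out of scope here).
* Published headline counts from the real database are not reproducible
  here by design: the package analyzes its own ingested collections, and
  the synthetic generator defines its own ground truth.
* The four-table reader supports the delimited quarterly layout only (no
  SGML/XML dialects, no network retrieval).
* Fisher's exact test is two-sided by the sum-of-small-p definition;
  mid-p and conditional-maximum-likelihood variants are not offered.
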