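# Methods

`carepath` re-implements, as a tested pipeline, a record-linkage analysis of
emergency ambulance attendances for mental-health and self-harm crises:
constructing coded care pathways from linked service contacts, selecting an
index cohort, and quantifying repeat attendance, self-discharge and one-year
mortality. Because person-level linked health records cannot be shared, the
package ships a calibrated synthetic generator; every downstream stage is
exercised and validated against generated data.

## Data model

Five CSV tables joined by `person_id`: persons (date of birth, sex,
residency), ambulance calls (class **S**, with the final AMPDS dispatch code
and optional alcohol / drug / priority / transport flags), emergency-
department attendances (class **E**, with a disposition: completed,
self-discharge, or admitted), inpatient admissions (acute wards map to class
**A**, psychiatric to **M**), and death records (date plus a coarse cause:
suicide, mental & behavioural, other). Timestamps are ISO-8601 at minute
resolution — sufficient for 24-hour chaining and minute-scale length-of-stay
medians. Boolean flags absent from a file read as false, so the known
under-reporting of optional clinical flags is representable directly.

## Pathway construction

A *continuous care pathway* is a maximal chain of one person's contacts in
which each contact starts within `gap_hours` (default 24, boundary
inclusive) of the previous contact's end — of its start when no end is
recorded. The source material does not state whether the gap is end-to-start
or start-to-start; end-to-start is the default here and the parameter is
exposed. Ties on start time break by class order S < E < A < M (an ambulance
precedes the ED it delivers to), then by contact id. Overlapping episodes
are chained in start order and logged rather than rejected.

Pathways encode as the concatenated class letters truncated at 11
characters; contacts beyond the 11th stay attached (interval metrics use
them) but are absent from the code string. A pathway with several
inclusion-coded ambulance calls is duplicated, one row per call, each row
anchored at that call. Classification reads the anchored suffix exactly:
`S`, `SE`, `SEA`, and `SEM`/`SM` (grouped) are the named classes; any other
suffix is OTHER. Anchored-suffix reading means pre-anchor history is
retained but never changes the class.

## Cohort selection

Mental-health calls are ambulance contacts whose *final* AMPDS code is on a
ten-entry inclusion list (hanging; two jumper fall codes; intentional
poisoning; six psychiatric chapter-25 codes). Chapter `23` is a chapter-level
entry: the default `prefix` matching mode accepts any code beginning `23`,
and an `exact` mode is available. The index cohort takes each person's
earliest qualifying call in the index year (boundaries inclusive), keeping
residents aged ≥ 16 — attained age in completed years, birthday inclusive,
reflecting the age-of-legal-capacity framing. Exclusions are tallied by
reason so that cohort + exclusions = distinct callers, exactly.

## Follow-up

Person-period conversion produces one row per cohort member listing all
subsequent ambulance calls. Repeats are **all-cause** by default (repeat
calls need not carry a mental-health code; an MH-only flag exists), counted
within ≤ 365 days of the index timestamp and binned
0/1/2/3/4/5–9/10–14/≥15. Deaths categorize as *within one day* (on the
index calendar date or the next) or *later within the year* (≤ 365 days);
the categories are mutually exclusive, a death dated before the index is
flagged, and persons dying in-year still contribute their pre-death repeat
calls — raw counts, no person-time adjustment. Two exposure/outcome tables
feed the tests: self-discharge at the index pathway × any repeat call
(over persons whose index pathway ended at an ED attendance, exposed =
self-discharged, unexposed = completed treatment), and alcohol flag on the
anchor call × self-discharge (over all ED-ending pathway rows).

## Statistics

Medians and quartiles use linear interpolation between order statistics
(the common package default; the source convention is unstated, so printed
IQRs are matched only approximately and never asserted exactly). The 2×2
test is Pearson's chi-squared without continuity correction (df = 1; a
Yates-corrected variant sits behind a flag), computed by the closed form
n(ad−bc)²/(r₁r₂c₁c₂). Relative risk is (a/(a+b))/(c/(c+d)) with a
log-normal 95% CI. The two-sample rank-sum test uses mid-ranks, a
tie-corrected variance n₁n₂/12·[(N+1) − Σ(t³−t)/(N(N−1))], a signed z for
the first sample (positive when it ranks larger) and two-sided normal p.
The test suite cross-checks each statistic against an independent
implementation (scipy, statsmodels) and, for the rank-sum test, against an
exhaustive permutation oracle: sign agreement is exact, and the asymptotic
p agrees with the exact *mid-p* (the finite-sample counterpart of the
uncorrected z) within 0.10 for samples up to seven — at such sizes an
asymptotic p cannot track the discrete exact p in relative terms, so the
agreement contract is absolute.

## Synthetic generator

The generator emulates the marginal structure the study reports, at any
cohort size:

- **Repeat-call distribution** — per-person repeat counts drawn from the
  observed bin frequencies (3564/1294/646/366/218/459/155/100 over 6802);
  within-bin placement is uniform, and the open ≥15 bin materializes as
  15–101 calls. Repeat calls land in evenly spaced, jittered slots between
  25 h after the index pathway closes and day 365, so distinct calls almost
  never chain accidentally.
- **Pathway mixture** — index and repeat calls alike spawn pathways from
  the observed class mixture (800/3369/995/656/982 over 6802). SEM vs SM
  within the grouped class is an even split (the split is unreported).
  OTHER pathways materialize as `S` followed by 2–10 letters from {E, A, M}
  — no second ambulance call, so repeat counting stays exact — rejecting
  collisions with the named classes. Intra-pathway gaps are uniform on
  (5 min, 20 h), keeping the 24-h rule true by construction.
- **ED length of stay** — log-normal with σ = 0.6, re-parameterized so the
  median equals the configured target (150.7 min completed, 100.5
  self-discharge). Only medians are calibrated; the implied IQRs are
  approximate. Admission stays are log-normal around 1 day (acute) and
  8 days (psychiatric), σ = 0.7.
- **Self-discharge and its couplings** — the configured self-discharge
  probability (0.17) is the *marginal* over ED-ending pathway rows. The
  unexposed baseline is solved as p₀ = p/(1 − a + a·RR) with a the alcohol
  prevalence and RR = 1.49, exposed p₁ = p₀·RR (capped at 1, logged). The
  same construction couples index self-discharge to repeat calling
  (RR = 1.25) using the realized exposure fraction, adjusting only the
  0-vs-≥1 split and leaving the conditional bin shape intact. Solving the
  baselines from the marginals lets the analysis recover the configured
  marginals *and* both risk ratios simultaneously; scaling the configured
  value directly would inflate the marginals.
- **Alcohol intoxication** is a person-level propensity (prevalence
  0.2015): all of a person's calls share the flag. Alcohol-related
  presentations cluster strongly within individuals, and a shared flag
  keeps the alcohol/self-discharge coupling intact even when a frequent
  caller's episodes chain into one pathway. The call-level marginal equals
  the configured prevalence.
- **Mortality** — independent per-person draws: within-one-day deaths
  (39/6802) on the index date or the next day; later deaths (240/6802)
  uniform on days 2–365; causes from the 97/64/118-of-279 mix. Deaths are
  drawn independently of calling behaviour and calls are not censored at
  death (validation surfaces post-death contacts as warnings, not errors),
  mirroring the raw-count follow-up convention.
- A configurable fraction of persons (default 0.05) is generated under 16
  to exercise the exclusion path; 20% of repeat calls carry a
  non-inclusion dispatch code (repeats are not all mental-health-related).

Generation is a pure function of the configuration including its seed; the
same seed yields a field-identical bundle and byte-identical pipeline
output.

### What the generator does not emulate

No seasonality, geography or deprivation structure; no joint distribution
for triage categories (they are independently missing at the observed
33.9% rate); no initial-vs-final dispatch code dynamics; no correlation
between mortality and pathway class or calling intensity. Passing
parameter-recovery tests therefore shows the pipeline measures faithfully
what the generator encodes — not that real linked data share these joint
structures.

## Reporting

Tables store exact counts and percentages; disclosure control is applied
only at render time: counts strictly between zero and the threshold
(default 15 in disclosure mode) print as `< 15`, sub-1% percentages as
`< 1`, totals never suppressed. Percentages round half-up at per-column
precision matching the published layouts. Internal totals must reconcile
with the cohort size — a mismatch raises, it does not warn.

## Problem sizes and numerical choices

Property and recovery tests run at 800–20 000 synthetic persons; 20 000 is
the package's standard desk-scale recovery size, at which every configured
proportion is recovered within three binomial standard errors, the risk
ratios within ±0.15, and the ED length-of-stay medians within ±5 min. The
chaining engine is verified against a brute-force partition oracle on all
gap layouts of up to five contacts straddling the 24-h boundary; the
classifier against exhaustive suffix enumeration. Degenerate inputs are
contracts, not crashes: empty bundles flow through every stage and produce
empty outputs, degenerate 2×2 tables are flagged with the RR undefined, and
an all-tied rank-sum input raises a zero-variance error.

## Known limitations

The upstream probabilistic/deterministic record linkage is out of scope —
`person_id` is assumed pre-linked. Initial (pre-confirmation) dispatch
codes and free-text mental-health mentions are not modelled, matching the
final-code scope of the analysis. The published statistics that depend on
unpublished cell values (χ² = 5.24 and 35.4) are validated by parameter
recovery on synthetic data, not reproduced exactly. No survival modelling
or standardized mortality ratios are attempted.
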