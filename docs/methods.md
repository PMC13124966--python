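# Methods

## Scope and data model

The package operates on spontaneous-report bundles: linked tables of
report versions (DEMO), drug entries with role codes PS/SS/C/I (DRUG +
THER start dates), reaction preferred terms (REAC), serious outcomes
(OUTC) and indications (INDI), keyed by PRIMARYID with CASEID linking
versions of one case. Only the post-2014 FAERS ASCII layout is read;
earlier LAERS-era layouts are out of scope, with a tab-delimited
`simple-tsv` dialect as the portable fixture format. All identifiers
are strings (ids exceed 32-bit ranges and may be zero-padded). Dates
are kept as YYYYMMDD/YYYYMM/YYYY strings: a partial date is *unknown at
day level*, never coerced to a day, so timeline rules and time-to-onset
simply skip it. Readers are non-judgemental — a decade-coded age of 65
is stored as 650 years and left to the cleaning stage — and never drop
rows silently: malformed and orphaned rows are quarantined with counts
satisfying rows_in = loaded + quarantined per table.

## Cleaning

The pipeline order is fixed: synonym normalization → deduplication →
deleted-case removal → plausibility filters → unique-primary-suspect
selection. The order is a design choice (the rules themselves don't
impose one): deduplicating first means the retained (most recent)
version of a case is the one that decides eligibility. Each removed
report is attributed to exactly one first-matching rule, so the
cleaning report partitions its input exactly — an auditable flowchart.

* Deduplication keeps, within a CASEID, the report with the latest
  FDA_DT, breaking ties by the numerically larger PRIMARYID. Reports
  without a CASEID are treated as singleton cases and logged.
* "Non-adverse-event report" is operationalized as: no reaction rows at
  all, or every PT in a configurable administrative-term list (shipped
  as an editable text file). The underlying notion ("unverifiable AE
  severity") has no standard operational definition; this one is
  explicit and editable.
* The study window (default 2004Q1–2024Q4 receipt dates) and the
  plausible age range [0, 120] years are configuration, not code.
* Unique-PS selection keeps reports where the target is the *only*
  primary-suspect drug; reports with several PS drugs, or the target
  only as SS/C/I, are excluded. For screening, the analysis universe
  is those qualifying reports plus all reports never mentioning the
  target (full-database comparator); target-mentioning non-qualifying
  reports are excluded entirely so that "exposed" is exactly the
  unique-PS series. An SS-inclusive selection is deliberately not the
  default.

## Contingency counting

The counting unit is the report–term pair: a report listing a PT twice
counts once, and at SOC level all of a report's PTs sharing a System
Organ Class collapse to one (report, SOC) pair. PT→SOC mapping uses
the primary SOC only (multi-axiality collapsed) and is supplied by the
user — MedDRA is licensed and not bundled; unmapped PTs are routed to
an explicit UNMAPPED bucket. Both the pair total and the distinct
report total are recorded so either denominator convention can be
compared downstream.

## Disproportionality estimators

Standard literature forms, each switchable in configuration:

* ROR with the Wald CI on the log scale; PRR paired with the Pearson χ²
  (Yates continuity optional, off by default). Zero cells trigger the
  Haldane +0.5 correction on all four cells for the ratio estimators
  only; χ² always uses raw cells, keeping it a pure Pearson statistic.
  With the correction disabled, zero-cell results are NaN markers.
* BCPNN information component: the closed-form shrinkage
  IC = log₂((a+½)/(E+½)) with credibility bound
  IC025 = IC − 3.3(a+½)^−½ − 2.0(a+½)^−1 as default; the classic
  moment-approximation posterior (Gaussian on the IC with the standard
  hyperparameters) is available as `ic_variant="moment"`.
* MGPS/EBGM: λ ~ p·Gamma(α₁,β₁) + (1−p)·Gamma(α₂,β₂) (rate
  parameterization), counts Poisson(λE), hence negative-binomial
  marginals. Hyperparameters maximize the summed marginal
  log-likelihood over all cells at one MedDRA level (PT and SOC fitted
  separately — the cell universes differ). Optimization is Nelder-Mead
  on (log α₁, log β₁, log α₂, log β₂, logit p) from three fixed starts
  (DuMouchel's classic (0.2, 0.1, 2, 4, ⅓) among them), best kept;
  parameters are clamped to |log θ| ≤ 20 because beyond that the
  gammaln differences lose all floating precision and fabricate
  likelihood. The posterior is the conjugate two-component gamma
  mixture; EBGM = exp(E[ln λ | a]) via the digamma expectation, and
  EBGM05 is the 5th percentile of λ itself (equivalent under
  monotonicity to the percentile of log₂λ), found by bracketed root
  search on the mixture CDF with 1e-12 absolute / 1e-9 relative
  tolerance.

**Combined rule.** A term is a signal when ≥2 of the four methods are
positive *and* the positives include at least one frequentist and one
Bayesian method (defaults: ROR lower CI > 1 with a ≥ 3; PRR ≥ 2 with
χ² ≥ 4 and a ≥ 3; IC025 > 0; EBGM05 > 2). Signals with a ≥ 100 are
tiered "prioritized", others "exploratory" — a tier, not a filter, so
nothing is hidden. The one-method ROR rule is computed as a separate
flag; both definitions coexist because both are in common use.
Undefined statistics count as not positive, which makes the rule
monotone: adding a positive method can never withdraw a signal. No
multiplicity correction is applied across terms (none is standard in
this screening tradition); the outputs are hypothesis-generating.

## Subgroups and sensitivity

Stratification: sex (M/F), age [0,18), [18,65), [65,∞) — the 65th
birthday goes to the elderly bin — and reporter type (healthcare
professional = physician, pharmacist, other health-professional,
registered nurse or the generic health-professional code; versus
consumer). Reports missing the dimension form a counted "missing"
stratum that is not screened. Each stratum is screened against its own
background; comparisons across strata are descriptive (CI overlap) —
no interaction tests, deliberately. The descriptive characteristics
table uses finer age bins (<18, 18–64, 65–85, >85) matching the usual
presentation; the screening bins are the coarser clinical ones.

The sensitivity analysis removes every report listing any of a
configurable co-medication set (default cisplatin, carboplatin,
pembrolizumab, bevacizumab) in any role, then re-screens.

## Time-to-onset

TTO = EVENT_DT − START_DT in days, START_DT being the earliest
full-precision start date among the target drug's rows. Only full-
precision, non-negative delays within a 10-year plausibility cap enter;
exclusions are counted. Two accounting modes exist (one sample per
report, or one per report–PT pair) because the attribution of a single
onset date to multiple PTs is ambiguous; per-report is the default.

The Weibull fit is maximum likelihood on (log α, log β) (Nelder-Mead;
moment-style start from the log-sample SD), with CIs from the observed
information matrix — normal approximation on the log parameters,
exponentiated, which keeps both positive. Zero-day onsets are shifted
to 0.5 days for likelihood validity (the Weibull support is t > 0 but
same-day onsets are real). Failure typing uses the shape CI: entirely
below 1 → early failure, above 1 → wear-out, spanning 1 → random.
CDF(α) = 1 − 1/e identically, a useful self-check exposed in the
summary.

There is **no censoring model**: a spontaneous-report database contains
only realized, reported events, so the "cumulative incidence" is a
plain ECDF conditional on an event having been reported — not a
survival analysis, and deliberately labelled as such. Strata are
compared with the log-rank test (all observations events); the test
choice is recorded in the output. Bimodal onset mixtures are out of
scope: a single Weibull is fitted even when the histogram suggests a
secondary late peak.

## Synthetic data and what passing tests mean

The generator draws, per report: a PS drug from a categorical marginal;
1 + Poisson(μ=2) PTs i.i.d. from the event marginal tilted by the
planted relative reporting ratio ρ for the report's PS drug and
renormalized (ρ ≡ 1 off the planted pairs); Poisson(1.5) co-medications
from a separate co-drug vocabulary (never the PS universe, so planted
associations are independent of co-medication by construction); sex /
age / reporter / country from categorical marginals and serious
outcomes as non-exclusive Bernoullis, defaults matching a large
pemetrexed case series (54.8% male, 24.1% age missing, 22.4% consumer
reports, 34.0% hospitalization, 18.5% death, 65.3% lung-neoplasm
indication); therapy start uniform over 2005–2023; onset delay from
Weibull(α=57.99 days, β=0.69); receipt 0–90 days after the event; event
dates missing at rate 0.2 (matching the ~20% of reports unusable for
TTO in practice) and start/event dates truncated to partial precision
at rate 0.05 each; a 5% fraction of reports cloned under the same
CASEID with a strictly later FDA_DT and larger PRIMARYID.

Expected 2×2 cells have the closed form: a report whose PS drug gives a
PT probability q mentions that PT with probability
h(q) = 1 − (1−q)·exp(−μq), so the expected exposed count is
n·P(drug)·h(q), and margins follow by summation. These expectations
are the test oracle: empirical tables from a 50,000-report draw agree
with them to sampling error, planted pairs with ρ > 1 have expected
ROR > 1, and with no planting the combined rule flags ≤5% of terms.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: reporting-latency dynamics and secular
trends, country effects, free-text narratives, drug-name misspellings
beyond the synonym table, correlated event co-reporting (PTs are
conditionally independent given the drug), masking/competition between
drugs, and duplicate reports that differ in content rather than being
clones. Calibration on synthetic nulls is a necessary, not sufficient,
condition for real-data validity.

## Numerical choices and degenerate inputs

* Random tie-breaks are avoided everywhere; sorts are stable
  (mergesort) and group orders deterministic, so identical config +
  seed reproduce outputs byte-for-byte.
* GPS fit refuses fewer than 2 usable cells and warns below 100. On
  small cell universes with one extreme outlier, the unconstrained ML
  mixture can place a near-zero-variance component on the outlier
  (the usual mixture-likelihood spike); EBGM is essentially unaffected
  (it stays ≤ a/E) but EBGM05 then sits close to EBGM for that cell —
  anticonservative. Real MGPS practice fits thousands of cells, where
  this does not arise; the <100-cell warning marks the regime.
* Weibull fitting rejects n < 2 and all-identical samples (degenerate
  likelihood); non-convergence raises with the optimizer message
  rather than returning garbage.
* Empty bundles propagate as empty results (screens, summaries,
  histograms), not errors, except where a computation is meaningless
  (SOC mapping without a map, EBGM with E = 0).
* Percentages in the descriptive table are rounded half-up to one
  decimal via exact decimal arithmetic, with the total retained reports
  as the base for every section (outcome categories overlap, so that
  section may sum past 100%).

## Problem sizes used in validation

Null calibration and planted-signal recovery run 20 independent
50,000-report databases each; mixture-prior recovery uses 50,000
simulated cells; Weibull recovery uses 10,000 draws (single-seed 3%
check) and 20 seeds of 10,000 for the 2% median-error check; estimator
agreement uses 1,000 random tables against an independently coded
reference. These sizes give stable disproportionality statistics while
keeping a full validation run in minutes on one core.
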