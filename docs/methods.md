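# Methods

This note documents the models, the numerical choices and the synthetic
data-generating process behind `pvsignal`, and what the bundled tests do and
do not establish about real spontaneous-report data.

## Report model and deduplication

A safety report is one submission to a spontaneous reporting system.  FAERS
identifies a *case* (CASEID) that may be re-submitted across quarterly
releases under new PRIMARYIDs; the canonical record per case is chosen by
the regulator's rule: keep the submission with the most recent receipt date
(FDA_DT), breaking ties by the higher PRIMARYID.  The implementation sorts
on the numeric (FDA_DT, PRIMARYID) pair within CASEID, which makes the
operation idempotent and independent of input row order; every non-retained
PRIMARYID is then dropped from all linked tables.  Deduplication is applied
database-wide before drug filtering.  JADER deduplication is defined only at
table level: byte-identical rows within DRUG and REAC are collapsed before
the DEMO linkage.

Target-drug reports are found by substring containment of normalized
synonyms (uppercase, punctuation stripped, whitespace collapsed) against
DRUGNAME and PROD_AI; FAERS free-text names make exact matching too brittle,
but an exact mode is available and is the default for JADER, whose generic
names are standardized.  Only reports where the target appears with an
accepted role code (primary suspect by default) become cases; the comparator
margins of every 2×2 table nevertheless use the complete deduplicated
universe, all drugs and all roles.

Ages are harmonized to years from AGE/AGE_COD (years, decades, months,
weeks, days, hours); unparseable values become missing.  Age groups are
<18, 18–65, >65; weight bands <50, 50–100, >100 kg.

## Disproportionality statistics

All four statistics are computed from the same report-level table
(a report mentioning k distinct PTs contributes to k tables; duplicate PT
rows within a report are collapsed):

* ROR = ad/bc, lognormal Wald CI with the Woolf SE √(1/a+1/b+1/c+1/d).
* PRR = a(c+d)/(c(a+b)); χ² is the uncorrected Pearson statistic
  (no Yates continuity correction).
* IC = log₂(aN/((a+c)(a+b))).  The 95% lower credibility bound is
  IC − 2√V(IC), where V(IC) is the Bayesian posterior-variance
  approximation with the standard non-informative priors
  (α₁ = β₁ = 1, α = β = 2, γ₁₁ = 1,
  γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁))):

      V(IC) = 1/ln²2 · [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                       + (N−(a+b)+α−α₁)/((a+b+α₁)(1+N+α))
                       + (N−(a+c)+β−β₁)/((a+c+β₁)(1+N+β)) ]

  The point estimate deliberately remains the observed/expected log₂ ratio
  rather than the shrunk posterior mean; pairing the raw IC with the
  Bayesian variance is the convention in the applied screening literature
  this package follows, and it reproduces published IC/IC025 pairs at both
  small and large counts.  A large-count profile approximation
  (IC − 3.3a^-1/2 − 2a^-3/2) is available via `ic_variance="approx"`.
* EBGM as implemented by default is the unshrunk relative reporting ratio
  aN/((a+c)(a+b)) — identical to 2^IC — with a lognormal CI on the Woolf
  SE.  A true empirical-Bayes gamma-Poisson shrinkage (two-component gamma
  mixture prior on the relative reporting rate, fitted by maximum marginal
  likelihood across all pairs; EBGM = exp E[log λ | a], EB05 the posterior
  5th percentile) is provided as `ebgm_mode="shrinkage"`.  The unshrunk
  ratio is the default because it is what the screening criteria in this
  workflow are calibrated against; the identity EBGM = 2^IC under the
  default also serves as a cross-check between two code paths.

Zero cells leave a statistic undefined (NaN, never 0), and an undefined
statistic fails its criterion.  No Haldane +0.5 correction is applied by
default; a flag enables it for exploration only.

Positivity criteria: ROR CI lower bound > 1 with a ≥ 3; PRR ≥ 2 with
χ² ≥ 4 and a ≥ 3; IC025 > 0; EBGM05 > 2.  Consensus requires all four.
Ranked output uses descending EBGM, ties broken by descending count then
lexical PT.  PTs named in a user-supplied indication list are removed before
decisions; consensus PTs absent from a user-supplied label list are flagged
unexpected (both lists are inputs — no dictionary content ships with the
package).

Bonferroni adjustment is `p·n` capped at 1 with threshold α/n, applied over
the PTs actually tested.

## Sex-stratified analysis

For each PT, the 2×2 table contrasts female vs male *within* target-drug
reports with known sex (unknown-sex reports cannot be placed and are
excluded): a/b = female reports with/without the PT, c/d = male.  ROR > 1
means female-skewed reporting.  This is a signal-strength contrast, not a
population odds ratio.  The volcano p-value is a two-sided Fisher exact test
(exact and robust to the small cells typical at PT level; Pearson χ² is a
config alternative), Bonferroni-adjusted.  The monotherapy sensitivity
filter retains reports whose drug list contains nothing but the target, in
any role, and re-screens against the unchanged background universe.

## Time to onset

TTO = EVENT_DT − START_DT in whole days, per (report, PT).  Records are
excluded — as data, with machine-readable reasons — when either date is
missing or partial (fewer than 8 digits) or the interval is negative.
Day-0 records are legitimate (exclusion is only for negative intervals);
they are kept in distributions and Kaplan-Meier curves but shifted to 0.5
days inside the Weibull likelihood, where log 0 is undefined
(`zeros="drop"` is available).  No outlier rule is applied by default.

The Weibull model S(t) = exp(−(t/α)^β) is fitted by maximum likelihood
(all records are observed events).  The 95% CI for β uses the normal
approximation on log β from the observed information, guaranteeing a
positive interval consistent with the two-decimal reporting granularity.
Failure taxonomy: early when β < 1 with CI upper bound < 1; wear-out when
β > 1 with CI lower bound > 1; random when the CI contains 1.  Under this
reading the three classes are exhaustive for any finite CI straddling or
excluding 1; "indeterminate" is reserved for the residual case and does not
occur in practice.

Subgroup timing uses the product-limit estimate per group (UNK levels
dropped) and the multivariate log-rank test; grouped summaries report
median/IQR per SOC or PT above a minimum count (40 at PT level by default)
with a Kruskal-Wallis test across groups; the long-term table counts SOC/PT
frequencies strictly beyond 360 days.

## Synthetic data generator

The generator emulates the multi-file structure of both dialects with a
deliberately simple generative model.  Per report: one primary suspect drug
uniform over `n_drugs`; independent Bernoulli event-term draws at
`background_report_rate`, multiplied for planted (drug, PT) pairs by the
planted relative risk; reports with no sampled term receive a dedicated
catch-all term (mirroring the high-frequency nonspecific terms of real
databases) so that every report has ≥ 1 reaction *without* perturbing any
per-PT marginal rate — the ratio P(PT | focal)/P(PT | other) therefore
converges exactly to the planted RR, and the reporting odds ratio to the
corresponding odds ratio (≈ 11 for RR 10 at a 1% background).  Onset is a
rounded Weibull(α, β) draw added to the therapy start; a configured fraction
of events is forced before the start (negative TTO), truncated to CCYYMM or
CCYY (partial dates), or missing.  A configured fraction of cases is
re-submitted with a strictly later FDA_DT and larger PRIMARYID — the only
duplicate mechanism modelled, since it is the one the dedup rule
distinguishes; JADER duplicates are exact re-emitted DRUG/REAC rows.

Defaults are the study conditions of real paliperidone-palmitate reporting:
sex 23.7% unknown and 41% female among known; 63% missing age, 84% missing
weight; onset Weibull(α = 69.1 d, β = 0.67), whose median α(ln 2)^(1/β) is
40 days; duplicate rate 0.15 (FAERS removes roughly this share of
submissions database-wide); background event rate 1% per PT over 50 PTs and
20 drugs, sized so a mid-size run yields a few hundred target cases.
Synthetic JADER files are UTF-8 (readers accept Shift-JIS for real files).

What the generator does *not* emulate: drug co-prescription correlation,
free-text name noise beyond case/spacing variants, sex- or age-dependent
event rates, reporting-delay trends, or MedDRA's real hierarchy (the PT→SOC
map is a bundled synthetic TSV).  Passing tests therefore demonstrate
correctness of the statistical machinery and the ingestion contracts under
known truth — not calibration against the biases of real spontaneous data.

## Numerical and design choices

* Comparator margins: full deduplicated universe (all drugs, all roles);
  restricting margins to the screened cohort is not supported.
* Statistics are computed vectorised over PTs; scalar and vectorised paths
  are cross-checked against exact rational arithmetic in the tests.
* Fisher exact p-values come from `scipy.stats.fisher_exact`; survival
  machinery from `lifelines`; the Weibull fit from `lifelines.WeibullFitter`
  with the CI transformed as described above.
* Determinism: all generator randomness flows from one seeded
  `numpy.random.Generator`; pipeline outputs are pure functions of
  (inputs, config, seed) and the run manifest (input SHA-256 hashes, seed,
  config, attrition counts) contains no timestamps, so re-runs are
  bit-identical.
* Acceptance-scale simulations use 50,000-report studies and 100-seed null
  replications at 5,000 reports — sizes at which the Monte-Carlo envelopes
  computed during development (planted-RR ROR in [8.0, 14.0]; first-month
  onset share in [0.35, 0.43] for Weibull(90, 0.67) at n = 2,000; Weibull
  shape MAE < 0.05 at n = 5,000) are comfortably discriminating.

## Known limitations

* Disproportionality quantifies reporting association, not risk or
  causality; the package deliberately stops at signal detection.
* The unshrunk EBGM overstates small-count signals relative to a true
  gamma-Poisson shrinker; use `ebgm_mode="shrinkage"` when ranking rare
  events matters.
* The sex-stratified ROR inherits all reporting biases (differential
  reporting propensity by sex is indistinguishable from differential risk).
* TTO analyses condition on complete dates, a small and probably
  non-random subset of reports.
* No probabilistic record linkage: only the regulator's CASEID rule and
  exact-row duplicates are handled.
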