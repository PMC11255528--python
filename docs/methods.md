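# Methods

## Audit model

The package models a dual-source chart audit of an HIV-care EHR
deployment. Each audited patient contributes one `RecordPair`: the same
28 variables abstracted from the paper chart and from the EHR. Three
metrics summarize agreement:

- **Completeness** per variable and source: filled fields / all fields.
- **Matching** per variable: among records filled in both sources, the
  fraction whose standardized values are equal.
- **Concordance score** per record: of 15 designated patient-specific
  variables, the count that either match or are missing in *both*
  sources (a both-missing field is treated as concordant, unlike the
  matching metric, which conditions on presence).

Facility-level quality is classified against a single threshold
(default 0.85, applied with ≥ in every rule) following a lot-quality
-assurance-sampling (LQAS) audit design: a small random sample of
charts per facility — 48 at low patient volume up to 76 at high volume
— suffices to label the facility high/low quality at that threshold.
`lqas_sample_size` maps volume to sample size by linear interpolation
between configurable knots (48 at ≤100 patients, 76 at ≥1000), clamped
so a facility never contributes more charts than it has patients. The
knot positions are a package default; any published step table can be
substituted.

### Missingness rules

A value is missing if it is blank, carries a coded "not available"
answer (configurable set; defaults are placeholders for the deployment's
actual codes), fails to parse, or — for dates — is implausible:

- a sentinel date (default {1980-01-01}, configurable; other
  deployments use other placeholders);
- a date after the chart-abstraction date (default 2018-12-01);
- for HIV-treatment-related dates (first positive test, enrollment,
  first ART, regimen starts, pickups, viral loads), a date before HIV
  care existed in the country (default 2002-01-01);
- for date of birth, a date outside 1900-01-01..abstraction.

Parsing never raises: malformed text is simply missing, and file
loading counts and logs each malformed cell.

### Standardization

- **Drug regimens** canonicalize to a sorted (drug, dose) multiset:
  separator dialect ("+", "and", commas, semicolons, slashes) and
  component order never matter; names are case-folded, accent-stripped
  and whitespace-collapsed. Duplicated components are preserved
  (multiset, not set) so "A + A + B" ≠ "A + B". No spelling correction
  is attempted — a user-supplied synonym map handles known variants.
- **Viral loads** match within an absolute 1 copy/mL on the raw
  numeric values (no prior rounding): EHR forms store whole numbers
  while lab reports may carry one decimal.
- **Dates** must agree exactly; there is no tolerance window.

### Viral-load alignment

Each source holds up to three (value, date) entries, newest first.
Entries pair iff their calendar dates are equal; an entry whose date
appears in only one source counts as missing in the other. Undated
entries never pair; a dated pair with a missing value has a
not-applicable match flag. Duplicate same-source dates pair
deterministically in position order with a logged warning. Two derived
views: *all viral loads* (per-pair match flags over the aligned series)
and *at least one viral load* (the EHR's newest value matches any of
the ≤3 paper values within tolerance, dates ignored — the value-only
reading of that definition is deliberate and flagged here for users).
The concordance score takes its most-recent VL value/date from the
aligned series by default (`use_aligned_vl=False` restores positional
slots).

## Association analyses

- **Covariate correlations** are computed at record level: each
  facility's survey covariates (EHR availability Likert 1–5,
  technology-experience score 0–4, mean years of EHR use) broadcast to
  its records and correlated with the per-record concordance score.
  Pearson r with a Fisher-z 95% CI, t = r√((n−2)/(1−r²)) on n−2 df, and
  Bonferroni adjustment p_adj = min(1, m·p) with m defaulting to the
  number of covariates tested (3). Facility-level aggregation is
  available by aggregating the returned frame, but the record-level
  form is the default because it matches the audit's reported degrees
  of freedom. Zero variance raises rather than returning NaN.
- **Alert effect**: records dated (paper last-visit date, falling back
  to the EHR) on/after the alert rollout (default 2018-07-01) are kept;
  EHR-present entries — viral-load values (matched via date alignment)
  or drug-pickup dates (matched exactly) — are cross-classified as
  match/no-match by whether the facility has the missing-VL alert
  (alert tier ≥ 2). The 2×2 chi-square uses the Yates continuity
  correction by default (both corrected and uncorrected are reported;
  on the published drug-pickup counts the corrected statistic
  reproduces the printed value, the uncorrected one is ~1 higher). The
  effect size is φ = √(χ²_uncorrected/N); its 95% CI comes from a
  seeded multinomial bootstrap over cell counts (2000 resamples,
  percentile interval), with a Fisher-z alternative. The record's
  last-visit date anchors the post-rollout filter because it is the
  only per-record visit timestamp in the variable set.

## Synthetic-data generator

`generate_dataset` draws a ground truth per patient from simple
plausible distributions (dates uniform in care-history windows, VL
log-uniform over 20..10⁶ copies/mL, regimens from a small fixed
formulary, ~4% of patients on second-line therapy) and renders both
sources from that truth through independent, labelled error processes.
Only the error structure matters for testing the pipeline; no clinical
plausibility beyond it is attempted (no disease progression or visit
scheduling).

Defaults are the audited study's shape: 50 facilities, half
intervention, 11/25 of the intervention arm with the missing-VL alert,
chart counts via the LQAS table over a lognormal volume model whose
median/σ (log 1100, 1.1) put the mean near 69 charts/facility (≈3470
records). Per-variable marginal missingness and EHR error rates default
to values that emulate the published completeness/matching pattern
(demographics ~99% complete; EHR viral loads 76/51/32% by position;
repeated dates matching ~17–28%, one-off dates ~60–75%). The VL series
uses a truth-entry count distribution (0.05, 0.09, 0.16, 0.70), a
series-level *lag* (p=0.25) in which the EHR misses the newest paper
result and shifts one slot, and per-slot EHR entry probabilities
(0.82, 0.64, 0.62) — together these compose to the positional
completeness targets in closed form (`expected_completeness`).

Date-transcription errors draw from a small-offset mixture: one-off
dates err within 30 days 36% of the time (31–90 days 20%), repeated
dates 12%/20% — corrupted dates are reflected back inside the
plausibility window so a transcription error never masquerades as a
missing value. Fractions of missing dates render as the sentinel
(rate 0.25) and of missing categorical cells as a coded-NA string
(rate 0.10). Regimen strings take an "and"-separator variant (rate
0.15) and paper VL values a one-decimal precision variant (rate 0.30);
both still match after standardization and exist to exercise it.

The **alert effect** (default 2.24) multiplies, for VL and pickup
variables at alert facilities after the rollout date, the EHR's entry
probabilities (clipping at 1), the complement of the VL lag, and the
date-correctness probabilities. The default, combined with the high
baseline VL date-error rate (0.868), was chosen so the post-rollout
VL match rates sit near the low-teens (control) vs high-twenties
(alert) regime the audit literature reports; `expected_vl_match_rate`
gives the closed form when covariate slopes are zero.

**Covariate coupling**: the EHR error rates are scaled per facility by
2/(1+exp(η)) with η = 0.12·(availability−3) − 0.08·(tech−2), so higher
reported EHR availability lowers error rates (positive concordance
correlation, r ≈ +0.18 at study scale) and higher technology experience
raises them (r ≈ −0.07); years of EHR use is deliberately uncoupled as
a negative control. Missingness is *not* covariate-scaled, keeping
completeness expectations exact. Every observed-vs-truth discrepancy
carries exactly one label (missing / sentinel / na_code / transcribed /
lagged / split / precision / wrong_value) in the `GroundTruth` sidecar.

What the generator does **not** emulate: correlated missingness across
variables (beyond the second-line-regimen presence mechanism), seasonal
visit patterns, facility-size–quality correlation, transfer patients,
or measurement error in the survey covariates themselves. Passing tests
therefore demonstrate that the pipeline recovers known error processes
of this structural form, not that real audits satisfy the same
independence assumptions.

## Numerical and design choices

- The 85% threshold is one config value applied with ≥ everywhere.
- Matching with a zero denominator reports count 0 and a
  not-applicable fraction/flag rather than 0%.
- Date-error buckets use 30/90 days for "within 1/3 months".
- The chi-square p-value comes from the χ²₁ survival function
  (`scipy.stats.chi2`); the statistic itself is the closed 2×2 form,
  with the Yates cross-term floored at zero.
- Bootstrap φ CIs are seeded; identical inputs and seeds give
  byte-identical report bundles.
- Files are delimited text with a fixed 58-column record schema; dates
  are ISO-8601 on disk with a day-first read option for sources that
  record DD/MM/YYYY.

## Test problem sizes

The suite validates at three scales, chosen to keep a full run inside a
few minutes: study scale (50 facilities, ≈3470 records) for parameter
recovery within 3 binomial SE of the closed forms; a reduced null
calibration (16 facilities, ~24 charts each, 500 replicates, VL date
error lowered to 0.6 for healthier cell counts) for the alert-effect
type-I error at α=0.05; and a mid-size power companion (32 facilities,
44–56 charts, 100 replicates) verifying ≥95% rejection at α=0.001 under
the default alert effect. Closed-form recovery checks switch the
covariate slopes and alert effect off where the expectation helpers
require it; covariate effects are then validated separately by
correlation sign and magnitude.

## Known limitations

- The volume→sample-size interpolation stands in for the published
  LQAS step table, which is not reproduced here; supply your own knots
  for a specific protocol.
- The coded-NA string set is deployment-specific and must be
  configured; the defaults are generic placeholders.
- Binomial SEs in the recovery tests ignore facility-level clustering;
  with covariate slopes active the realized covariate mix of 50
  facilities adds cluster noise on top of the binomial bound, which is
  why the closed-form checks zero the slopes.
- The alert-effect analysis treats record-entries as independent
  observations, as the underlying audit design does; no clustered
  standard errors or mixed models are provided.
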