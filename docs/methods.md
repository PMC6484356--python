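# Methods

## Scope and data model

The package estimates sex-specific median life expectancy (MLE) from
individual-level records of managed *ex situ* populations. A record is an
animal's sex, birth date, entry date (birth or acquisition), and death or
last-known-alive date. Analysis is confined to a calendar window chosen
by the analyst (`AnalysisWindow`); records become per-individual
*exposures* — (entry age, exit age, death-observed) in integer days of
age — and everything downstream operates on exposures.

Ages are whole-day differences between calendar dates; there is no
leap-year correction beyond calendar arithmetic. Window boundaries are
inclusive: a death exactly on the window's closing date is an observed
event, while a recorded death after it is censoring at the window's end
(the death is unobserved within the window).

### Record validation

Validation never hard-fails on content; it excludes and logs. A record is
dropped when its birth date is unknown, its end date is unknown, its
institution is unknown/unrecognized, or its dates are out of order (end
before birth, or entry outside [birth, end]). Each dropped individual is
logged once per applicable reason. A missing entry date is not an
exclusion: entry falls back to birth, the common case for captive-born
animals. Duplicate IDs and missing required columns are hard parse
errors, since they indicate a corrupt file rather than an uncertain
record.

### Exposure rules

Entry age = max(starting age, age at window start, age at entry date);
exit age = age at min(end date, window end). Individuals with exit age at
or below the starting age (died or left before their first birthday) or
with no time between entry and exit inside the window contribute nothing
and are dropped. Animals of unknown sex are retained and contribute only
to the overall stratum, so overall n = male n + female n + unknown-sex n,
exactly.

## Estimator

Product-limit survivorship over death ages, with survivorship 1.0 at the
starting age (default 365 days) and estimates up to the largest observed
exit age. Risk-set membership uses `entry < t <= exit`: an entrant at age
*a* is not at risk for an event at exactly *a*, the standard guard
against self-inclusion under delayed entry. Tied deaths and censorings at
one age are resolved deaths first. Events on the same day are aggregated.
Censoring-only ages are retained in the event table and exported, though
they leave the estimate unchanged.

Greenwood's formula gives the variance. When everyone at risk dies at
some age the Greenwood summand is undefined, and the variance is flagged
unavailable (NaN) from that age onward rather than silently continued.

`n_start`, the sample size in the first age class, is the maximum at-risk
count over ages [365, 730). "First age class" is read as the one-year
life-table age class starting at the analysis starting age; the maximum
(rather than the count at a fixed age) credits left-truncated entrants
arriving during the class.

## Median and confidence limits

The median is the earliest age whose estimate equals 0.5 exactly
(tolerance 1e-12, needed because the estimate is a float product of
rationals), else the linear interpolation between the death ages
bracketing 0.5. Interpolation anchors are death ages only: censoring-only
ages repeat the previous estimate and carry no information about the
crossing. If the very first death already drops the curve below 0.5, that
age is reported (the step crosses there); a curve that never reaches 0.5
has an undefined median, which feeds quality test 1.

The 95% limits invert the complementary log-log test of L(t)=0.5. Z is
taken asymptotically standard normal, i.e. the transformed deviation is
divided by sqrt(V̂) — required for ±1.96 to be meaningful. Z is evaluated
only at death ages (where the estimate changes) and is undefined where
the estimate is 0 or 1 or the variance is unavailable or zero. The
confidence set is {death ages : |Z| < 1.96}; its minimum and maximum are
the limits, each reported only when some defined-Z death age lies
strictly outside the set on that side. Otherwise the boundary was never
crossed within the observed data — the true limit lies beyond the
curve — and the limit is undefined, which feeds quality test 4. Limits
are restricted to observed event ages; no interpolation between them is
attempted, so agreement with other implementations is expected to within
one event age.

`n_at_median` (quality test 3) is the at-risk count at the exact-0.5 age
when one exists, else at the interpolation's lower-survivorship anchor
x1 — the first age at which fewer than half survive.

## Quality gating

Thresholds are strict as published: n_start of exactly 30 fails test 2
(more than 30 required), exactly 20 at the median fails test 3, and a CI
longer than 0.33 × maximum longevity fails test 5. Maximum longevity is
the analyzed stratum's largest exit age (not the whole studbook's). An
undefined CI fails tests 4 and 5. A data-deficient stratum still reports
its point estimate. Report files round years to one decimal; full
precision is retained on the result objects.

## Synthetic studbooks

The generator emulates the observation structure the estimator must
handle: births spread over decades, a first-year mortality mass, adult
lifespans of 365 + Weibull(k, λ) days, acquisitions entering after the
first birthday, and censoring at the window's close. The Weibull is a
test-harness choice for its flexible hazard shapes, not a biological
claim; its closed-form conditional median, 365 + λ(ln 2)^(1/k), is what
calibration runs recover.

Acquisition (import) sampling follows the truncated-sampling model the
delayed-entry estimator assumes: the entry age is drawn independently of
the lifespan (uniform over one lifespan scale past the first birthday),
and the lifespan from the Weibull conditioned to exceed it via the
closed-form inverse CDF. Coupling entry to the realized lifespan instead
(say, uniform over the individual's own life) makes truncation
informative — deaths are always in the risk set while long-lived
survivors often are not — and biases the estimator low by double-digit
percentages; the generator deliberately avoids it.

Defaults, chosen once as the reference study conditions: 500 animals born
uniformly 1980-01-01 to 2014-12-31, window 1980-01-01 to 2019-12-31,
first-year mortality 0.2, exponential adult lifespans (k=1, λ=3650 d,
i.e. a 10-year scale), import fraction 0.2, sex ratio 0.5, unknown-sex
fraction 0.05. Under these spans the probability that an adult death
falls beyond the window, averaged over birth dates, is ≈0.19 — so
roughly 20% right censoring and 19% left truncation arise from the
data-generating process itself rather than from a censoring dial. All
randomness flows through one seeded generator stream; the same seed
yields byte-identical studbook files.

What the generator does not emulate: pedigree structure, transfers
between institutions beyond a single entry date, cohort trends in
husbandry, or recording errors. Passing calibration therefore shows the
estimator is correct under independent truncation/censoring with clean
records; it says nothing about informatively censored or mis-dated real
studbooks, which is precisely why the record-validation and
data-deficiency gates exist.

## Calibration runs

Two standing simulation studies (module `calibration`, sizes chosen to
keep the whole suite fast while leaving Monte-Carlo error well inside the
bands): coverage of the true conditional median by the 95% CI over 500
replicates under the reference conditions (binomial SE ≈ 1 point at 95%,
against an acceptance band of 92–98%), and the median of 200 replicate
MLEs against the closed form (observed relative error well under 1%,
against a 3% band). Replicate seeds derive from one root seed.

## Species-level dataset schema

The species table schema (per-stratum sample size, MLE, 95% limits in
years, plus per-sex data-deficiency flags) is read and written with
missing cells preserved, and summarized per taxonomic group and stratum
as count, arithmetic mean and sample (n−1) SD. Sex-specific values
flagged data deficient are excluded from summaries by default, matching
the recommendation that such values be kept out of formal analysis; the
overall stratum carries no flag in the schema and always summarizes every
non-missing value. Taxa outside the six named vertebrate/invertebrate
classes are grouped as "other". The reference table itself is not
redistributable with the package; its reader is exercised on synthetic
stand-ins and, when a user supplies the table at
`data/deposited_mle_dataset.csv`, on the real thing.

## Known limitations

- CI limits are event ages, so intervals are conservative on sparse
  curves with long flat stretches.
- The exact-0.5 plateau convention (earliest attaining age) differs from
  implementations that treat a terminal 0.5 plateau as an uncrossed
  median; comparisons account for this.
- The starting-age convention makes every estimate conditional on
  first-year survival; estimates are not comparable to unconditional
  life expectancies.
- Input is the package's own delimited-text dialect; real studbook
  databases require export/conversion upstream.
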