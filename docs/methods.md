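# Methods

`accelpool` implements a standardized reduction pipeline for legacy
uniaxial Actigraph count data (models 7164, 71256, GT1M), of the kind
used to pool children's accelerometry across heterogeneous studies into
one database of comparable outcome variables. This note documents the
procedures, the tunable parameters, the synthetic-data model used for
testing, and the design choices made where the underlying conventions
were genuinely open.

## The data model

The unit of processing is an `EpochSeries`: a device-stamped sequence of
non-negative integer counts at a fixed epoch of 1–60 s. Counts are
dimensionless accelerations integrated per epoch; the legacy sensors
saturate at 32767. The timestamp of epoch *i* is always derived as
`start + i × epoch`, never stored, so a series can never carry an
inconsistent time axis. Files are plain-text: a short header (serial,
start time/date, epoch period, download stamps) followed by integer
counts. Because header layouts drifted across download-software
versions, the reader's default mode locates the four required fields by
labeled-line search; a strict mode insists on the canonical 10-line
layout the writer emits. Header dates are ambiguous across countries, so
month-first vs day-first is a dialect option rather than a guess.

Survey exports that withhold raw headers (NHANES-style) are
reconstituted from their (day, time, count) tables: start time 00:00:00,
epoch 60 s, and a start date placed in January 1–7 of the survey cycle
year so that the weekday of the true first day is preserved without
disclosing the real date. The weekday argument is explicit (ISO
1=Monday..7=Sunday) because the stitching of mid-week starts cannot be
inferred from the table itself.

## Epoch harmonization and clock changes

Sub-minute epochs are reintegrated to 60 s by block summation; a partial
trailing block is dropped and recorded in provenance, so the count total
is conserved exactly up to the logged tail. The operation is idempotent.

Recordings spanning a daylight-saving event are normalized so every
complete local-clock day has exactly 1440 minutes:

* **spring forward** — the missing hour is imputed as a copy of the 30
  minutes before the event followed by the 30 minutes after it
  (pre-block first, preserving temporal adjacency on both edges; if the
  event falls within 30 min of a recording boundary the shortfall is
  zero-filled and a warning logged);
* **fall back** — of the 120 device minutes covering the repeated hour,
  the middle 60 (minutes 30–89 of the doubled span) are retained.
  Keeping the first repetition instead is available as
  `fall_rule="first"`, since "middle hour" admits both readings.

Imputed and collapsed ranges are written to a provenance sidecar; the
affected epochs are *not* excluded from summaries (all files should be
comparable on equal terms).

Event dates/times are supplied per study through configuration rather
than derived from a timezone database: the contributing studies span
hemispheres and two decades, and explicit dates are auditable.

## Wear-time segmentation

A minute is non-wear iff it lies in some window of ≥ 60 consecutive
minutes that starts and ends on a zero count and contains at most 2
non-zero interruption minutes; all qualifying windows are unioned, and
interruption minutes inside them are non-wear too. Non-wear zeros are
thereby separated from legitimate sedentary zeros, which remain wear.
Two conventions were fixed here: window endpoints must themselves be
zero (a lone spike can never extend a non-wear block), and interruption
magnitude is unbounded by default (an optional per-minute cap,
`interruption_cap`, is available for sensitivity analyses).

The production detector is a linear-time two-pointer sweep. An
independent O(n²) oracle (`nonwear_oracle`) enumerates every candidate
window explicitly and is used in tests to certify the sweep on hundreds
of seeded random series; the two are required to agree epoch-for-epoch.

Days are local-clock midnight-to-midnight. A day is valid when its wear
minutes reach the criterion (default grid 8, 10, 12 h; the comparison is
inclusive, so 480 min passes ≥ 8 h). Partial first/last days are
reported with their true monitored minutes and may still qualify. The
valid-day tabulator reports, per sex × age group (3–5, 6–8, 9–11, 12–14,
15–18) × criterion, the percentage of participants at 0..7 valid days
(counts above 7 are capped at 7), plus ≥ 1 and ≥ 4 columns; rows sum to
100% and the identities ≥1 = 100 − P(0) and ≥4 = ΣP(4..7) hold by
construction. Empty cells are absent, not zero.

## Quality flagging

Every file receives exactly one flag with precedence
CORRUPT > NO_WEAR > TEMPORALLY_SHIFTED > SPURIOUS > OK; the report
retains the evidence of every rule that fired, including lower-precedence
ones. Parser failure is the sole corrupt criterion. NO_WEAR means zero
wear minutes after segmentation. Duplicate deposits for one participant
are resolved first: a non-corrupt file beats a corrupt one, otherwise
the lexicographically first filename wins.

The overnight-wear trigger fires when any single clock hour among
[02:00,03:00), [03:00,04:00), [04:00,05:00) contains ≥ 10 wear minutes
on any monitored day ("and/or" is read per-hour, the stricter
interpretation; summing across the three hours is a config switch).
Overnight wear has four possible causes, and the original adjudication
was visual; a reproducible pipeline needs deterministic stand-ins:

* **temporal shift** — fires only when *every* complete day shows the
  symptom pair: ≥ 10 non-zero minutes in the night block (00:00–05:00)
  *and* a zero run of ≥ 180 min in the day block (09:00–18:00). The
  shift size is estimated by circular correlation of the mean diurnal
  profile against a trapezoidal day-active template (flat 08:00–20:00,
  1-h ramps) at whole-hour lags; because the score plateaus over
  adjacent lags when the active span is wider than the template, the
  estimate is the midpoint of the ≥ 97%-of-max plateau. With these
  defaults, shifts of ≥ 5 h are detectable; smaller offsets do not
  produce the day-dominated-by-zeros symptom.
* **non-return-to-baseline** — fires when the night-block minimum count
  is > 0 on every complete day (a worn device at night shows
  interspersed zeros; a voltage offset does not). The numeric criterion
  is this package's own.
* **plateau** — ≥ 3 identical consecutive counts at a value ≥ 10
  (saturation runs at 32767 are tagged specially). Zero runs are exempt
  by the value threshold.

A shifted file is TEMPORALLY_SHIFTED; plateau or baseline-floor evidence
makes it SPURIOUS; overnight wear with none of these attributions is
treated as legitimate overnight wear and the file stays OK. Both
SPURIOUS and TEMPORALLY_SHIFTED files are *retained* in the database
with an excluded-by-default marker rather than deleted. Batch
accounting always reconciles: files presented = viable + duplicates +
missing-phenotype + no-wear + corrupt + flagged-excluded.

## Outcome variables

Counts-per-minute cutpoints map each wear minute to sedentary / light /
moderate / vigorous; intervals are lower-bound inclusive, contiguous and
exhaustive, and non-wear minutes are excluded from every total (never
counted as sedentary). Because no consensus cutpoint set exists for
children, the registry ships three widely used sets (Evenson 2008,
Mattocks 2007, Puyau 2002) with citations, and summaries can be emitted
under several sets at once; changing the set can change intensity and
bout fields but never wear minutes.

MVPA (moderate + vigorous) minutes are additionally accumulated by bout:
a bout is a maximal run of minutes at/above moderate with zero tolerated
interruptions (a tolerance parameter exists but defaults to the
strictest reading); non-wear always breaks a bout. Bout minutes bin into
[1,10) and [10,∞) — a 10-minute bout is conventionally a "10+" bout.

Every intensity variable is also reported per clock window: the 24
on-the-hour windows hr1..hr24 (half-open, so 08:59 belongs to hr9 and
the hourly windows exactly partition each day) plus arbitrary custom
windows from configuration (school commute, lunch, recess, ...), which
may overlap (logged) or wrap midnight. The per-day summary table is
always accompanied by a machine-readable data dictionary.

## Pooling

Phenotype tables are harmonized under the minimum-inclusion rule (age
and sex required per participant; rows lacking either are excluded and
flagged) and the coverage rule (an extra variable is pooled only if
declared by ≥ 3 studies, evaluated on declared columns, not non-missing
counts). Categorical responses pass through per-study recode maps;
unmapped source categories are set missing and logged, never coerced.
Unit conversions are per-study multiplicative factors.

Pooled IDs are keyed BLAKE2 hashes of (study, participant) under a
seed-derived salt: deterministic, stable across waves, collision-checked,
and re-salted if the digest would contain the source identifier as a
substring. The database is long format (one row per file-day) with keys
for participant and wave, so repeated measures need no reshaping; the
baseline view selects each participant's earliest wave (the package's
reading of "baseline"). Rebuilding on identical inputs is byte-identical
(stable sort keys, seeded IDs).

## The synthetic cohort generator

The generator emulates the study conditions the pipeline was built for:
waist-worn monitors on children aged 3–18, deployments of 2–7 days
(default 7) at epochs of 5–60 s (default 60), worn during waking hours
and removed overnight. Defaults: wake 07:00 and sleep 22:00 with
per-day jitter (wake +0..2 h, sleep −3..0 h) so daily wear spans roughly
10–15 h and the 8/10/12-h criteria genuinely discriminate; at most one
daytime removal episode per day (probability 0.4, length 60–150 min,
optionally carrying 1–2 spike minutes); activity as a minute-level
mixture of sedentary (45% of non-MVPA minutes, 60% of them zero) and
light minutes, with short spontaneous MVPA bursts (start probability
0.015/min, geometric length with mean 3 min, 30% vigorous). Counts are
drawn uniformly *within* the active cutpoint set's interval for the
minute's true category, so intensity classification recovers the truth
exactly regardless of distributional realism — a deliberate choice: the
generator certifies bookkeeping, not physiology.

Three guards keep clean files inside the detectors' identifiable regime
by construction: each wear segment opens and closes with three non-zero
minutes (no non-wear window can bleed across a wear boundary), every
aligned 15-minute wear chunk contains a non-zero minute (no 60-minute
window inside wear can satisfy the non-wear rule), and equal-count
triples at values ≥ 10 are jittered by ±1 within their category
interval (the plateau rule cannot fire by chance). Under these guards
the detected wear mask equals the generated truth exactly and clean
files are never flagged, which is what makes precision = recall = 1.0 a
well-posed requirement for artifact recovery rather than a statistical
aspiration.

Artifacts are injected at documented detectable presets: per-day
rotation by +6 h (temporal shift), a 30-epoch saturation run at 32767,
and a +30-count night floor (which is detected both as a plateau and as
a non-returning baseline — both map to SPURIOUS). Sub-threshold
parameters are permitted but labelled as such. Ground truth records the
exact wear mask, per-day intensity minutes, MVPA bout lengths and
artifact parameters; for artifact files the truth describes the
pre-injection series, since those files are flagged and excluded rather
than summarized.

What the generator does **not** emulate: realistic count
autocorrelation and spectral content, population activity levels,
seasonal and weekday effects, device-model output differences, or
gradual battery decay. Passing tests therefore certify the *reduction
logic* — rule boundaries, conservation identities, detector equivalence,
determinism — not the epidemiological realism of any summary value.

## Numerical and degenerate-input conventions

* Counts above 32767 on read produce a warning and are left to the
  cleaning stage; they are not a parse error.
* Reintegration requires the target epoch to be a multiple of the
  source; anything else is a precondition error, not a silent resample.
* Wear-rule, overnight, shift and window operations require 60-s
  epochs and refuse sub-minute input (reintegrate first).
* Series shorter than 2 complete days return "insufficient data" from
  the shift detector instead of guessing.
* Empty duplicate groups, misaligned masks, overlapping exception keys
  and orphan summary rows are hard errors.
* All randomness flows from explicit seeds (`numpy.random.default_rng`);
  generation, ID assignment and the full pipeline are reproducible
  byte-for-byte.

## Problem sizes used in the shipped checks

The test suite certifies detector/oracle equivalence on 500 seeded
random series of 2000 minutes; conservation laws on 100 synthetic files
(20 per epoch length in {5,10,15,20,30} at 2-day deployments); artifact
recovery on a 200-file cohort with 20% injected artifacts; and
end-to-end determinism on a 10-participant cohort run twice. The
acceptance script reduces a 150-file cohort (20% artifacts) end to end
and re-verifies oracle agreement on 100 further series. These sizes were
chosen to exercise every code path at full statistical coverage while
keeping a complete run in well under a minute.

## Known limitations

* "Corrupt" is operationalized as parser failure only; a file that
  parses but is physiologically impossible will surface through the
  other rules or not at all.
* The shift estimator assumes a roughly day-active diurnal profile; it
  is undefined for populations with genuinely nocturnal activity, and
  offsets under 5 h are below its symptom thresholds by design.
* The baseline-floor criterion (night minimum > 0 every day) is this
  package's proxy for what was originally a visual judgement.
* Custom clock windows (commute, recess, ...) have no shipped defaults;
  their definitions were study-specific and must come from config.
* DST handling assumes whole-hour events supplied explicitly; sub-hour
  zone offsets are out of scope.
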