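# accelpool

Standardized reduction and pooling of legacy uniaxial Actigraph count
data (models 7164, 71256, GT1M), for researchers harmonizing children's
accelerometry across studies into one database of comparable outcome
variables.

Objectively measured physical activity is stored by these devices as
integer *counts* per fixed *epoch* (5–60 s). Different studies used
different epochs, devices, deployment lengths and processing rules, so
raw files must be reduced with one standard method before their outcome
variables (wear time, minutes of moderate-to-vigorous physical activity,
valid days, ...) can be pooled. `accelpool` implements that reduction
end to end:

* **ingestion** — read/write plain-text `.dat` count files (dialect
  aware), reconstitute headerless survey exports, apply per-file
  start-date/time exception lists;
* **quality flagging** — duplicate resolution, and per-file
  classification as OK / SPURIOUS / TEMPORALLY_SHIFTED / CORRUPT /
  NO_WEAR, with rule-level evidence and full attrition accounting;
* **harmonization** — reintegration of sub-minute epochs to 60 s and
  normalization of recordings spanning daylight-saving events;
* **wear-time segmentation** — the 60-minute consecutive-zero rule with
  a tolerance of 2 non-zero interruption minutes, certified against an
  exhaustive window-enumeration oracle;
* **outcome variables** — intensity minutes under multiple
  counts-per-minute cutpoint sets, MVPA bout minutes (bouts < 10 min vs
  10+ min), hourly and custom clock-window summaries, valid-day flags at
  ≥ 8 / ≥ 10 / ≥ 12 h of wear, and sex × age valid-day tabulations;
* **pooling** — phenotype harmonization (age/sex minimum-inclusion,
  ≥ 3-study variable coverage, per-study recodes and unit conversions),
  anonymized deterministic IDs, and a long-format one-row-per-file-day
  database with a baseline view and attrition report;
* **simulation** — a synthetic-cohort generator with exact ground truth
  (wear masks, intensity minutes, bout lengths, injected artifacts), so
  the whole pipeline is testable without any study data.

The core rules, briefly: non-wear is any ≥ 60-min window of zeros with
≤ 2 interruption minutes and zero endpoints; a day is valid iff wear
≥ the criterion (inclusive); a count plateau is ≥ 3 identical
consecutive counts at a value ≥ 10 (most often at the 32767 saturation
ceiling); a temporally shifted file shows night activity plus
day-dominating zero runs on *every* monitored day. See
`docs/methods.md` for the full account, including every threshold that
is this package's own choice.

## Worked example

```python
from accelpool import (SimConfig, generate_cohort, detect_nonwear,
                       classify_file, summarize_series)
from accelpool.wear import day_wear, valid_days

cohort = generate_cohort(SimConfig(seed=7, n_participants=3,
                                   artifact_rates={"saturation_plateau": 1/3}))
for series in cohort.files:
    mask = detect_nonwear(series)              # wear/non-wear per minute
    flag = classify_file(series, mask).flag.value
    days = day_wear(series, mask)              # per-calendar-day wear
    n8 = valid_days(days, 8).n_valid
    summ = summarize_series(series, mask)      # per-day outcome table
    mvpa = summ["evenson_2008_mvpa_min"].mean()
    print(f"{series.source_name}: flag={flag:<9} wear/day="
          f"{mask.wear_minutes // len(days)} min  valid(8h)={n8}/7  "
          f"MVPA={mvpa:.1f} min/day")
```

prints

```
SYNTH_P0001: flag=SPURIOUS  wear/day=730 min  valid(8h)=7/7  MVPA=31.6 min/day
SYNTH_P0002: flag=OK        wear/day=782 min  valid(8h)=7/7  MVPA=32.3 min/day
SYNTH_P0003: flag=OK        wear/day=713 min  valid(8h)=7/7  MVPA=32.7 min/day
```

Participant 1 received an injected saturation plateau and is flagged
SPURIOUS (such files stay in the database, marked excluded-by-default);
the other two are clean, wear the monitor 12–13 h per day, all 7 days
valid at the ≥ 8 h criterion, with ~32 min/day of MVPA under the
Evenson cutpoints.

The same stages are available from the shell:

```sh
accelpool simulate --seed 42 --out data/
accelpool flag     --in data/ --report flags.tsv
accelpool wear     --in data/ --criteria 8,10,12 --table validdays.tsv
accelpool process  --in data/ --out summaries.tsv
accelpool pool     --summaries summaries.tsv --flags flags.tsv \
                   --phenotypes pheno/ --out pooled.tsv
```

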