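# flowstream

Resource-based patient **flow-stream stratification** from EMR event streams.

`flowstream` implements a four-stage analysis pipeline for classifying
hospital admissions into four resource-intensity cohorts (FS1–FS4) from
routinely collected encounter and order data:

1. **`flowstream.synthetic_emr`** — a seeded synthetic EMR generator. Produces
   encounter and event/order tables with per-stream resource archetypes
   (length of stay, consults, imaging, bloods, ICU stays, transfers,
   medications, allied health) plus ground-truth labels, and can inject
   realistic documentation defects: duplicate rows, negative durations,
   self-service consults, blanked structured fields, retrospectively
   overwritten demographics, and under-reported high-acuity (MTP) events.
2. **`flowstream.linkage_cleaning`** — cleaning rules (duplicate collapse,
   implausible-row exclusion, format standardisation, no imputation),
   deterministic time-threshold linkage of encounters into admission
   episodes (default gap threshold 6 h, transitive chaining), and
   de-identification via a separate identity-map file.
3. **`flowstream.features`** — per-episode resource-utilisation features over
   evaluation windows ending at 24 h, 72 h, or discharge: consult counts
   with self-consult exclusion, blood/imaging/IR orders, cumulative clipped
   ICU hours, critical-location and emergency-theatre flags,
   admission-anchored first-24 h counters, transfers, medications,
   polypharmacy (≥ 5 medication orders).
4. **`flowstream.classifier`** — the hierarchical rule set (FS1 → FS4 → FS2 →
   FS3 residual) with per-criterion traces, per-episode trajectories across
   the three windows, transition tables and the reclassification rate.
5. **`flowstream.reporting`** — stratified stream summaries (medians/IQRs,
   admission-type mix with mental-health exclusion), source-by-stream
   cross-tabulation, and a data-quality report (field completeness,
   self-consult rate, duplicate/implausible counts, MTP recorded÷reference
   ratio, demographic-inconsistency count).

## Stream definitions (defaults, all configurable via `RuleConfig`)

| Stream | Rule |
|---|---|
| FS1 | concluded day-procedure stay with LOS < 24 h |
| FS4 | any of: cumulative ICU ≥ 24 h; critical location (ED Resus / Theatre / ICU / Spinal); emergency theatre; CT/MR **and** ≥ 5 bloods; group-and-hold ordered; within 24 h of admission ≥ 3 external consults or ≥ 4 transfers |
| FS2 | ≤ 1 external consult, ≤ 2 total consults, LOS < 5 days (assessed provisionally while still admitted) |
| FS3 | residual: none of the above |

Streams are evaluated in that order; the first satisfied stream wins.

## CLI

```bash
# generate a seeded synthetic cohort
flowstream simulate --out-dir run/ --seed 1 --n-patients 5000 --with-defects

# clean, link (6 h gap threshold) and de-identify
flowstream link --encounters run/encounters.csv --events run/events.csv \
    --gap-hours 6 --out-dir run/ --identity-map secure/identity_map.csv

# classify at 24 h / 72 h / discharge
flowstream classify --episodes run/episodes.csv --events run/episode_events.csv \
    --out-dir run/ --dump-features run/features.csv

# stratified summary, source-by-stream and quality report
flowstream report --run-dir run/ --out-dir run/reports

# or the whole chain at once
flowstream run-all --out-dir run/ --seed 1 --n-patients 5000
```

Configuration files (TOML or JSON) can override cohort parameters,
per-archetype generator blocks (`[archetypes.FS3]`), defect rates
(`[defects]`) and every classification threshold (`--rules`).

## Output column dictionaries

* `encounters.csv`: `mrn, encounter_id, encounter_type(ED|IP|OPD|ITF),
  start_ts, end_ts, admitting_team, ward, age, gender, postcode,
  usual_accommodation, admission_type, day_procedure, problem_list`
  (ISO 8601 timestamps, minute resolution).
* `events.csv`: `mrn, event_type(order|location_transfer|icu_entry|icu_exit|
  theatre_emergency|mtp_activation), order_subtype, ts, target_service,
  location, structured`.
* `episodes.csv` / `episode_events.csv`: de-identified per-episode rows keyed
  by `episode_id` (and patient-level `study_id`).
* `identity_map.csv`: the only artefact containing `mrn`; store it apart
  from the analytical outputs.
* `assignments.csv`: `episode_id, study_id, window, stream, trace` — the
  trace lists every criterion evaluated with its outcome.
* `trajectories.csv`, `transitions_24h_72h.csv`,
  `transitions_72h_discharge.csv`, `stream_summary.csv`,
  `source_by_stream.csv`, `quality_report.csv`.
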