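# smbgpattern

Structured self-monitored blood glucose (SMBG) pattern management as an open,
testable library and CLI:

1. **Data sufficiency (Step 1)** — quantity gate (default 28 tests per 2
   weeks), tag-coverage quality check, and the pattern-analysis activation
   gate (default 72 tests per 4 weeks, settable 30–120, clamped).
2. **Pattern detection (Step 2)** — rule-based red/clear detectors with
   settable parameters: hyperglycemia trend (≥2 hyper tests/day on 3
   consecutive days), very-high trend (≥1 test above 250 mg/dL),
   hypoglycemia trend (≥1 event/day on 2 consecutive days), hypoglycemia in
   time block (≥2 events in one block within a sliding 7-day span), very-low
   trend (≥1 test below 54 mg/dL), a mirrored hyper time-block rule, plus
   declared heuristics (overcorrection pairs, missed-bolus hyperglycemia;
   off by default) and a test-frequency adherence check. Every red finding
   carries its exact triggering readings.
3. **Variability and actions (Step 3)** — SD, CV (overall and of mean daily
   glucose), LBGI/HBGI risk indices, CV classification (low < 33 %,
   acceptable 33–36 %, high > 36 %), and categorical action flags. High
   variability suppresses treatment-change flags and asks for intensified
   testing first. Two disjoint periods can be compared metric by metric.

A synthetic-data module generates structured regimens (7-point profiles,
staggered 5-point) with injectable patterns shaped exactly at — or exactly
one unit below — each detector's default trigger, self-checked against
brute-force rule oracles at generation time.

## CLI

```sh
# simulate a 4-week 7-point log with an injected hypoglycemia trend
smbgpattern simulate --seed 7 --days 28 --inject hypo_trend:10 --out log.csv

# run the 3-step analysis (JSON report; --format text for the matrix view)
smbgpattern analyze --input log.csv --window 2024-01-01:2024-01-28 --out report.json

# compare two disjoint periods
smbgpattern compare --input log.csv \
    --window-a 2024-01-01:2024-01-14 --window-b 2024-01-15:2024-01-28 \
    --out compare.json
```

Exit code 0 covers insufficient-data outcomes (a valid clinical result); 2 is
reserved for input/config errors. All thresholds and pattern parameters are
overridable through `--config config.json`; unknown keys are rejected and
out-of-range parameters are clamped into their settable ranges with a logged
warning.

Readings CSV dialect: header `timestamp,value_mgdl,tag,bolus_given,carbs_logged`,
ISO-8601 timestamps, tags from the fixed vocabulary, booleans
`true`/`false`/empty. `--unit mmol` converts at ingest (× 18.016).

## Layout

| module | role |
| --- | --- |
| `smbgpattern.core` | reading/threshold/time-block domain types, classification, day arithmetic |
| `smbgpattern.io` | readings CSV ingest/export |
| `smbgpattern.config` | analysis configuration (JSON), validation, clamping |
| `smbgpattern.sufficiency` | Step 1 gates |
| `smbgpattern.patterns` | Step 2 detectors and parameters |
| `smbgpattern.variability` | SD/CV/LBGI/HBGI and the CV gate |
| `smbgpattern.flowchart` | orchestration, action flags, period comparison |
| `smbgpattern.synthetic` | regimen simulator with oracle-verified injections |
| `smbgpattern.oracles` | naive brute-force reference rules |
| `smbgpattern.report` / `smbgpattern.cli` | text rendering and the `smbgpattern` command |
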