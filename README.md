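# faerspv

A pharmacovigilance pipeline for FAERS-style spontaneous adverse-event
report data: quarterly ASCII-file ingestion, report cleaning and
deduplication, primary-suspect cohort selection, adverse-event query
mapping, disproportionality signal detection (PRR, ROR, Pearson
chi-square, BCPNN information component), time-to-onset analysis, cohort
descriptives — plus a synthetic corpus generator with a ground-truth
ledger so the entire pipeline can be exercised and validated without any
external download.

## Modules

| Module | Purpose |
| --- | --- |
| `faerspv.faers_io` | Read/write `"$"`-delimited quarterly tables (DEMO/DRUG/REAC/OUTC/THER + deleted-case lists), join them into case reports, write CSV results |
| `faerspv.cleaning` | Cleaning cascade: deleted-case removal, latest-version-per-case, cross-caseid deduplication, age validation |
| `faerspv.cohort` | Drug-name normalization and primary-suspect cohort selection via variant dictionaries |
| `faerspv.meddra_map` | Named PT-set queries (SOC/SMQ-style), report flagging, PT reporting-frequency tables |
| `faerspv.signal_stats` | 2×2 tables, PRR/ROR/chi-square, IC + IC025 (three variants), signal decision |
| `faerspv.tte` | Date validation, earliest suspect start date, median/IQR time-to-onset summaries |
| `faerspv.descriptives` | Cohort characteristic tables (age, sex, occupation, serious outcomes) |
| `faerspv.synthetic_data` | Deterministic synthetic corpora with planted reporting-rate ratios, duplicates, follow-ups, invalid dates, and an exact-count ledger |
| `faerspv.cli` | `faerspv` command-line orchestration |

MedDRA is licensed and is **not** bundled: query definitions (PT lists)
are user-supplied YAML; the repo ships a small synthetic toy vocabulary
under `faerspv/data/queries/` for tests and simulations. A default
drug dictionary for the three CDK4/6 inhibitors ships in
`faerspv/data/drugs.yaml`.

## CLI

Generate a synthetic corpus with one planted drug–query signal, then run
every stage:

```sh
faerspv simulate --n 2000 --seed 7 --out corpus \
    --rho "ribociclib/Toy torsade/QT prolongation=8"

cat > config.yaml <<EOF
input_dir: corpus
output_dir: results
EOF

faerspv run --config config.yaml
```

Outputs under `results/`: `manifest.json` (stage-by-stage report counts),
`signals.csv` (one row per drug–query pair), `pt_frequency.csv`,
`tte_summary.csv`, `tte_rejections.csv`, `descriptives.csv`. Stage
subcommands (`clean`, `cohort`, `signal`, `tte`, `describe`) run the
pipeline up to the named stage. The IC variant is selected with the
`ic_method` config key (`bcpnn_bate1998` default, `log2_oe`,
`log2_oe_shrunk`); every output row is labelled with the method used.

To analyze real FAERS data, point `input_dir` at a directory containing
the quarterly ASCII files (`DEMOyyQq.txt`, `DRUGyyQq.txt`, …) plus
deleted-case lists named `DELETED*.txt`, and list your own query YAML
files under the `queries` config key.

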