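# brcapath

Micro-costing model of a UK cancer-genetics service for breast/ovarian
cancer (2013 GBP). The package costs 28 referral-to-management patient
pathways bottom-up from unit activities, applies 3.5%-per-year discounting
to surveillance streams anchored at presentation age 30, takes
probability-weighted expectations over carrier management (30% mastectomy /
60% salpingo-oophorectomy uptake, 5-year survival scaling), summarises a
220-patient six-month audit (subgroup means, count-weighted means, service
total), and runs one-way deterministic sensitivity analyses (test price,
consultant/counsellor mix, face-to-face/telephone mix, London weighting).

Components with no published unit price (GP referral, predictive-test
price, per-tier surveillance aggregates, carrier-management bundles,
relative-coordination remainders) are recovered by least squares against
the published per-pathway reference totals, with per-pathway residuals and
identifiability flags reported rather than hidden.

## Layout

| module | role |
| --- | --- |
| `brcapath.money` | exact decimal GBP; penny rounding only at display |
| `brcapath.cost_engine` | discount factors, staff-time costs, schedule expansion, stream costs, management expectations, pathway itemisation |
| `brcapath.pathway_catalog` | the 28 pathways as data + case classification |
| `brcapath.audit_weighting` | audit counts, 50% pending allocation, weighted summaries |
| `brcapath.calibration` | least-squares recovery of unpriced components; affected-split inference |
| `brcapath.sensitivity` | one-way scenario engine over the service total |
| `brcapath.synthetic_data` | seeded synthetic cohorts and perturbed cost tables with known truth |
| `brcapath.config` / `brcapath.cli_io` | typed configuration, file I/O, CLI |

All inputs ship as plain-text fixtures under `src/brcapath/data/`
(unit-cost CSV, pathway YAML, audit counts/narrative, model config,
scenario file).

## CLI

```sh
brcapath compute --out report.json            # cost all pathways + audit summaries
brcapath sensitivity --out sens.json          # one-way scenario table
brcapath calibrate --out cal.json             # component estimates + residuals
brcapath simulate --n 220 --seed 17 --out cohort.csv
```

Each command accepts `--costs/--pathways/--audit/--scenario/--config` to
replace the packaged fixtures with your own files.

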