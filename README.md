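# chwvitals

Validation toolkit for community-based vital-events reporting. The package
simulates ground-truth births and under-five deaths for a grid of catchment
areas, derives two imperfect observations of that truth — community health
worker (CHW) monthly reports and retrospective full-birth-history (FBH)
survey data — and measures how well the CHW stream recovers the survey's
demographic rates over rolling 12-month windows, along with process,
data-quality and cost metrics.

## Modules

| Module | What it does |
|---|---|
| `chwvitals.synthetic_data` | Ground-truth event ledger (`simulate_ledger`), CHW observation model (`apply_chw_observation`: per-event capture, stillbirth misclassification, missing monthly reports), survey observation model (`apply_survey_observation`: census or household sample, recall omission, 12-month age heaping, date displacement) |
| `chwvitals.demography` | Century-month-code arithmetic, rolling 12-month windows stepping by 3 months, event tabulation for both data streams, and period rates (CBR; NMR/IMR/U5MR as deaths-in-window per 1,000 births-in-window) |
| `chwvitals.validation` | Completeness vs expected events (reference CBR/U5MR × population), per-window and average annual accuracy ratios, sex ratio at birth with the 102–107 band, nested death ratios, 12-month heaping index, monthly reporting coverage, greedy register matching |
| `chwvitals.costing` | CPI inflation to a base year, currency conversion, and total / annual-per-1,000 / per-event cost metrics |
| `chwvitals.cli_report` | YAML-configured pipeline (simulate → observe → analyze → cost), named presets, tidy CSV + JSON artifacts, and the `chwvitals` CLI |

Rates are deliberately period ratios, not DHS synthetic-cohort
probabilities; under changing fertility they are biased relative to cohort
q(5), so interpret them under approximate stationarity.

## CLI

```bash
# full pipeline from a config file, artifacts to an output directory
chwvitals all --config examples/mali_like.yaml --seed 1 --out scratch/mali

# named presets: gold (error-free), mali_like, malawi_like, ethiopia_like
chwvitals analyze --preset gold --seed 42

# individual stages
chwvitals simulate --preset gold --seed 1 --out scratch/sim
chwvitals observe  --config examples/mali_like.yaml --out scratch/obs
chwvitals cost     --config examples/mali_like.yaml
```

Exit codes: 0 ok, 1 config error, 2 runtime error. All randomness derives
from the single `--seed` via `numpy.random.SeedSequence(seed).spawn(3)`
(simulation, CHW observation, survey observation streams, in that order);
the same config + seed reproduces every artifact byte for byte.

Pipeline artifacts (all plain CSV/JSON): `ledger.csv` (ground truth),
`monthly_reports.csv` (one row per submitted catchment-month),
`birth_histories.csv` (one row per recalled live birth),
`metrics_by_window.csv` (tidy: window × source × metric),
`summary.json`, `summary_table.csv`, `death_ratio_table.csv`.

## Known reporting caveats

The published summary the worked examples come from contains two internal
inconsistencies, which this package does not attempt to reconcile: the
abstract's "under-estimated by 9%" for one site conflicts with the summary
table's 100.6% accuracy ratio for the same site (the table convention is
used here), and a quoted neonatal:infant range (3.9–9.6) is not
reproducible from the printed table values (3.9–8.6).
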