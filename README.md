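# itpclaims

Claims-database analysis of corticosteroid (CS) use in adult primary
immune thrombocytopenia (ITP), built as a reusable, tested Python
package. Given administrative-claims-shaped tables (patients,
diagnoses, prescriptions, procedures) it performs:

- **new-user cohort construction** — first non-suspected ITP diagnosis,
  adult age, full 6-month look-back enrollment, no CS in look-back, with
  a per-criterion exclusion flowchart and a baseline characteristics
  table;
- **CS exposure quantification** — gap-period episode merging (oral and
  injectable rules), prednisolone-equivalent dose conversion,
  pulse/high-dose-dexamethasone flagging, duration and cumulative-dose
  binning, a weekly dose grid from CS initiation, and time to
  withdrawal (≥ 60 CS-free days after a coverage end, capped at 6
  months);
- **treatment patterns** — yearly modality counts, treatment-line
  derivation, switch/add-on state sequences with Sankey JSON export;
- **time-to-withdrawal analysis** — Kaplan–Meier per era (2015–2019 vs
  2020–2021) with median, 95% CI, survival at 1/3 months, and a
  log-rank comparison;
- **nested case–control risk assessment** — risk-set (incidence
  density) sampling with up-to-5:1 time-point matching, look-back
  washout per outcome, three exposure codings (presence, duration
  category, cumulative-dose category), and matched-set conditional
  logistic regression (authored Newton solver) with univariate and
  covariate-adjusted models;
- **synthetic claims generation** — a generator with era structure,
  taper schedules, and discrete-time daily logistic outcome hazards
  with a known multiplicative CS effect, so that the full pipeline's
  parameter recovery is testable end to end.

The proprietary source database is not available; all inputs are
synthetic or user-supplied CSV tables. Real ICD-10/drug code lists are
user configuration (`AnalysisConfig` / `config.yaml`).

## CLI

```bash
# generate synthetic claims (4 CSVs + ground truth) into out/
itpclaims simulate --out out --seed 1

# run the analysis stages in dependency order
itpclaims run --out out --seed 1 \
    --stages cohort,exposure,patterns,km,ncc

# individual stages
itpclaims cohort --out out
itpclaims km --out out
```

Stage outputs are plain CSV/JSON (`cohort.csv`, `exclusion_flow.csv`,
`baseline_table.csv`, `episodes.csv`, `duration_table.csv`,
`dose_grid.csv`, `withdrawal.csv`, `yearly_counts.csv`, `lines.csv`,
`flows.csv`, `sankey.json`, `km_curves.csv`, `km_summary.json`,
`incidence.csv`, `matched_sets.csv`, `ncc_results.csv`) plus a
`manifest.json` with config hash, seed, and per-file SHA-256 digests;
identical config + seed reproduce byte-identical outputs.

Analysis constants (look-back months, gap days per drug class, the
60-day withdrawal rule, dose/duration bins, the week grid, matching
ratio, PSL-equivalence factors, code lists) live in `AnalysisConfig`
and can be overridden from YAML via `--config`.

## Package layout

```
src/itpclaims/
  config.py    AnalysisConfig: code lists, gaps, bins, thresholds
  io.py        claims CSV schemas, readers/writers, validation
  simulate.py  synthetic claims generator + ground truth
  fixture.py   deterministic hand-written ~20-patient fixture
  cohort.py    selection flow, assessment periods, baseline table
  exposure.py  episodes, PSL dose, pulse/HDD flags, grids, withdrawal
  patterns.py  yearly counts, states, switch sequences, lines, Sankey
  km.py        Kaplan-Meier + log-rank (lifelines-backed)
  ncc.py       risk-set sampling + conditional logistic (Newton)
  report.py    percentage/tabulation helpers
  cli.py       stage orchestration and the itpclaims entry point
```
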