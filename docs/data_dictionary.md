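# Data dictionary

All files are CSV (UTF-8, ISO-8601 timestamps) unless noted. The three
input tables are produced by `akicausal simulate` or supplied by the user
in the same layout.

## Input tables

### encounters.csv
| column | type | meaning |
|---|---|---|
| encounter_id | str | unique encounter key |
| age | float | age in years at admission (> 18) |
| gender | str | `F` / `M` |
| race | str | `asian` / `black` / `other` / `white` |
| admission | datetime | hospital admission |
| discharge | datetime | hospital discharge (≥ admission + 2 days) |
| egfr_admission | float | precomputed eGFR at admission, mL/min/1.73 m² |

### scr_measurements.csv
| column | type | meaning |
|---|---|---|
| encounter_id | str | encounter key |
| time | datetime | measurement time (pre-admission values allowed) |
| scr_mgdl | float | serum creatinine, mg/dL |

### feature_events.csv
| column | type | meaning |
|---|---|---|
| encounter_id | str | encounter key |
| time | datetime | event time; empty for time-independent categories |
| feature | str | resolved feature name |
| category | str | `medication` / `history` / `comorbidity` / `admission_dx` / `lab` / `vitals` |
| value | float | numeric value for labs/vitals; 1.0 for binary events |

## Ground truth (synthetic runs only)

`truth.json` — planted causes, generating graph edges, intended KDIGO stage
per encounter. `truth_matrix.csv` — intended state label per (encounter,
feature), including the derived demographic columns.

## Stage outputs

`cohort.csv` — encounter_id, stage (0–3), onset_time, baseline_scr,
baseline_source (`pre-admission-window` / `first-inpatient`),
matched_pair_id. One row per matched encounter.

`exclusion_log.csv` — encounter_id, reason (`underage`, `short_stay`,
`insufficient_scr`, `low_egfr`, `abnormal_admission_scr`).

`feature_matrix.csv` — one row per encounter, one column per feature, cells
are state labels, plus the binary outcome column `y`.
`feature_dict.csv` — feature, category, states (`|`-separated, ordered),
m (state count), time_dependent. `checkpoint_drop_log.csv` — encounters
dropped for lack of a valid checkpoint.

`blanket.csv` — Markov-blanket members. `blanket_trace.csv` — ordered
admit/remove events with the justifying test (statistic, dof, p, reliable).

`causes.csv` — accepted cause set with forward/backward p-values.
`direction_search.csv` — every tested subset with its converted state count
`m_bar`, both p-values, admissibility, and skip reason if any.

`odds_ratios.csv` — combination (mask string, bit 1 = exposed to that
cause), cell counts a/b/c/d, odds_ratio, ci_low, ci_high, haldane flag.

`cv_metrics.csv` — feature_set, n_features, model, metric
(auc/f_score/recall/precision), mean, ci_low, ci_high, per-fold values.
`cv_summary.txt` — human-readable table of the same means.

`manifest.json` — per-stage outputs and counts, seed, package version
(byte-deterministic). `timings.txt` — per-stage wall-clock (excluded from
reproducibility comparisons).
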