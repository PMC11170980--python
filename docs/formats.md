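# File formats

All CSV files are comma-separated, UTF-8, `.` decimal, with a mandatory
header row. Files written by the CLI carry a leading provenance comment
line (`# hemofluid v… seed=… config=…`); every reader in this package skips
`#` comment lines. Structured results are JSON; declarative configuration
is YAML.

## Protocol CSV

Piecewise-constant inputs; each row's rates hold from its time until the
next row. The final row is a sentinel with zero rates whose time marks the
protocol duration.

| column | units | meaning |
|---|---|---|
| `time_min` | min | interval start (first row at 0) |
| `U_l_per_min` | l/min | infusion rate on the interval |
| `V_l_per_min` | l/min | loss rate (hemorrhage + urine) |

Equivalent JSON: `{"duration_min": …, "breakpoints": [{"time_min": …,
"U_l_per_min": …, "V_l_per_min": …}, …]}`.

## Trajectory CSV

Written by `simulate` on a regular grid.

| column | units |
|---|---|
| `time_min` | min |
| `BV_l` | l |
| `HCT_pct` | % |
| `HR_bpm` | bpm |
| `SV_l` | l |
| `CO_l_per_min` | l/min |
| `BP_mmHg` | mmHg |

## Parameter table CSV

One row per subject: `subject_id` plus the 25 parameter columns in
canonical order (`A_U_BV, A_V_BV, alpha_U, alpha_V, K_P_BV, G_U_T, G_V_T,
G_V_L, P_U_T, P_V_L, K_P_H, K_I_H, G_BV, G_HR, A_SV, r_SV, K_P_SV, A_BP,
K_P_BP, r_BP, HCT0, BV0, H0, SV0, TPR0`). The packaged reference table
`calibrated_sheep_parameters.csv` uses this schema (27 rows).

## Measurement CSV

| column | units | notes |
|---|---|---|
| `time_min` | min | strictly increasing |
| `HCT_pct` | % | empty cell = missing |
| `HR_bpm` | bpm | |
| `SV_l` | l | |
| `CO_l_per_min` | l/min | |
| `BP_mmHg` | mmHg | |

## Cohort CSV

The parameter-table schema plus provenance columns:

| column | meaning |
|---|---|
| `kind` | `mixing` or `average` |
| `donor_bv`, `donor_hr`, `donor_sv`, `donor_bp` | donor subject id per compartment; average subjects list their three donors joined with `\|` in every column |
| `seed` | cohort generation seed |

## Fit JSON (`calibrate`)

`parameters` (all 25 values), `subject_id`, `sigma` (per calibrated
variable, its units), `neg_ll`, `objective`, `nrmse`/`nmae` (percent, all
five variables), `start_objectives`, `converged`, `beta`, `provenance`.

## Report JSON (`assess`)

`best_subject {avg_nrmse, max_nrmse, avg_nmae, max_nmae, neg_ll,
cohort_index}`, `cohort {pct_physiological, pct_relevant, pct_coverage,
n_cohort, n_relevant}`, `nis {hct, hr, sv, co, bp}`, `flags` (e.g.
`no-relevant-subjects`, `no-envelope`), `provenance`.

## Envelope CSV

| column | meaning |
|---|---|
| `variable` | `hct`, `hr`, `sv`, `co`, `bp` |
| `time_min` | measurement time |
| `lower`, `upper` | envelope bounds in the variable's units |
| `n_relevant` | number of relevant simulations spanning the band |

## ProtocolSpec / RunConfig YAML

`ProtocolSpec`: `template` (`sheep-like` | `swine-like` | `custom`),
`weight_kg`, `options` (builder keyword arguments; for `custom`:
`duration`, `loss_events`, `infusion_events` as `[start, stop, rate]`
triples). `RunConfig`: input paths, per-stage option mappings (`solver`,
`calibration`, `cohort`, `credibility`), `seed`, `log_level`; round-trips
losslessly through YAML.
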