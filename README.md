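# pdmilestones

Milestone-based progression endpoints for early Parkinson's disease cohorts:
a declarative engine for 25 clinically defined progression milestones across
six domains, derivation of the composite time-to-first-event endpoint, the
Kaplan-Meier / Cox predictor-selection workflow with a time-dependent
medication covariate, milestone stability (reverter) analysis, and a
log-rank sample-size calculator driven by a piecewise-linear control
survival curve.  A truth-first cohort simulator makes the whole pipeline
testable without any access-controlled data.

## Layout

| Module | Role |
| --- | --- |
| `pdmilestones.study_data` | Long-format visit / wide covariate data model, CSV I/O, schedule validation |
| `pdmilestones.milestone_engine` | 25-milestone registry (criterion trees), conservative per-visit evaluation |
| `pdmilestones.endpoint_pipeline` | Composite endpoint under `annual` / `all` visit modes, exclusions, tabulations |
| `pdmilestones.survival_models` | Kaplan-Meier on per-protocol time; screening → priority rules → backward selection Cox workflow (Efron ties) |
| `pdmilestones.stability_analysis` | Persistent / temporary / permanent reverter classification, domain persistence, 2×2 chi-square |
| `pdmilestones.trial_design` | Schoenfeld event counts, Lakatos-style Markov sample size, trial power simulator |
| `pdmilestones.synthetic_data` | Cohort generator with exact milestone ground truth and known covariate effects |

## Data formats

Visits are tidy CSV — one recorded score per row:

```
participant_id,scheduled_month,actual_month,item_code,state,value
P00001,12,12.0,UPDRS_3_10,OFF,3
P00001,12,12.0,MOCA_TOTAL,NA,24
```

`state` is `OFF`/`ON` for motor-exam items scored per medication state and
`NA` otherwise; a missing score is an absent row, never zero.  Item codes
and instrument ranges ship in `pdmilestones.items.ITEM_TABLE`.  Covariates
are wide CSV, one row per participant
(`pdmilestones.items.COVARIATE_COLUMNS`), including
`med_initiation_month`.

## CLI

```bash
pdmilestones simulate --n 400 --seed 17 --out-dir data/
pdmilestones classify --visits data/visits.csv --covariates data/covariates.csv --out hits.csv
pdmilestones endpoint --visits data/visits.csv --covariates data/covariates.csv \
    --mode annual --out endpoint.csv --report-out first_events.csv
pdmilestones fit --endpoint endpoint.csv --covariates data/covariates.csv --out-prefix cox
pdmilestones stability --endpoint endpoint.csv --visits data/visits.csv \
    --covariates data/covariates.csv --out-prefix stab
pdmilestones samplesize --endpoint endpoint.csv --hr 0.5 --length 36
pdmilestones power-sim --km km.csv --hr 0.5 --length 36 --n 292 --sims 2000 --seed 1
```

## Notes

- Milestone evaluation is conservative under missing data: a missing score
  never satisfies a criterion, so deleting information can never create a
  hit (enforced as a property test).
- "ON or OFF" motor criteria are satisfied by either state, so a milestone
  remains evaluable when only one state was assessed.
- The simulator is truth-first: item scores are back-filled from intended
  milestone states, giving the engine an exact oracle
  (`engine_roundtrip_check`).
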