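# orplan

Elective-surgery scheduling for day-hospital wards with *ready-to-deploy
backup plans*: alongside the nominal schedule (patient → day, OR, within-day
position and start slot), the tool pre-computes one restoration schedule for
every enumerated disruption scenario — an emergency case of a given length
class arriving at any 15-minute slot of the first day, or a no-show of any
patient scheduled on that day, covered by a pre-designated substitute from
the following day.

The optimization model is a mixed-integer program over urgency-weighted
waiting-time penalties, solved by a sequential procedure: nominal solve,
warm-start or minimum-difference heuristic completion to a disruption-
recoverable schedule, then per-scenario optimization of the emergency and
no-show backup plans. An independent arithmetic validator re-checks every
constraint family on the produced bundle without consulting the solver, and
a brute-force oracle provides ground truth on tiny instances.

## Layout

| module | contents |
|---|---|
| `orplan.instance` | domain types (patients, instances, penalty tables), penalty formulas, JSON/CSV I/O |
| `orplan.generate` | seeded synthetic waiting-list generator (benchmark mixes A–D + case-study mix) |
| `orplan.backend` | minimal MILP container + HiGHS backend (via `scipy.optimize.milp`), LP-text export |
| `orplan.model` | the full MILP: nominal block, ordering, OR-state, emergency and no-show blocks, auxiliary heuristic blocks, objective switching |
| `orplan.scenario_opt` | per-scenario backup-plan optimization for a fixed nominal schedule (fast decomposed route) |
| `orplan.pipeline` | the sequential solution procedure and solution bundles |
| `orplan.semantics` | schedule decoding, the arithmetic validator, objective re-evaluation, plan application |
| `orplan.oracle` | exhaustive reference solver for tiny instances |
| `orplan.report` | textual Gantt rendering and benchmark-style CSV tables |
| `orplan.cli` | `orplan generate / solve / validate / report` |

Index conventions everywhere: days and ORs are 1-based; within-day moments
`h` are 0-based; surgery start slots are 1-based (a patient of duration `t`
starting at slot `s` occupies `s .. s+t-1`).

## CLI

```sh
# 40-patient benchmark-style instance, mix A, 14 days, 2 ORs
orplan generate --patients 40 --mix A --days 14 --ors 2 --seed 1 --out inst.json

# full pipeline (nominal + all backup plans); writes bundle.json
orplan solve inst.json --strategy heuristic --time-limit 60 --out bundle.json

# re-check every constraint family arithmetically (exit 0 iff clean)
orplan validate bundle.json inst.json

# textual Gantt of the nominal schedule, or of one backup plan
orplan report bundle.json inst.json
orplan report bundle.json inst.json --scenario 7,1,2     # emergency (h,g,l)
orplan report bundle.json inst.json --scenario P03,1     # no-show (patient, g)
```

`orplan solve --mode` picks the solve route: `faithful` solves the
monolithic model at every step (tractable only for small instances),
`fix` uses the fast decomposed route (per-scenario subproblems for a fixed
nominal schedule, with a repair ladder when the nominal schedule is not
recoverable), and `auto` (default) combines both. `--oracle` additionally
reports the brute-force optimum on tiny instances.

## Bundle format

`bundle.json` holds the nominal schedule (`patient`, `day`, `or`,
`position`, `start_slot`), the substitute designation per (day, OR), one
emergency plan per scenario key `"h,g,l"` (`l` is a 0-based index into the
instance's emergency length classes) with the chosen OR, impacted and
dropped patients and the full reschedule, one no-show plan per key
`"<patient>,g"`, and per-step solver metrics (objective, bound, gap,
status, runtime).
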