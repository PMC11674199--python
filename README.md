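# aesiloc

Level-of-certainty (LOC) classification for adverse-event-of-special-interest
(AESI) hospital surveillance line lists, in the style of the Brighton
Collaboration case definitions: each suspected case is graded from level 1
(most specific) through level 3 (most sensitive), level 4 (insufficient
information) or level 5 (not a case).

The engine evaluates declarative rule sets under **strong Kleene three-valued
logic**, so undocumented criteria propagate honestly: a case is only level 4
when missing data genuinely blocks every definite outcome, and only level 5
when the most sensitive definition is definitively excluded.

## Components

- `aesiloc.case_model` — domain types (tri-state criterion values, case
  records, rule expressions) and line-list CSV I/O.
- `aesiloc.logic_engine` — Kleene evaluation, LOC assignment, level-4
  blocking-criteria explanation.
- `aesiloc.definitions` — declarative JSON rule sets for 13 conditions, a
  loader with JSON-pointer error reporting, and an exhaustive
  level1 ⇒ level2 ⇒ level3 nesting validator. Only the Guillain-Barré /
  Fisher set transcribes published level logic; the rest are simplified,
  clearly versioned stand-ins that can be replaced by dropping in new JSON.
- `aesiloc.synthetic_cases` — a seeded roster simulator (per-criterion
  prevalence and missingness, demographics) and a deterministic 203-case
  fixture roster reproducing the reference surveillance's aggregate tables.
- `aesiloc.surveillance_summary` — LOC distributions, level-4 reason
  tabulation, criterion-prevalence (n/N) tables, demographics tables.
- `aesiloc.cli` — `aesiloc` command-line tool.

## CLI

```sh
aesiloc fixture  --out roster.csv                     # built-in 203-case roster
aesiloc classify --in roster.csv --out classified.csv # appends loc + provenance
aesiloc summarize --in roster.csv --format markdown   # all summary tables
aesiloc simulate --params examples/sim_params.json --seed 7 --out sim.csv
aesiloc validate-rules                                # nesting check, shipped rules
aesiloc validate-rules --rules my_rules/              # ... or your own directory
```

Line-list CSVs have fixed columns `case_id, condition, age, sex, residence,
detection_site` followed by one `crit.<id>` column per criterion with values
`yes`/`no`/blank (blank = unknown). Logs go to stderr, data to files; all
commands are deterministic given identical inputs and seeds.

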