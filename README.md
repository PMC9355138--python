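# crowdval

Scoring, reliability, and construct-validity toolkit for peer-crowd
segmentation surveys, with a synthetic-cohort generator for end-to-end
validation studies.

The package covers two instruments that measure identification with five
teen peer crowds (Alternative, Country, Hip Hop, Mainstream, Popular):

* a **ranked-choice mindset survey** — 7 questions, five crowd-mapped options
  each; rank-1 picks earn 2 points, rank-2 picks 1 point (0.5 for
  Alternative and Mainstream), yielding five 0–14 crowd scores;
* a **photo-grid survey** — 2 grids, 3 best-fit + 3 least-fit photo picks
  each, ±2 points per pick, yielding five −12..12 crowd scores.

On top of the instrument scores it provides:

| module | what it does |
|---|---|
| `crowdval.cohort` | synthetic respondent cohorts with a known latent crowd, tunable instrument fidelity, and injectable crowd-specific outcome effects |
| `crowdval.instruments` | instrument scoring, single-crowd assignment (ties flagged), ACE/resilience/social-prioritization/sensation-seeking scales, behavior dichotomization |
| `crowdval.reliability` | McDonald's omega per crowd subscale via a one-factor fit (ULS on the item correlation matrix; ML optional) |
| `crowdval.mtmm` | the 10×10 multi-trait multi-method matrix, convergent/discriminant validity decision rules, and a packaged fixture of the published matrix |
| `crowdval.predictive` | the 110-model regression battery (logistic AORs for 7 behaviors, linear Bs for 4 trait scores, each adjusted for age, gender, race/ethnicity) |
| `crowdval.pipeline` / `crowdval.cli` | validated CSV ingestion and one-command orchestration with a reproducible report bundle |

## CLI

```sh
# generate a synthetic cohort (config YAML written alongside the CSV)
crowdval simulate --seed 1 --n 1113 --out cohort.csv

# append all score columns
crowdval score --in cohort.csv --out scored.csv

# full pipeline: generate/load, score, reliability, MTMM, validity, battery
crowdval run --seed 1 --out run_dir
crowdval run --in cohort.csv --out run_dir        # user-supplied data

# reliability + MTMM + validity only
crowdval validate --seed 1 --alpha 0.05 --out run_dir --mtmm-only 2>/dev/null
crowdval validate --published-fixture --out run_dir   # evaluate the printed matrix

# emit the packaged published-matrix fixture
crowdval fixtures --out mtmm_fixture.csv
```

`run` writes `cohort.csv`, `scored.csv`, `descriptives.csv`,
`reliability.csv`, `mtmm.csv` (+ `mtmm_pvalues.csv`), `validity.json`/`.txt`,
`battery_long.csv`/`battery_wide.csv`, a `manifest.json` (seed + config
hash), and a human-readable `report.txt`. Identical config and seed give
byte-identical outputs.

## Cohort CSV column dictionary

One row per respondent: `respondent_id`; `vmls_q{1..7}_rank{1,2}` (crowd
names); `ibase_g{1,2}_{best,least}_{1..3}` (photo ids, mapped to crowds by
the grid spec); `ace_{1..9}` (0/1); `brs_{1..6}`, `spi_{1..8}`,
`bsss_{1..8}` (1–5); `use_days_{cigarettes,lcc,smokeless,vape,alcohol,marijuana}`
(0–30); `sad_hopeless` (0/1); `age` (13–18); `gender`; `race_ethnicity`;
`region`. Generated cohorts additionally carry `latent_crowd`, which is a
ground-truth oracle for recovery tests only — no analysis stage reads it.

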