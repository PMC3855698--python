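# dyadrl

Simulation and reinforcement-learning analysis of dyadic perceptual
decision making with shared confidence.

Two observers each judge which of two stimulus intervals contained a
target and report a signed confidence (−5..−1, 1..5; sign = chosen
interval). On disagreement trials a randomly nominated member indicates
the joint decision. `dyadrl` provides:

- **`synthetic_data`** — seeded generators for such sessions (16 blocks ×
  16 trials by default, 4 contrast-difference magnitudes). Observers are
  equal-variance Gaussian signal-detection models whose choice curve is
  exactly the cumulative Gaussian fitted downstream. An optional
  *escalation* mechanism geometrically decays the confidence thresholds
  so mean absolute confidence rises over a session without any change in
  accuracy. Cohort simulation records every drawn parameter in a manifest.
- **`psychometrics`** — maximum-likelihood probit fits of
  `P(choose 2nd) = Φ((Δc − b)/σ)`, the maximum slope
  `s = 1/(σ√(2π))`, and the collective-benefit ratio
  `CB = s_test / max(s_member1, s_member2)`.
- **`rl_agent`** — a single-step temporal-difference learner over reduced
  confidence-pair states (magnitudes 4 and 5 collapse to 4; 64 states),
  actions = intervals, reward ±1, update `Q ← Q + α(r − Q)`, greedy
  action selection with a higher-confidence tie-break.
- **`fitting`** — 3-bin splits with learning restarts and a learning-rate
  grid search under two objectives: *max accuracy* (maximise the model's
  own psychometric slope per bin) and *max similarity* (per member,
  maximise agreement with the joint decisions that member indicated).
  Collapsed decisions yield the overall model slope, `cb_model =
  s_model/s_max` and concordance `s_model/s_dyad`.
- **`escalation`** — mean absolute confidence per time bin, the
  escalation index `(M_last − M_first)/M_first` (absolute variant
  selectable), dyadic escalation (sum over members), and its Pearson
  correlation with model collective benefit.
- **`io_cli`** — strict CSV trial-table I/O, YAML run configs, and the
  `dyadrl` command line.

## Command line

```sh
# simulate a cohort of dyads to CSV trial tables + parameter manifest
dyadrl simulate --seed 1 --dyads 2 --preset V --out-dir out/

# fit both model objectives to trial tables
dyadrl fit --input out/dyad_000.csv --input out/dyad_001.csv \
    --objective both --bins 3 --alpha-grid 0:1:101 --seed 1 --out fits.csv

# escalation analysis of a fitted cohort
dyadrl analyze --results fits.csv --trials out/dyad_000.csv \
    --trials out/dyad_001.csv --out cohort.csv

# full synthetic pipeline (cohort -> both fits -> escalation correlation)
dyadrl reproduce --preset V --dyads 14 --seed 1 --out-dir results/
```

Presets: `V` (mild confidence escalation), `VV` (strong escalation),
`calibrated` (none). `--alpha-grid` accepts `start:stop:num` (linspace)
or a comma-separated list.

### Trial-table schema

CSV, UTF-8, header row, columns exactly:

| column | meaning |
| --- | --- |
| `trial_index` | 0-based, strictly increasing |
| `delta_c` | signed contrast difference; positive ⇒ target in 2nd interval |
| `c1`, `c2` | signed confidence in {−5..−1, 1..5}; sign = chosen interval |
| `correct_interval` | 1 or 2; must equal 2 iff `delta_c` > 0 |
| `nominated` | member (1/2) indicating the joint decision on disagreement |
| `dyad_decision` | empirical joint choice (1/2); equals the common choice on agreement trials |

### Fitting results CSV

One row per (objective, bin[, member]): `dyad_id, objective, bin, member,
alpha, s_member1, s_member2, s_dyad, s_model, cb_dyad, cb_model,
concordance`. `member` is 0 for max-accuracy rows (one learner per dyad)
and 1/2 for max-similarity rows (one learner per member).

### Escalation cohort CSV

Per dyad: `member{1,2}_M{1..3}` (mean absolute confidence per time bin),
`member{1,2}_index`, `dyad_escalation`, `cb_model`; the cohort Pearson
r/p/n goes to the JSON summary next to it.

## Reproducibility

Every random draw derives from one master seed via numpy `SeedSequence`
(per-dyad spawns; per-(dyad, bin, α-index[, member]) streams inside the
grid search), so identical configs give byte-identical outputs.
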