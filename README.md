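# lagddm

Multi-attribute drift diffusion modelling with **asynchronous attribute
onsets**, for two-attribute (self-payoff / other-payoff) binary dictator-game
choices under a relative-social-status manipulation.

The accumulator follows `E_t = E_{t-1} + nu_t * dt + eps_t` with
`eps_t ~ N(0, 0.1)` per 10 ms step and symmetric boundaries.  The drift
`nu_t = tau_s(t) * omega_s * dMs + tau_o(t) * omega_o * dMo` gates each
attribute by its onset: a *relative start time* (`rst`) > 0 means the
self-payoff difference enters the accumulation first and the other-payoff
difference joins `ceil(rst/dt)` steps later (symmetric for `rst < 0`).
Four candidate variants differ in which parameters the status condition
(better / equal / worse) may modulate:

| variant | weights by status | rst by status | free parameters |
|---------|-------------------|---------------|-----------------|
| 1       | yes               | fixed at 0    | 9               |
| 2       | shared            | yes           | 8               |
| 3       | yes               | shared        | 10              |
| 4       | yes               | yes           | 12              |

The package covers the full analysis chain:

- `lagddm.design` — task-design generation (feedback schedule 60/60/90/90
  collapsing to status counts 90/120/90, option pairs with integer payoffs in
  [1, 20] under |Pearson r| <= 0.1 constraints, dot-stimulus metadata) and
  fully synthetic cohorts driven by the simulator.
- `lagddm.ddm` — the Euler-walk simulator (numba kernels), latency schedules,
  parameter vectors for the four variants.
- `lagddm.likelihood` — simulation-based likelihood (choice x RT-bin
  histogram with smoothing, censored cell), trial exclusion (RT > 10 s or
  beyond mean + 3 SD), and per-subject fitting with differential evolution
  (common random numbers, independent restarts, referee re-ranking).
- `lagddm.selection` — random-effects Bayesian model selection (variational
  Dirichlet updates, Monte-Carlo exceedance probabilities), parameter- and
  model-recovery harnesses.
- `lagddm.behavior` — choice proportions, per-subject logistic decision
  betas, sliding-window betas over RT, split-half cross-validation, social
  value orientation scoring (binary split at 22.45 deg), simple mediation
  with percentile bootstrap.
- `lagddm.io` / `lagddm.config` / `lagddm.pipeline` / `lagddm.cli` —
  CSV interchange, desk/paper scale profiles, the end-to-end pipeline and
  the command-line interface.

Two scale profiles are built in: **desk** (300 simulations/trial, 40 DE
iterations, 4 restarts — used by the test suite) and **paper** (3000
simulations/trial, 150 iterations, 100 restarts).

## CLI

```sh
lagddm --help
simulate-cohort --config cfg.yaml --seed 1 --out cohort.csv
simulate-trial --params params.json --variant 2 --status worse \
    --ms1 15 --mo1 5 --ms2 8 --mo2 12 --n 3000 --seed 1 --out sims.csv
lagddm fit --data cohort.csv --variant 2 --seed 1 --out fits_v2.json
lagddm compare --fits fits_dir/ --out bms.json
lagddm analyze --data cohort.csv --out tables/
lagddm svo --items items.csv
lagddm recover-params --seed 1 --out recovery.json
lagddm recover-models --seed 1 --out confusion.json
lagddm run --config cfg.yaml --seed 1 --out runs/
```

Config files (YAML or JSON) map onto `lagddm.config.RunConfig`; trial tables
are flat CSVs with header
`subject_id, group, trial_index, status, ms1, mo1, ms2, mo2, choice, rt`
(RT in seconds — millisecond-scale columns are rejected at ingestion).

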