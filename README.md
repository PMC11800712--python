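# ivsurvsim

A simulation laboratory for comparing **additive-hazards** and **Cox
(multiplicative)** instrumental-variable estimators of treatment effects on
time-to-event outcomes under unmeasured confounding.

The package generates matched observational cohorts from additive and
multiplicative hazard data-generating mechanisms (exponential and Weibull
baselines, probit treatment assignment, binary instrument), applies six
analysis methods, evaluates the true causal estimands with a Monte-Carlo
oracle, and summarises performance (bias, MC SE, MSE, relative bias,
coverage, power, survival-prediction error).

## Analysis methods

| Code | Method | Native scale |
|------|--------|--------------|
| `AN`  | naive additive-hazards regression adjusting for the measured confounder | hazard difference |
| `CN`  | naive Cox regression adjusting for the measured confounder | log hazard ratio |
| `A2S` | two-stage additive IV (outcome on first-stage predictions) | hazard difference |
| `ARI` | control-function / 2SRI additive IV with time-varying residual effects | hazard difference |
| `C2S` | two-stage Cox IV | log hazard ratio |
| `CSt` | structural Cox g-estimator (effect of treatment in the treated) | log hazard ratio |

All IV methods share a logistic first stage of treatment on the instrument
and the measured confounder (deliberately mis-specified relative to the
probit data-generating model).

## Layout

- `scenario_config` — the 432-scenario factorial grid and its calibration
  (closed-form baseline scales; follow-up restriction and time rescaling for
  additive scenarios so both mechanisms match on 5-year survival).
- `dgm` — cohort simulation: covariates, probit treatment, event times by
  cumulative-hazard inversion (closed form or safeguarded vectorised root
  solve), administrative censoring.
- `first_stage` — IRLS logistic treatment model, predictions, residuals and
  the treatment-probability-difference instrument-strength diagnostic.
- `additive_hazards` — one semiparametric least-squares engine serving the
  constant-effects (Lin–Ying-type), two-stage and control-function fits,
  plus standardized survival prediction with out-of-range flagging.
- `cox_models` — Breslow-tie Newton partial-likelihood fitter (optionally
  weighted), two-stage Cox, the structural g-estimator (survival-power
  moment by default, linearised closed-form variant available), Breslow
  baseline and standardized survival prediction.
- `truth_oracle` — Monte-Carlo true marginal / conditional / treated-subgroup
  contrasts and true survival from a simulated ideal RCT, per follow-up year.
- `evaluation` — replicated runs, per-year censor-and-refit, performance
  metrics, survival-prediction error summaries, deterministic text reports.

## CLI

```sh
# resolved numeric parameters for the full grid (or one scenario)
ivsurvsim calibrate -o manifest.csv
ivsurvsim calibrate --scenario additive:exponential:low:large:moderate:strong

# one observational cohort as a table
ivsurvsim simulate --scenario additive:exponential:low:large:moderate:strong \
    --n 10000 --seed 1 -o cohort.csv

# Monte-Carlo true estimands per follow-up year
ivsurvsim truth --scenario additive:exponential:low:large:moderate:strong \
    --n-mc 2000000 --seed 1 -o truth.csv

# replicated analyses, then metrics against the truth table
ivsurvsim run --scenario additive:exponential:low:large:moderate:strong \
    --reps 1000 --n 10000 --seed 1 -o runs/
ivsurvsim metrics --estimates runs/estimates.csv --truth-table truth.csv -o metrics.csv
ivsurvsim report --estimates runs/estimates.csv --metrics-table metrics.csv -o report/
```

Scenario labels are
`<dgm_form>:<baseline>:<survival_level>:<effect_size>:<iv_strength>:<confounding>`
with levels
`additive|multiplicative`,
`exponential|weibull_decreasing|weibull_increasing`, `high|low`,
`small|medium|large`, `very_weak|weak|moderate|strong`,
and `weak|moderate|strong`.

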