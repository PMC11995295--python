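# cogspan

Multistate modelling of cognitive ageing: who spends how many of their
remaining years cognitively healthy, and how genotype and lifestyle shift
that balance.

`cogspan` is a pipeline for longitudinal surveys of older adults in which
cognition is screened at interviews every few years (so transitions between
cognitive states are interval-censored) while death dates are known exactly.
It implements:

- **Phenotyping** — cognitive state from the MMSE (impaired below 18 points
  or with self-reported dementia), five binary healthy-lifestyle factors
  (non-smoking, no alcohol, diverse diet, physical activity, cognitive
  engagement) grouped 0–1 / 2–3 / 4–5, a regression-weighted Healthy Living
  Index with tertiles, APOE ε2/ε3/ε4 grouping from rs429358/rs7412 with a
  Hardy–Weinberg check, covariate encodings and nearest-wave imputation.
- **A continuous-time three-state Markov model** CH ⇄ CI → Death with
  Gompertz age dependence and proportional covariate effects, fitted by
  maximum likelihood on panel data.
- **Multistate life tables** — state-specific, total and marginal life
  expectancy to a maximum age of 110, with percentile-bootstrap confidence
  intervals.
- **A synthetic cohort generator** with known ground truth, emulating the
  observation process of a national ageing cohort (old-heavy baseline ages
  65–99, interview gaps of 2–4 years over ~15 years, ~63 % observed deaths,
  dropout), so the whole pipeline is testable end to end.

## Model

For living states r ∈ {CH, CI} and destinations s, the transition intensity
of subject *i* at age *a* is

```
q_rs(a, z_i) = exp( α_rs + ξ_rs (a − a0) + β_rsᵀ z_i ),        a0 = 65
```

so `exp(β_rs)` is the hazard ratio of a covariate on transition r→s and
`ξ_rs` is a Gompertz log-linear age slope. Death is absorbing. Transition
probability matrices P(a₁, a₂) are computed under piecewise-constant
intensities on a 1-year (or 1-month) grid using a closed-form 2×2 matrix
exponential of the living-states block. The panel likelihood multiplies
P entries for interval-censored living transitions and P·q sub-densities
for exactly observed deaths; it is maximised by BFGS with an exact analytic
gradient (forward sensitivity through the product of interval factors).

Life expectancy from state r at age a is the occupancy integral

```
e_rs(a) = ∫_a^ω P_rs(a, u) du ,   ω = 110,
```

evaluated by composite midpoint (default) or Simpson quadrature on a yearly
or monthly grid; marginal life expectancy weights the start states by their
prevalence at age a (logistic model of baseline state on age). Confidence
intervals come from resampling subjects with replacement and refitting
(percentile bootstrap, B = 1000 by default).

## Worked example

Generate a 500-subject synthetic cohort, fit the model, and tabulate life
expectancy at 65:

```
$ cogspan synth --n 500 --seed 7 --out synth
wrote synth/panel.csv (500 subjects, 386 deaths)

$ cogspan fit --input synth/panel.csv --out fit
stratum all: loglik=-1313.37 converged=True

$ cogspan le --model fit/model_all.json --age 65 --out le
wrote le/le_grid.csv (54 rows)
```

`fit/hr_all.csv` holds one hazard ratio (with 95 % Wald CI) per covariate
and transition, e.g. for an ε2 carrier the CH→CI row reads
`0.72 (0.30 to 1.77)` — at n = 500 the intervals are wide; they tighten at
cohort scale. `le/le_grid.csv` gives, for a woman with the ε3/ε3 genotype
at age 65:

| lifestyle group | healthy years | impaired years | total |
|---|---|---|---|
| 4–5 healthy factors | 19.35 | 1.32 | 20.68 |
| 0–1 healthy factors | 15.78 | 1.53 | 17.31 |

i.e. in this synthetic cohort a favourable lifestyle adds about 3.6
cognitively healthy years at 65 while the years lived with impairment stay
essentially flat — the qualitative pattern the simulating truth encodes.

The same steps are available as library calls
(`cogspan.GompertzMultistateModel`, `cogspan.state_specific_le`,
`cogspan.bootstrap_le`, …); the estimator follows scikit-learn conventions
(`fit`, `get_params`, fitted attributes with trailing underscores).

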