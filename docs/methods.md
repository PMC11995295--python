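# Methods

## The model

`cogspan` models late-life cognition as a continuous-time Markov process on
three states — cognitively healthy (CH), cognitively impaired (CI, defined
by an MMSE score below 18 or self-reported dementia) and dead — with four
allowed transitions: CH→CI, CH→Death, CI→CH (recovery), CI→Death. Each
transition intensity is Gompertz in age with proportional covariate
effects,

    q_rs(a, z) = exp(alpha_rs + xi_rs (a - a0) + beta_rs' z),   a0 = 65,

so `alpha_rs` is the log intensity at 65 for the reference profile,
`xi_rs` a log-linear age slope per year (a Gompertz hazard on the age
scale), and `exp(beta)` the hazard ratio of a covariate. Age is the time
scale of the process; covariates are fixed at their baseline values
(time-varying covariates other than age are out of scope). The Gompertz
slope is free on all four transitions by default; `gompertz="mortality"`
pins the two living-state slopes at zero for the variant in which only
mortality is age-graded.

Assumptions worth stating explicitly: the process is Markov given age and
covariates (no duration-in-state dependence); living states are observed
without misclassification at interview ages only (interval censoring);
death ages are exact; censoring and interview timing are non-informative.

## Likelihood and its evaluation

The data are consecutive observation pairs. A living→living pair
contributes `log P_{rs}(a1, a2)`; an exactly observed death after a living
observation in state r contributes the sub-density
`log( P_{r,CH}(a1, a_d) q_{CH,D}(a_d) + P_{r,CI}(a1, a_d) q_{CI,D}(a_d) )`;
subjects right-censored at their last interview contribute nothing further.
P(a1, a2) is computed under piecewise-constant intensities on sub-intervals
of width at most `step` (1 year by default, 1/12 for the monthly
sensitivity), each evaluated at its midpoint. Because death is absorbing,
the 2×2 living-states block multiplies independently across sub-intervals;
its matrix exponential is evaluated in closed form from the (always real)
spectrum of the 2×2 generator block, with a first-order Taylor branch when
the two eigenvalues nearly coincide. The kernel agrees with
`scipy.linalg.expm` to machine precision (tested) and with the analytic
solution of the homogeneous illness-death model without recovery.

The midpoint discretisation error in a P entry scales like
`q xi^2 h^2 / 24` per year; at epidemiologically realistic intensities
(≲ 0.05/yr at the evaluation ages) halving the step moves entries by less
than 1e-4, which is the regime the grid-convergence tests pin down. Very
large intensities combined with steep slopes (q ≈ 0.2, |xi| = 0.15) give
~2e-4 — still far below any quantity of interest here, but outside the
1e-4 bound.

Maximisation is quasi-Newton (BFGS) on the unconstrained
`(alpha, xi, beta)` vector with an exact analytic gradient: forward
sensitivity propagation through the product of interval factors, with the
derivative of the closed-form 2×2 exponential with respect to each rate
obtained by complex-step differentiation (step 1e-200, exact to machine
precision; validated against finite differences). The objective is the
mean log-likelihood per observation pair so the gradient-norm tolerance
(default 1e-5) is scale-free. Starting values are log crude occurrence
rates (events / time at risk) with zero slopes and covariate effects;
transitions with no observed events are flagged `weakly_identified_`.
Standard errors come from the observed information, computed by central
differences of the analytic gradient and inverted where non-singular;
Wald intervals are reported (matching common msm-style practice), not
profile intervals. Non-convergence is never silent: the fit carries
`converged_`, the gradient norm, and a warning.

## Life tables

State-specific life expectancy from state r at age a is
`e_rs(a) = ∫_a^ω P_rs(a, u) du` with the maximum age ω = 110. The
occupancy probabilities are evaluated on a half-step grid so that one
product chain yields both midpoint values (cell centres, for the composite
midpoint rule — the default, matching annual life tables) and node values
(cell edges, for composite Simpson with a trapezoid fallback on an odd
final panel). Because e_r,CH and e_r,CI share one quadrature,
`e_total = e_CH + e_CI` holds to machine precision by construction.
At monthly steps Simpson and midpoint agree within 0.01 years and monthly
vs yearly within 0.1 years on the default truth — the two integration
sensitivity checks. Truncation at ω = 110 loses < 0.05 years whenever the
mortality hazard at 110 exceeds 0.5/yr, as it does for every parameter set
used here.

Marginal life expectancy weights start states by their prevalence at a,
estimated by a logistic regression of the baseline living state on
baseline age (the weighting model is a design choice; the package exposes
the weights so any other choice can be substituted).

Uncertainty: percentile bootstrap resampling **subjects** with replacement,
refitting per replicate (warm-started at the full-data MLE) and taking the
empirical 2.5/97.5 percentiles. B defaults to 1000; tests use 25–100.
Replicates that fail or do not converge are dropped and counted; more than
5 % failures flags the result unreliable. Fixed seeds give bit-identical
results.

## Synthetic cohorts

The generator emulates the observation process of a nationwide ageing
survey: baseline ages drawn from an old-heavy three-band mix (26.8 % /
30.5 % / 42.7 % for 65–74 / 75–84 / 85+), APOE groups 68.0 / 14.2 / 17.8 %
(ε3/ε3, ε2 carrier, ε4 carrier), lifestyle groups 17.5 / 63.6 / 18.9 %,
49.1 % women; interviews every 2–4 years (probabilities 0.25/0.50/0.25)
over 15 years with 10 % per-wave dropout; baseline impairment from a
logistic in age (~15 % overall). Default truth hazard ratios are the
published point estimates for genotype, lifestyle group and sex on each
transition; baseline intensities (0.012, 0.018, 0.25, 0.045 at 65) and
slopes (0.08, 0.085, −0.02, 0.08) were chosen once to give roughly 60–65 %
observed deaths and a mean follow-up near 5–6 years, matching the study
conditions the generator stands in for.

Latent trajectories are simulated **exactly**: per-transition event times
by inversion of the Gompertz cumulative hazard (closed form for either
sign of the slope; a bounded cumulative hazard under negative slopes
correctly yields "never"), the minimum winning the competing risk. A
thinning (rejection) sampler is provided as an alternative path and
cross-validated distributionally against inversion. The observation
operator records the latent state at attended interviews, emits deaths
with their exact age when they precede the next attended interview, and
censors deaths after the last attended interview — so the panel never
contains information the survey design could not have seen (impairment
spells between interviews are invisible, which is the point).

What the generator does **not** emulate: misclassification of the MMSE
screen, informative dropout, time-varying lifestyle, survey weights,
household clustering, or secular trends. Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to their violation in real survey data.

## Numerical and design choices

- Reference age a0 = 65; all ages continuous years; interview intervals
  half-open.
- Likelihood floors each pair's contribution at 1e-300 to keep early
  optimizer iterations finite; at any reasonable parameters the floor is
  never active.
- The ambiguous rs429358/rs7412 double heterozygote is resolved as ε2/ε4
  (standard convention without phase information) and excluded, consistent
  with excluding ε2/ε4 carriers; genotype combinations implying the
  vanishingly rare ε1 haplotype are rejected with an explicit error rather
  than forced into the three-group scheme.
- Missing single lifestyle items count as unhealthy; subjects missing all
  five items, or cognition at every wave, are excluded. The 10-year
  smoking/alcohol abstinence threshold is strict (> 10; exactly 10 is not
  "over 10 years"). The ideal-diet cut is fixed at ≥ 5 of 12 daily food
  items rather than recomputed per cohort, keeping the rule deterministic.
- Healthy Living Index weights are absolute logistic-regression
  coefficients of impairment on the five flags, estimated in the input
  cohort and recorded in the run manifest; tertile ties break by stable
  subject-id order so group sizes differ by at most one.
- Test problem sizes: parameter recovery runs at n = 4000 with the full
  covariate set; interval-coverage checks run at n = 500 (50 replicates,
  single covariate) and bootstrap-coverage checks at n = 250 with no
  covariates and B = 100 over 100 cohorts. These sizes keep the full suite
  to a few minutes of CPU while leaving every fit well identified.

## Known limitations

- No hidden-Markov misclassification layer: an MMSE screen is noisy, and
  ignoring that typically inflates apparent recovery (CI→CH) rates.
- Recovery parameters are weakly identified in panel data with 2–4-year
  gaps; their standard errors are honest about this, but fits on small
  cohorts can put the recovery intensity far from truth at little
  likelihood cost.
- Lifestyle is a baseline grouping; behaviour change during follow-up is
  attributed to the baseline group.
- The percentile bootstrap refits the model per replicate and is the
  dominant computational cost; at B = 1000 on cohort-scale data expect
  minutes, not seconds.
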