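# Methods

`bayespop` produces probabilistic age–sex population forecasts for a
closed population by the cohort-component method, with the fertility and
mortality inputs fitted as Bayesian nonlinear growth curves.  This note
records the models, the numerical choices, and what the synthetic-data
experiments do and do not establish.

## Vital-rate models

**Fertility.** The annual total fertility rate (TFR) is modelled as

    Y_i = h(t_i) + e_i,    e_i ~ iid N(0, 1/τ),
    h(t) = d + c · exp(−exp(−b·(t − a)))

with `t` a 1-based year index (first observation year → t = 1).  `d` is the
early-time plateau, `d + c` the late-time asymptote (`c < 0` for a decline),
`b` the transition rate per year, and `a` the index of steepest decline.
Fitted to the Bangladesh series 1991–2001 (11 points), the posterior-mean
curve declines from ≈ 4.3 births per woman at t = 1 towards an eventual
level `d + c` ≈ 1.6.  A nonlinear least-squares cross-check of this
parameterization (a 3.59, b 0.169, c −3.29, d 4.97, residual SD 0.095)
falls inside the published 95% credible intervals for all four parameters.

**Mortality.** Life expectancy at birth (e0), per sex, follows a
four-parameter logistic

    Q_i = p(t_i) + ε_i,    ε_i ~ iid N(0, 1/τ),
    p(t) = q4 + q1 / (1 + exp(q2 − q3·t))

rising from the baseline `q4` to a ceiling `q4 + q1`, with inflection at
`t = q2/q3`.  The sexes are fitted independently; nothing couples the two
posteriors.  The default calendar anchor places the first of 21 annual
observations at 1986 (so t = 21 ≈ 2006); the anchor affects only year
labels.

## Priors

The error precision τ carries a conventional vague gamma(0.001, 0.001)
prior in both models, and is updated by an exact conjugate Gibbs step.

The curve parameters carry independent normal priors whose scale is chosen
per model, *weakly informative on the scale of the data* rather than
arbitrarily diffuse:

- fertility `(a, b, c, d)`: N(0, 3²).  Under a near-flat prior
  (e.g. precision 10⁻⁶) the Gompertz likelihood for a short declining
  series has an unbounded ridge — `b → 0` with `|c|, |d|` growing without
  limit fits an almost-linear decline equally well — so posterior means of
  the curve parameters are then determined by the prior's tails, not the
  data (sampled values of `c`, `d` drift to magnitudes of hundreds).  A
  scale of 3 is diffuse relative to TFR magnitudes (single digits) while
  excluding that degenerate regime; with it the posterior reproduces the
  published summaries closely.
- mortality `(q1..q4)`: N(0, 100²), diffuse relative to life expectancy in
  years.  The analogous `q3 ↔ q1` ridge is bounded at this scale, and the
  mortality results are assessed by recovery coverage, which is insensitive
  to the wide tails.

Both sets are configurable through `RegressionPriors`.

## Sampler

A generic Metropolis-within-Gibbs kernel (`bayespop.mcmc.run_sampler`):

- per-parameter Gaussian random-walk updates, step sizes adapted every 50
  burn-in iterations towards an acceptance rate of 0.44;
- from mid-burn-in, an additional joint random-walk proposal whose
  covariance is refreshed from the chain history every 1,000 iterations and
  whose global scale adapts towards acceptance 0.234 — this is what lets
  the chains traverse the strong `a–c–d` posterior correlations;
- an exact gamma Gibbs draw for τ given the mean curve;
- all adaptation frozen at the end of burn-in, so retained draws come from
  a fixed kernel;
- chain k seeded by `(seed, k)`; identical inputs give bit-identical
  output.  Initial values are crude moment-based estimates scaled by
  alternating factors 1, 1.5, 1/1.5, … across chains for over-dispersion.

Default run lengths are 2 chains with 10,000 burn-in and 80,000 (fertility)
or 70,000 (mortality) retained iterations.  Convergence is monitored by the
classic Gelman–Rubin PSRF (no rank normalization), with 1.1 as the alarm
level and 1.2 as hard failure (draws are still returned, flagged).  The
Monte Carlo error of each posterior mean uses non-overlapping batch means
with ⌈√n⌉ batches per chain, pooled across chains by root mean square; runs
are considered long enough when every parameter's MC error is below 5% of
its posterior SD.  Summary intervals are equal-tailed 2.5/50/97.5
percentiles; a shortest-interval HPD helper is provided separately.

## From rates to projection inputs

**TFR → ASFR.** A projected TFR is spread over the seven 5-year
reproductive age groups by a proportional base-year pattern:
`ASFR_g = TFR · w_g / 5`, so five times the summed rates recovers the TFR
exactly.  The bundled pattern is synthetic and illustrative (documented in
the fixture header); any observed pattern can be supplied.

**e0 → survivorship.** A projected e0 is expanded into an abridged life
table through a Brass relational system around a bundled standard:
`logit(l'ₓ) = α + β·logit(lₓ)` with `logit(p) = ½ln((1−p)/p)`, β fixed at
1, and α solved by bisection until the table's e0 is within 0.01 years of
the target (α is decreasing in e0).  The bundled standard survivorship
columns are *synthetic* smooth schedules with a South-Asian-type age
pattern (e0 61.5 male / 63.9 female at α = 0); they stand in for a
published model life table and can be replaced by editing one CSV.  Life
tables close at 80+ using the standard's `m80`, held fixed across α — an
approximation that slightly misstates open-interval expectancy away from
the standard's level.  Person-years use trapezoids, with separation factor
a0 = 0.3 folding the infant year into the 0–4 group.

## Cohort-component engine

State: counts (thousands) in 17 five-year age groups (0–4 … 75–79, 80+)
per sex.  One 5-year step:

1. survivorship-only pass: `new[i+1] = old[i]·S_i` for closed groups, and
   `new[80+] = (old[75–79] + old[80+])·S_open` with `S_open = T80/T75`
   (the pooled open-interval treatment);
2. births `B = 5·Σ_g ASFR_g·(F_g(t) + F'_g)/2` with `F'` the survived
   female population from step 1 (mid-period exposure convention);
3. births split male:female = 105:100 and survived into 0–4 by
   `S_birth = L0–4 / (5·l0)`;
4. net migration added per configuration (zero by default — a closed
   population).

The step is linear in the start population, and the engine is verified
against an independently coded Leslie-matrix construction to 10⁻⁹ on random
instances.

Uncertainty propagation: each trajectory pairs one fertility draw with one
mortality draw per sex (components are fitted independently, so pairing is
random, seeded); TFR and e0 are evaluated at each step's midpoint year;
per-sex survivorship is looked up through `match_e0` with results cached on
a 0.01-year e0 grid; pointwise 2.5/50/97.5 percentiles across trajectories
give the interval forecasts.  Draws whose e0 falls outside the relational
system's achievable span are clipped to its boundary (rare at the default
regimes).  The default of 500 trajectories keeps a 50-year projection to a
few seconds; increase `n_trajectories` for smoother tails.

## Synthetic data and what the tests show

`bayespop.synthetic` generates series from exactly the likelihood the
fitting routines assume (curve + i.i.d. Gaussian noise), with default
truths set to the reference posterior means for the Bangladesh series:
TFR n = 11 from 1991, e0 n = 21 from 1986, noise SDs 0.1011 (TFR) and
0.6012/0.5063 years (male/female e0).  Values driven below 0.01 by noise
are clipped with a warning rather than rejected (negligible at these
regimes).  The base-population generator draws an exponential young-heavy
pyramid (decay 0.167 per group, matching the 2001 census structure) with
small lognormal perturbations.

Because generator and likelihood agree by construction, recovery failures
indicate sampler defects, not model misspecification — and conversely,
passing recovery says nothing about whether real vital-rate series follow
Gompertz/logistic curves with i.i.d. noise (real series have autocorrelated
measurement error and structural breaks the generator does not emulate).

The observed e0 series behind the published mortality fit is not available,
so the mortality model is validated by recovery coverage (95% intervals
covering truth in ≥ 80% of 20 replicates at reduced run lengths of
5,000 + 20,000 iterations) rather than by reproducing the published
posterior table.  Similarly, the published projection table was produced
with age patterns and life tables that are not available; the engine is
therefore validated against the Leslie oracle and the table's internal
bookkeeping identities (persons = male + female; age sums = totals, within
a 2-thousand rounding tolerance), not cell-by-cell.

## Degenerate inputs and edge cases

- τ ≤ 0 yields log-posterior −∞ (rejected), never an exception; τ Gibbs
  draws are floored at 10⁻³⁰⁰ against underflow in prior-only runs.
- Non-finite proposal evaluations are treated as rejections.
- Projected TFR is floored at 0 (inactive in practice: the fitted lower
  asymptote is ≈ 1.6).
- A constant e0 series drives the logistic towards a flat curve (`q1` or
  `q3` near 0); the fit warns about weak identification.
- `match_e0` raises, naming the achievable range, when a target is
  unreachable for α ∈ [−2, 2].
- Zero posterior SD makes the MC-error rule pass vacuously, with a warning.

## Known limitations

- The relational life-table stand-in cannot reproduce projections made
  with a specific published model life table; absolute projected levels
  depend on the bundled synthetic standard and pattern fixtures.
- Migration is zero by design; the engine accepts per-age net flows but no
  migration model is provided.
- Single-site random walks mix slowly on ridge-shaped posteriors; the
  joint adaptive proposal mitigates but does not eliminate this (watch the
  R-hat flags at short run lengths).
- Period fertility only; no parity or cohort structure.
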