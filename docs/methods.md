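# Methods

`survsync` estimates interpopulation differences and temporal synchrony in
adult survival for two seabird colonies monitored by annual mark-recapture,
asks how much of the shared variation a summer wind covariate explains,
fits a post-hoc breakpoint regression of survival on wind, and projects
the population-level consequences of the imputed survival differences.
This note documents the models, the generator that stands in for the
restricted ringing data, and the numerical choices.

## Survival model

Detection histories are modelled with a state-space Cormack-Jolly-Seber
(CJS) formulation: annual survival is the latent state process, annual
recapture the observation process, both Bernoulli with a logit link.
For colony *c* and year *t*,

    logit φ_{c,t} = logit(α_c) + β_c W_t + γ_t + ε_{φ,c,t}
    logit p_{c,t} = logit(δ_{c,k}) + ε_{p,c,t}

* `α_c` — survival intercept (probability scale; the geometric mean
  survival of the colony);
* `β_c` — colony-specific slope on the centred summer wind speed `W_t`
  (absent in the no-covariate model);
* `γ_t ~ N(0, σ_γ²)` — year effect shared by all colonies (synchronous);
* `ε_{φ,c,t} ~ N(0, σ_{φ,ε}²)` — colony-specific year deviation
  (asynchronous);
* `δ_{c,k}` — trap-dependent recapture intercepts: `k = 1` if the
  individual was captured the year before, `k = 2` otherwise.  The trap
  covariate is the *observed* previous detection, so it conditions on
  data, not on a latent state; the occasion immediately after first
  release always uses `δ_{c,1}`.
* `ε_{p,c,t} ~ N(0, σ_{p,ε}²)` — colony-year recapture noise added to
  both trap states.

A survival interval runs from the end of one breeding season to the end
of the next and is labelled by its terminal year; the covariate for an
interval is the summer wind of its *starting* year (the carry-over
mechanism: breeding-season conditions affect survival through the
following winter), re-centred on whatever year range is fitted.

Priors: uniform(0,1) on every probability intercept, applied on the
logit sampling scale through the inverse-logit Jacobian; N(0,1) on each
`β_c`; uniform(0.1, 10) on the three random-effect SDs (logit scale).

### Likelihood

The latent alive/dead state is marginalised analytically rather than
sampled.  Two equivalent routes are implemented and cross-checked to
machine precision: a per-history two-state forward recursion, and a
closed form over sufficient statistics — counts of known-alive survival
intervals, of the four (capture/miss x seen/unseen) detection events,
and of final releases weighted by the never-seen-again probability

    χ_{c,t} = (1 − φ) + φ (1 − p_seen) ψ_{t+1},
    ψ_t = (1 − φ) + φ (1 − p_unseen) ψ_{t+1}.

The sufficient-statistics form costs O(colonies × occasions) per
evaluation regardless of sample size, which is what makes desk-scale
Bayesian fitting of tens of thousands of histories cheap.

### Sampling

The posterior is sampled with an adaptive Metropolis-within-Gibbs
kernel (componentwise Gaussian random-walk proposals, step sizes adapted
toward 0.44 acceptance during burn-in and frozen afterwards), compiled
with numba.  Three additions matter for mixing:

* ridge moves that translate an intercept against the mean of its
  random-effect block (e.g. `α_c` up, `ε_{φ,c,·}` down) — these
  directions are exactly likelihood-invariant and otherwise mix slowly;
* a per-year partition move (`γ_t` up, every `ε_{φ,c,t}` down).  With
  only two colonies the split of a year effect into shared and
  idiosyncratic parts is identified *only through the priors*, so
  without this move the intra-class correlation barely moves from its
  initialization;
* SD updates use the conditional prior only (the likelihood does not
  involve the SDs directly).

Defaults are desk-scale: 3 chains × 10,000 sweeps, 2,000 burn-in, thin
10.  The study-scale protocol (3 × 100,000, thin 100, 5,000 burn-in) is
available as `MCMCSettings.study_scale()`.  The published protocol's
burn-in accounting (5,000 discarded vs every-100th retained) is
internally ambiguous; here burn-in sweeps are discarded before thinning
and all counts are configurable.  Convergence is summarised by split
R-hat and effective sample size (arviz); R-hat > 1.01 or ESS < 300
warns rather than fails, because short desk-scale chains on small test
problems are expected to trip the ESS threshold.  The final survival
interval and final-occasion recapture deviation are confounded, as in
any CJS; they are reported, not special-cased.

## Synchrony and variance decomposition

The intra-class correlation ICC = σ_γ²/(σ_γ² + σ_{φ,ε}²) is the share
of between-year survival variance common to the colonies.  It is
computed per posterior draw and summarised by the median and central
95% interval; the ICC of the posterior-median variances is reported
alongside under a distinct label because the two differ by a Jensen
gap.  The wind-attributable fraction of each variance component is
ω = 1 − σ²_res/σ²_total from the paired no-covariate/covariate fits,
using the ratio of posterior medians for the point estimate (a per-draw
ω distribution is offered as a labelled extension).  Negative ω is
reported as-is — it is the signature of the covariate modelling noise.

## Wind covariate

Monthly mean northerly and easterly wind components per reanalysis grid
cell are averaged (signed vector means) over May–August, the summer
speed per cell is the hypotenuse of those means, cell speeds are
averaged, and the series is centred on zero.  Averaging months before
taking the hypotenuse is part of the definition: the reverse order
differs whenever the monthly wind direction varies.  Signed means are
used (the standard vector-mean speed); mean absolute components would
be an alternative reading and are not offered.

## Breakpoint regression

Posterior-median survival per colony-year, pooled across colonies, is
regressed on raw wind speed with one breakpoint ψ by iterative
linearization (working design `{1, x, (x−ψ)₊, −1(x>ψ)}`, ψ updated by
the coefficient ratio with step-halving so the RSS never increases on
an accepted step; |Δψ| < 1e−8 or 100 iterations).  Ten bootstrap
restarts guard against dependence on the starting value.  SE(ψ) comes
from the Delta method on the indicator/hinge coefficient ratio with the
OLS covariance; the 95% interval uses the residual-df t quantile, as
segmented-regression software does.  Pure straight-line input leaves
the hinge coefficient indistinguishable from zero and is flagged
degenerate rather than returning a spurious interval.  Fitting is on
the probability scale of survival, unweighted by credible-interval
width.  Pooling the two colonies is the default (per-colony series can
be fitted separately); the uncertainty of the survival medians is not
propagated — a known limitation.

## Population projection

A female-only pre-breeding-census Leslie matrix with age at first
breeding 5: recruitment into age class 1 is `b · (f/2) · φ_j` per
breeding female with fecundity f = 0.64 chicks/pair/yr, breeding
propensity b = 0.87, and first-year survival φ_j = 0.5 · φ_a (a
theoretical scalar — direct juvenile estimates are lacking); immature
classes advance with adult survival φ_a and adults persist with φ_a.
Each colony starts from 4,000 breeding females (pairs, 1:1 sex ratio)
with the younger classes filled from the stable age distribution of the
mean-survival matrix.  Demographic stochasticity draws every survival
transition as a binomial count; recruitment defaults to a single
composite binomial per breeding female (probability b·(f/2)·φ_j ≈ 0.13)
with an expected-value alternative.  Parameter uncertainty enters by
sampling 1,000 complete survival time series from the joint posterior —
both colonies always from the same draw, preserving the cross-colony
correlation the synchrony structure induces.  Annual growth is the
dominant eigenvalue of that year's matrix (year *t*'s survival builds
year *t*'s matrix); the counterfactual ratio divides the colonies'
total female populations per iteration-year, excluding zero
denominators.  Projections ignore density dependence, dispersal,
temporal variation in f and b, and individual heterogeneity: they
quantify the population-level leverage of the survival differences,
not realised colony trajectories.

## Synthetic-data generator

The generator runs the same state-space model forwards: staggered entry
of newly marked individuals (default: uniform over occasions 1..T−5 so
every cohort can be re-detected; real ringing effort schedules are
unknown), Bernoulli survival with the logit-linear predictor above,
trap-dependent Bernoulli detection, and an optional transient fraction
forced to survival zero immediately after release (the standard
idealization of immediate permanent emigration).  The latent
realization (γ, ε, φ, p, W) is returned so recovery tests compare
posteriors against ground truth.  Wind can be drawn internally
(Gaussian, mean 2.25 m/s, SD 0.55 — matching the observed summer-speed
range of roughly 1.1–3.4 m/s) or supplied from the monthly-table
simulator, which adds equicorrelated Gaussian noise to per-cell
components so that per-cell summer-speed series show a chosen rank
correlation (default 0.86, the observed inter-cell value).

Defaults emulate the study system: 44 occasions from 1977; two colonies
with survival intercepts 0.96/0.94; trap-dependent recapture 0.25/0.69
(seen) and 0.16/0.23 (unseen); wind slopes −0.19/−0.23; σ_γ = 1.0,
σ_{φ,ε} = 0.4 (near the published variance medians 1.05 and 0.13–0.16);
σ_{p,ε} = 0.5 (unpublished; a moderate value); entry totals 10,800 and
1,600 with transient fractions 0.35/0.10, chosen so roughly 55% and 27%
of marked birds are never re-detected, the removal rates the transient
filter is meant to reproduce.

What the generator does *not* emulate: individual heterogeneity beyond
the trap response, sex structure, breeder/non-breeder states, dispersal
between colonies, ringing-effort variation, and any non-logit-linear
covariate response.  Passing recovery tests therefore show that the
estimator inverts its own generative model at realistic sizes — not
that the model is adequate for any particular field dataset.

## Preprocessing rules

* Transient filtering keeps exactly the individuals re-detected at
  least once after first release and reports per-colony removal counts;
  it is idempotent.
* Left truncation at a start year drops earlier occasions; individuals
  detected at or after the start keep their history with the first
  post-truncation detection as the release (a CJS likelihood must
  condition on an actual encounter — whether the original study pinned
  such birds to the start year itself or to their first later encounter
  is ambiguous; the first-later-encounter convention is implemented).
* The m-array builder provides the standard sufficient summary
  (releases by occasion of next re-encounter) for external
  goodness-of-fit tools; the RELEASE-style test statistics themselves
  are out of scope.

## Desk-scale test problem sizes

The statistical acceptance tests run: parameter recovery at 2 colonies
× 40 occasions × 600 individuals/colony, 20 replicates, 3 × 12,000
sweeps; synchrony-regime recovery (ICC 0.9 vs 0.2) at the same data
size, 20 pairs, 3 × 8,000 sweeps; breakpoint coverage over 100
replicates at n = 44; projection checks at 1,000 stochastic iterations.
Note that a fixed-truth coverage experiment of this kind is itself a
binomial sample: with eleven parameters each checked against a >=90%
threshold over twenty replicates, occasional sub-threshold counts are
expected from a perfectly calibrated sampler.

## Known limitations

* Apparent survival confounds death with permanent emigration.
* ω from ratios of posterior medians is a point summary; its per-draw
  distribution is wide whenever the variance posteriors overlap.
* The breakpoint regression treats posterior medians as error-free
  responses.
* The Leslie projection's fecundity/propensity are constants borrowed
  from one colony's published profile; results are counterfactual
  comparisons, not forecasts.
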