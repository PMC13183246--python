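# Methods

## The model

`metabovar` models repeated measurements of M metabolite concentrations on N
individuals at up to T timepoints, with L individual-level covariates, as a
multivariate Gaussian linear mixed model

    Y = X β + Z u + ε,

where Y is the (rows × M) response matrix (one row per individual ×
timepoint), X is the fixed-effect design with a leading intercept column and
the covariates untransformed, β is (L+1) × M, Z encodes individual
membership (stored as a row→individual index, never materialised as the
binary matrix), u_i ~ Normal_M(0, G) is individual i's random effect and the
residual rows are ε ~ Normal_M(0, R).  The dense covariance matrices G
(between-individual) and R (within-individual) carry the between-metabolite
dependence; setting both diagonal recovers the univariate "independent"
model, which the package also implements as M separate random-intercept
Gibbs samplers.

The scientific use of the model is individual-level: for every
(individual, timepoint, metabolite) cell a posterior-predictive distribution
β'x_it + u_i + η with η ~ Normal_M(0, R) is accumulated over retained MCMC
draws, a highest-posterior-density (HPD) prediction interval is computed at
the requested levels (defaults 95%, 97.5%, 99%), and an observed value
outside its own interval flags the individual for intra-individual variation
in that metabolite at that timepoint.

## Priors and the empirical-Bayes recipe

* β gets a normal prior with mean β₀ and diagonal covariance B.  Both are
  harvested from the univariate stage: β₀ stacks the per-metabolite
  univariate posterior means, B's diagonal the posterior variances.
* G and R get inverse-Wishart priors with scale matrices Σ² and Σε² and a
  shared degrees-of-freedom ν.  The scale-matrix diagonals take the
  univariate posterior means of σ²_u and σ²_ε; every off-diagonal has
  magnitude 0.1, signed by the pooled Pearson correlation of the observed Y
  (exact zeros and undefined correlations map to +1 by documented
  convention).  ν = ⌈1.5·M⌉ by default.  A scale matrix that fails a
  Cholesky check has its off-diagonal magnitudes halved (0.1 → 0.05 → …)
  until it passes, with a loud warning.
* The univariate stage itself uses weakly informative, scale-aware priors:
  per-coefficient Normal(0, 10⁸·s²) with s² the metabolite's sample
  variance, and inverse-gamma(0.001, 0.001·s²) on both variance components.
  These exist only to harvest posterior summaries, so they are deliberately
  near-flat; every hyperparameter is overridable (e.g. the M = 1 test
  matches the inverse-Wishart prior exactly via explicit shape/rate).

The phrase "variances of the posterior distributions of the random effects
and residuals" admits two readings; the default takes the posterior means of
the variance components (`variance_reading="component_mean"`), which keeps
the scale-matrix diagonals on the data's variance scale.  The alternative
reading — dispersion of the sampled effect and residual draws — is computed
alongside and selectable via `variance_reading="effect_variance"`.

## Inference

The Gaussian response makes every full conditional conjugate, so the sampler
is a systematic-scan Gibbs sampler (a Metropolis-Hastings chain whose
proposals are always accepted):

* **vec(β)** — multivariate normal with precision diag(1/B) + (X'X) ⊗ R⁻¹.
  The vec ordering is metabolite-major throughout: the sampled vector is
  `beta.ravel()` in C order, i.e. blocks per coefficient with the metabolite
  index fastest.
* **u_i** — M-variate normal with precision G⁻¹ + T_i R⁻¹ and linear term
  R⁻¹ Σ_t (y_it − β'x_it).  Individuals sharing an observation count share
  the Cholesky factor, so the update vectorises per count.
* **G | u** — inverse-Wishart(ν + N, Σ² + Σ_i u_i u_i').
* **R | β, u** — inverse-Wishart(ν + n_rows, Σε² + Σ_rows e e').

The inverse-Wishart parameterisation is scipy's: prior mean Σ/(ν − M − 1)
for ν > M + 1.  Initialisation is deterministic (OLS β, zero u, prior-mean
G and R), burn-in is discarded and thinning applied per chain; chain c draws
from `SeedSequence(seed).spawn(...)[c]`, so any run is exactly reproducible
from its master seed.  Default MCMC protocol: 4 chains × 5000 iterations,
2000 burn-in, thinning 3.  Convergence is monitored with the Gelman–Rubin
potential scale reduction factor per scalar parameter (every β, G and R
entry), flagged against a threshold of 1.1; exact-copy chains give the
closed-form √((S−1)/S) and zero-variance parameters are reported undefined.

Each conditional is exposed as a module function (`sample_beta`, `sample_u`,
`sample_G`, `sample_R`, `gibbs_step`) so the test suite can check it against
its closed form in isolation, and the whole sampler is validated by
successive-conditional simulation (alternating prior-respecting data
regeneration with Gibbs scans must leave the prior invariant).

## HPD intervals and flagging

HPD intervals use the Chen–Shao shortest-sample-window estimator: among all
windows of ⌈level·S⌉ consecutive order statistics, the narrowest; ties break
toward the lower start index.  Equal-tail intervals are available behind
`method="central"`.  Empirical shortest windows are not mathematically
nested across levels; observed nesting violations are logged, never hidden.
Flags are computed per marginal metabolite on the raw concentration scale.

Cohort summaries follow the "in a time point" rule: an individual counts at
a level if at least `min_metabolites` metabolites are flagged at one single
timepoint; flags spread over several timepoints do not accumulate.  The
pair-count matrix restricts to those qualifying individuals and counts, for
each metabolite pair, individuals with both flagged at the same timepoint.

A consequence of the in-sample protocol (the observed point is part of the
training data for its own interval) is that predictive intervals are
conservative on well-specified data: at T = 4 the observed deviation from
the fitted cell mean has variance ≈ σ²_ε(1 − 1/T) plus small terms, while
the interval width reflects σ²_ε plus posterior uncertainty, so the
fraction of cells outside a 95% interval is ≈ 1–2%, not the nominal 5%.
The acceptance script reports the measured rate.  Flags remain monotone:
widening the interval never flags more cells.  Leave-one-out prediction,
which would restore nominal calibration, is out of scope.

## Synthetic-data generator and the simulation study

The generator draws data from the model itself, so simulation studies are
well-specified by construction.  Defaults mirror a monthly-sampling human
cohort: N = 150 individuals, T = 4 timepoints, M = 5 metabolites, L = 3
time-invariant covariates with age ~ Normal(35, 12.6²),
BMI ~ Normal(24.1, 3.07²) and sex ~ Bernoulli(111/164).  Intercepts sit on
a plasma-amino-acid-like concentration scale (30–120 units) with modest
covariate effects; per-metabolite variances default to 4 (between
individuals) and 1 (residual), a realistic dominance of between-individual
variation.  Three correlation scenarios are built from fixed target lists
(printed in `simulation.py` and overridable): (1) all pairwise correlations
in [0.1, 0.9] with half in [0.5, 0.9]; (2) exact independence; (3) mixed
correlations in [−0.6, 0.6] with more than half in [−0.3, 0.3].  The
default M = 5 target lists are positive definite as given; other dimensions
use a deterministic generic recipe with a nearest-positive-definite
projection and a re-check of the scenario ranges.

What the generator does **not** emulate: skewed or zero-inflated
concentration distributions, measurement batch effects, missingness
mechanisms, time trends, or covariate-dependent variances.  Passing tests
therefore demonstrate correctness of the inference machinery under the
Gaussian model, not robustness to real-data pathologies.

The study protocol fits both models to each simulated dataset (the
multivariate prior built from the univariate stage on the same data), draws
100 posterior-predictive replicate datasets per model using systematically
spaced retained draws (reproducible, unlike random subsampling), and
computes the mean absolute difference (MAD) between each replicate's
per-timepoint metabolite correlation matrix and the simulated data's.  MAD
averages the strictly-upper-triangular entries (the diagonal would only add
zeros); undefined entries are excluded pairwise.  At the shipped scaled-down
settings (5 datasets, N = 80, 2 chains × 1500 iterations, 100 replicates —
sizes chosen so the full three-scenario study runs in about a minute) the
multivariate model's median MAD is lower than the independent model's at
every timepoint under scenario 1, within 0.05 under scenario 2, and no
worse than the independent model under scenario 3.

## Numerical choices and degenerate inputs

* Complete-case filtering per row: a row with any missing metabolite or
  covariate is excluded from the likelihood; per-cell imputation is out of
  scope.  Intervals are still produced for observed (individual, timepoint)
  pairs whose covariates are available; a missing observed value yields an
  interval with an absent flag marker.
* Pairwise-complete Pearson correlations; a metabolite constant at a
  timepoint gets undefined (NaN) correlations with a warning and is
  excluded pairwise downstream.
* All precision matrices go through Cholesky factorisations; a failure
  anywhere is a hard error naming the block and iteration.  An all-zero R
  (the noise-free testing limit) short-circuits to a zero factor.
* Timepoints are 1-based consecutive integers.  Covariates are not
  standardised internally; that choice (and its effect on the near-flat
  β prior) is the caller's.

## Known limitations

Runtime grows with M³ in the R/G updates and (L+1)³M³ in the β update, so
very wide metabolite panels need longer runs or fewer chains.  The Gaussian
response is an assumption, not a finding; heavy-tailed or truncated
responses are out of scope.  In-sample predictive intervals are
conservative (see above), so the per-cell flag rate at a given level
understates the nominal tail mass — comparisons across individuals and
levels, the method's purpose, are unaffected.
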