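# Methods

## Model

`sigtrend` models the abundance of each gene's transcripts as a smooth,
monotone function of a continuous sample-level covariate (the motivating use
case is a post-surgical prostate-cancer risk score treated as
pseudo-continuous on 0–7, with RNA-extraction batch as a nuisance covariate).

For sample *t* and gene *g*, with design row `X_t` (no intercept, scaled
covariates, column 1 the covariate of interest):

    Y[t, g] ~ NB( exp(delta_t) * GLA(X_t; y0_g, beta_g, eta_g), omega )

where the NB uses the mean/overdispersion convention (variance
`mu + mu^2/omega`) and `GLA` is a generalised (Richards-type) sigmoid with
lower plateau 0,

    GLA(x) = y0 * (1 + exp(eta * beta1)) / (1 + exp(eta * beta1 - x @ beta)).

This is an exact re-parameterisation of the standard form
`GL(x) = kappa / (1 + exp(-(alpha + x @ beta)))` via `alpha = -eta * beta1`,
`kappa = y0 * (1 + exp(eta * beta1))`.  The robust form is parameterised by
the curve value at the covariate origin (`y0`) rather than by the upper
plateau, which remains identified when the data only support a flat or
exponential-like trend: in the standard form the plateau then runs away to
infinity, while `y0` is always anchored by the observed counts.

Priors:

* `beta1_g` (slope of interest): regularised horseshoe —
  `beta1_g ~ N(0, tau * lam_tilde_g)`,
  `lam_tilde_g^2 = c^2 lam_g^2 / (c^2 + tau^2 lam_g^2)`, `lam_g` half-Cauchy,
  `tau` half-Cauchy with scale `tau0 = par_ratio / sqrt(T)`,
  `c^2 ~ slab_scale^2 * scaled-inv-chi2(slab_df)`.  Hyperparameters:
  `nu_local = nu_global = 1`, `par_ratio = 0.8`, `slab_df = 4`,
  `slab_scale = 0.5`.  This encodes the sparsity assumption that most genes
  do not change along the covariate while the slab keeps genuinely changing
  genes from being over-shrunk.  The precise rule linking `par_ratio` to the
  global scale is a configuration choice (`HorseshoeConfig.global_scale_base`
  overrides it); the default `par_ratio / sqrt(T)` is the simplest published
  variant of the expected-nonzero-ratio construction.
* nuisance slopes `beta_{g,k} ~ N(0, sigma_k)`, `sigma_k ~ HalfNormal(0, 1)`;
* intercepts `y0_g ~ Gamma(gamma1 + 1, gamma2)` (shape/rate) with
  `gamma_i ~ Exponential(1)`;
* overdispersion `omega ~ Gamma(1.02, 2)` — a single scalar shared by all
  genes of a block, which is deliberately faithful to the model as stated
  even though gene-wise dispersions are more common in RNA-seq packages;
* inflections `eta_g ~ N(0, 1)` on the scaled covariate axis;
* exposures `delta_t ~ N(0, 1)` with the soft sum-to-zero constraint
  `sum_t delta_t ~ N(0, 0.001 * T)`, which pins the additive
  exposure/intercept non-identifiability.

## Inference

No probabilistic-programming backend is used: the package carries its own
No-U-Turn sampler (multinomial tree doubling, generalised U-turn criterion,
dual-averaging step-size adaptation, Stan-style windowed diagonal
mass-matrix estimation) driven by hand-derived analytic gradients of the
joint log density.  Correctness is enforced two ways in the test suite: the
gradient is checked against central finite differences coordinate by
coordinate, and the unconstrained-space density is checked to equal the
natural-space joint density plus the exact log-Jacobians of the transforms.

Sampling coordinates: all positive parameters on the log scale; the
hierarchical slopes non-centred (`beta1 = z * tau * lam_tilde`,
`beta_k = z * sigma_k`) to remove the funnel geometry that defeats HMC in
centred horseshoe hierarchies.  The likelihood is evaluated purely in terms
of `log mu` (`log(omega + mu)` via `logaddexp`), so no intermediate quantity
overflows even at exponents of several hundred.

Defaults: 4 chains, 1000 warmup + 1000 sampling draws, target acceptance
0.95 (conservative, for the heavy-tailed horseshoe), maximum tree depth 10,
divergence threshold 1000 on the energy error.  A fit aborts with a
`FitError` when more than 10% of post-warmup transitions diverge.  Genes are
partitioned into blocks (default 5000) fit independently, each with its own
exposures and overdispersion; the test suite checks that a dataset fit as
one block and as two blocks gives per-gene slope posteriors agreeing within
posterior uncertainty.  Chains run sequentially; every random quantity
derives from the single user seed through `numpy.random.SeedSequence`
spawn keys, so runs are exactly reproducible.

## Data preparation

Genes with zero counts in strictly more than half of the samples are removed
before fitting.  Continuous covariates are centred and scaled to unit sample
standard deviation; two-level factors are coded ±0.5 and then centred and
scaled the same way.  The scaling parameters are stored so inflection points
can be reported on the raw covariate axis.

## Gene-level outputs

* **Posterior predictive check.**  For each gene and sample, the observed
  count is compared to the pooled posterior-predictive distribution — the NB
  mixture across (thinned) posterior draws, evaluated through its exact
  mixture CDF rather than by resampling, which makes the check deterministic.
  A sample is an outlier when it falls outside the central 95% of that
  mixture (two-sided; a one-sided rule would never flag over-prediction);
  a gene is well fitted when at most 3 samples are outliers.
* **Differential call.**  A gene is differentially transcribed when the
  equal-tailed 95% credible interval of `beta1` excludes zero.  No
  multiplicity adjustment is applied, consistent with standard Bayesian
  reporting practice.
* **Adjusted inflection.**  Because the curve's lower plateau is 0, the
  log-scale curve has no inflection; forcing a lower plateau of 1 gives the
  covariate value where the curve crosses `sqrt(k)`, the geometric midpoint
  between 1 and the upper plateau `k`:

      x_dot = eta - log(sqrt(k) - 1) / beta1,  k = y0 * (1 + exp(eta * beta1)).

  The closed form is validated against bisection on `GLA(x) - sqrt(k)`.  It
  is computed per posterior draw where defined (`beta1 != 0`, `k > 1`),
  back-transformed to the raw covariate scale and summarised by median and
  95% interval over the defined draws; genes with more than 50% undefined
  draws (a new knob — per-draw undefinedness has no established convention)
  get no summary.  Values outside the observed covariate range flag changes
  that happen before or after it.

Equal-tailed (quantile) intervals are used throughout rather than HPD
intervals.  Nuisance covariates are held at their reference (0 after
scaling) when evaluating inflections, so each gene gets a single inflection
on the covariate-of-interest axis.

## Synthetic data

The generator ancestrally samples the model itself: gamma intercepts,
standard-normal inflections, batch slopes `N(0, batch_sd)`, exposures
`N(0, delta_sd)` recentred to sum exactly to zero, and NB counts.  Signal
genes get slopes of magnitude uniform in `effect_range` with random sign —
a controlled, bounded-away-from-zero signal rather than horseshoe draws, so
recovery tests have unambiguous truth.  The cohort-shaped default mimics a
small surgical series: 13 samples, covariate spanning 0–7, two extraction
batches of 6 and 7 samples interleaved along the covariate.

Generator defaults: `gamma1 = 1`, `gamma2 = 0.02` (mean intercept 100
counts, right-skewed), `omega = 10` (moderate RNA-seq-like overdispersion),
`delta_sd = 0.3` (±35% library-size spread), `batch_sd = 0.3`.  What the
generator does **not** emulate: gene–gene correlation, outlier samples,
zero-inflation beyond NB sampling, composition effects or cell-type
mixtures.  Passing recovery and calibration tests on these data therefore
demonstrates the estimator's correctness under its own assumptions, not
robustness to real-data violations of them.

## Problem sizes and numerical choices

The bundled tests and the acceptance script run scaled-down versions of the
analysis chosen to finish on a single CPU in minutes: signal recovery on 200
genes × 13 samples with 20 signal genes (|beta1| in [1, 2]), null
calibration on 100 genes, both at 2 chains × (500 warmup + 500 sampling)
draws.  At these sizes a fit takes a few minutes; the defaults (4 × 2000)
remain the recommendation for real analyses.

Rank correlation between true and estimated slopes is reported among the
signal genes: with 90% of true slopes exactly zero, a rank correlation over
all genes is bounded near 0.5 by the tied zeros alone (the bound is a
property of mid-ranked ties, not of the estimator), so the all-gene value is
also reported but is not an informative recovery measure.

Degenerate inputs: empty count matrices, constant covariates, >2-level
factors, negative or fractional counts, and mismatched gene/sample universes
all raise `InvalidArgumentError` early.  `joint_log_density` returns `-inf`
(not an exception) for type-valid zero-probability states.

## Known limitations

* One shared overdispersion per block (as the model states) under-fits
  genes with atypical dispersion; the posterior predictive check is the
  safety valve that removes them from reporting.
* Blocks are statistically independent: exposures and overdispersion are
  re-estimated per block rather than shared hierarchically.
* The sampler is pure numpy and single-threaded; tens of thousands of genes
  are feasible only through blocking and patience.  Chains could be
  parallelised trivially if needed.
* Monotone trends only: the generalised sigmoid cannot represent
  non-monotone (e.g. transient) expression changes.
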