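# Methods

## Model

For one EIV index at a time, every scored species occurrence enters the
model individually:

```
y_i ~ Normal(alpha_j[i] + beta_j[i] * x_i, sigma_species)    i = 1..n
```

`x_i` is 0 for the first survey period and 1 for the second; no
centering is applied, so `alpha_j` is interpretable as plot *j*'s
period-1 mean score and `beta_j` as its between-period change. Scores
are ordinal in origin (integers, 1–12 for F, 1–9 for L/N/R, 0–9 for S)
but are modelled with a Gaussian likelihood; the depletion experiment
(below) is the empirical check that this approximation serves the
actual goal, accurate plot-mean estimation.

The three variants:

* **M1 (no pooling)** — `(alpha_j, beta_j)` independent across plots
  with wide normal priors. Posterior means equal the per-plot
  least-squares solution (period-1 mean, raw difference) up to prior
  shrinkage that is negligible at the default prior scale.
* **M2 (partial pooling)** — `(alpha_j, beta_j) ~ BVN((mu_alpha,
  mu_beta), Sigma)` with `Sigma` parameterized by standard deviations
  `sigma_alpha`, `sigma_beta` and correlation `rho`.
* **M3 (habitat pooling)** — as M2 but the means carry a categorical
  group-level predictor: `(mu_alpha[k], mu_beta[k])` per habitat `k`.
  `sigma_alpha`/`sigma_beta` then measure residual plot-level spread
  *after* habitat.

## Priors

Minimally informative throughout: `Normal(0, 100)` on all location
parameters (plot effects in M1; population/habitat means in M2/M3),
`Uniform(0, 100)` on `sigma_species`, `sigma_alpha`, `sigma_beta`, and
`Uniform(-1, 1)` on `rho`. The `(sigma, sigma, rho)` decomposition of
the covariance avoids the prior pathologies of an inverse-Wishart on
`Sigma`. Both scales are configurable (`PriorConfig`); doubling the
location-prior sd moves posterior means by well under the Monte-Carlo
error at these data sizes (tested).

## Posterior simulation

The posterior is simulated by a seeded Gibbs sampler written for this
model family. Because `x` is binary, the per-plot likelihood reduces to
counts and score sums per period, giving cheap conjugate blocks:

* `(alpha_j, beta_j) | rest` — bivariate normal, vectorized over plots;
* `sigma_species^2 | rest` — truncated inverse gamma;
* the population block in M2/M3 is updated against the **marginal**
  likelihood with the plot effects integrated out: the pair of per-plot
  period means satisfies
  `(ybar0_j, ybar1_j) ~ BVN(T mu_k, T Sigma T' + diag(s2/n0, s2/n1))`
  with `T = [[1,0],[1,1]]`. `(mu_alpha[k], mu_beta[k])` is conjugate
  under this marginal; `(sigma_alpha, sigma_beta, rho)` takes
  per-coordinate random-walk Metropolis steps on
  `(log sigma_alpha, log sigma_beta, atanh rho)` (two sweeps per scan,
  proposal scales Robbins–Monro-adapted toward ~44% acceptance during
  warmup only, frozen afterwards). The plot effects are then redrawn
  from their exact conditional, which keeps the partially collapsed
  scheme a valid MCMC. Collapsing removes the funnel coupling between
  the random effects and their covariance; split R-hat is ≤ 1.01 and
  bulk ESS several hundred per 1000 retained draws per chain on
  survey-scale fits.

Defaults (`McmcConfig`): 4 chains × (1000 warmup + 1000 retained),
thinning 1. Chains are seeded via `SeedSequence(seed).spawn`, so a fit
is bit-reproducible from `(data, config, seed)`. Each fit computes
split R-hat/ESS (via arviz) and flags `converged_ = False` with a
warning when any R-hat exceeds 1.05. Plots observed in a single period
are retained; the unobserved period's parameter is informed by pooling
(M2/M3) or, in M1, only by its prior (warned).

## Derived quantities

All metrics are computed from raw draws.

* **Bayesian R² per level** (Gelman–Pardoe form): per draw,
  `R² = 1 − V(errors)/V(values)` with `V` the finite-sample variance
  across units; data level uses `y_i − (alpha_j[i] + beta_j[i] x_i)`
  against the observed `y`, the intercept level `alpha_j − mu_alpha(…)`
  against the `alpha_j` draws, the slope level analogously. Reported as
  the posterior mean. Under M2 the level-2 fitted value is a common
  shift within each draw, so level-2 R² is identically zero — a useful
  structural check, and the reason habitat R² isolates what the
  grouping factor explains.
* **Pooling factor** `lambda = 1 − V_j(E_s[eps_j]) / E_s[V_j(eps_j)]`
  over the level-2 errors: 1 means complete pooling, 0 none. Values
  outside [−0.05, 1.05] trigger a warning rather than an error (they
  indicate Monte-Carlo noise or non-convergence).
* **DIC**: `D(theta) = −2 Σ_i log p(y_i | theta)`;
  `pD = Dbar − D(theta_bar)` with `theta_bar` the posterior mean of
  each parameter (classic Spiegelhalter plug-in; for M1 this makes
  `pD ≈ 2·J + 1`, the free-parameter count, which the tests verify);
  `DIC = Dbar + pD`. Per-draw deviances are evaluated in chunks to
  bound memory.
* **Change tables**: equal-tail central 50%/95% credible intervals for
  `beta_j` (plots) and `mu_beta[k]` (habitats), with exclude-zero
  flags; habitat contrasts are formed draw-wise. No multiplicity
  adjustment is applied — partial pooling already regularizes the
  family of estimates.

## Raw-means baseline

The comparison method fits a linear mixed model to the per-(plot,
period) raw mean scores with habitat × period fixed effects and a plot
random intercept (statsmodels `MixedLM`, REML), all plot means
unweighted by species count — deliberately reproducing the traditional
analysis, including its flaws. Habitat-level change contrasts get
unadjusted normal intervals plus family-wise simultaneous intervals:
single-step max-|z| over the estimated contrast correlation matrix (the
equicoordinate multivariate-normal quantile, found by root-finding on
rectangle probabilities) or Bonferroni. When the response is exactly
constant the REML problem is degenerate and the least-squares solution
with zero variances is returned directly.

The phrase "plot random effect nested in time-period" admits two
readings; an independent plot effect per period is unidentifiable here
(one raw mean per plot-period cell leaves it fully confounded with the
residual), so the model uses a plot effect shared across periods — the
term that actually accounts for repeat sampling. This is the one place
the implementation resolves an ambiguity by identifiability.

## Depletion experiment

One plot with more than 50 scored species per (habitat, period) stratum
is selected uniformly at random (a 7-habitat, 2-period survey yields 14
cells); strata without a qualifying plot are skipped with a warning.
Per iteration, each selected cell retains `max(1, round(n·(1−f)))`
species (default removal fraction `f = 0.9`), drawn with a seed derived
from (plan seed, iteration); the selection of plots is fixed across
iterations and only the removed species re-randomized. Default 120
iterations, configurable. Models are refitted on the depleted frame and
each cell's plot mean — `alpha_j` for period-1 cells, `alpha_j +
beta_j` draw-wise for period-2 cells — is summarized and scored against
the cell's **full-data raw mean** (the "true mean"; plots this rich
estimate their own mean well). Aggregated per (index, model): mean
50%/95% interval widths; mean precision, defined as the inverse
variance across iterations of the per-iteration point estimates,
computed per cell then averaged; interval hit proportions; and mean
absolute distance from the true mean. The summary table is exactly
recomputable from the persisted per-iteration raw estimates.

## Synthetic-data generator

`simulate_survey` reads the habitat-pooling model generatively: habitat
means `(mu_alpha[k], mu_beta[k])`, plot effects from the bivariate
normal, species scores from the data-level normal, optional rounding
and clipping to the index's ordinal bounds. Defaults mirror the
variance ordering of real indicator-value resurveys — within-plot sd
1.6 against between-plot 0.35 and between-period 0.3 — and the
`studland_like_preset` emulates a seven-habitat coastal-mosaic survey:
70 plots, two periods, cell richness uniform on 10–120 species.

What the generator does *not* emulate, and hence what passing tests do
not establish about real data: species identities are independent
across plot-period cells (no shared species pool, no repeat occurrence
of a species in both periods), scores are continuous by default rather
than ordinal, there is no detection/recording process, no spatial
autocorrelation, and no abundance weighting. The ordinal-rounding mode
exists precisely to bound the first-order effect of discreteness: at
default magnitudes it moves the fitted `sigma_species` by well under
0.15 (tested).

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately desk-scale
configurations chosen to match the study conditions: a 20-plot
two-habitat survey for the closed-form and shrinkage checks, 50
replicates of a 3-habitat × 8-plot × 30-species survey for interval
calibration, 20 replicates of a 7-habitat × 10-plot survey (the shape
of the real 74-plot survey) for DIC ordering, and 20 depletion
iterations on the preset survey. Reduced chain counts/lengths
(2 × 500-ish) are used where only posterior means and quantiles of
well-mixing quantities are needed; all seeds are fixed.

Ties and degenerate inputs: per-plot retention in depletion never drops
below one species; an exactly-constant response short-circuits the
baseline REML; `sigma = 0` in the generator is handled by an explicit
factor rather than a covariance Cholesky; the truncated inverse-gamma
draw for `sigma_species` resamples on the (never observed in practice)
event of exceeding the prior bound.

## Known limitations

* Gaussian likelihood on ordinal scores; no cumulative-link variant.
* One EIV index per fit; indices are analyzed independently.
* No species-level covariates, abundance/cover weights, spatial terms
  or detection modelling; habitat is the only group-level predictor
  (the submodels for `mu_alpha`/`mu_beta` are the clean extension
  point).
* DIC is the only model-comparison criterion implemented (matching the
  comparison it is used for); no WAIC/LOO.
* The pooling factor is reported as a single posterior-mean-based value;
  its "interval" summary is a Monte-Carlo spread indicator, not a
  posterior for a model parameter.
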