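# Methods

## Model

`hbfm` infers gene co-expression networks from single-cell RNA-seq count
matrices with a sparse hierarchical Bayesian factor model.  Counts are
conditionally Poisson,

    Y_gi | mu_gi ~ Poisson(mu_gi),
    mu_gi = beta_g * prod_f exp{-phi_f/2 |alpha_gf|} * lambda_if^{alpha_gf},

for genes g = 1..G and cells i = 1..N.  The parameters:

* `beta_g > 0` — baseline expression of gene g; equals the marginal mean
  E(Y_gi) for every loading pattern, because each active factor carries the
  compensating `exp{-phi_f/2}` adjustment (the second moment of a
  lognormal).
* `alpha_gf in {-1, 0, 1}` — discrete loading: factor f leaves gene g
  untouched (0), multiplies its mean (+1), or divides it (-1).
* `lambda_if > 0` — cell-specific factor score, log lambda_if ~
  Normal(0, phi_f).  **phi_f is the variance, not the standard deviation,
  of the log score**; this parameterization is forced by the log-mean
  variance identity below and is used consistently everywhere.
* Priors: beta_g ~ Gamma(0.001, 0.001) (shape/rate); |alpha_gf| ~
  Bernoulli(theta_f) with the sign split evenly, theta_f ~ Beta(1, 1);
  phi_f ~ Lognormal(h1, h2), h1 ~ Normal(0, 100) (variance),
  h2 ~ InverseGamma(1, 1) (shape/scale).  All hyperparameters are
  configurable through `PriorSpec`.

Marginally over the factor scores,

    E(Y_gi)   = beta_g,
    Var(Y_gi) = beta_g + beta_g^2 (exp{sum_f phi_f |alpha_gf|} - 1),

so counts are overdispersed whenever any factor is active.  The variance
formula aggregates all active factors and its inflation term is positive;
it is validated against Monte-Carlo simulation in the test suite.

## The correlation statistic and the network

Because log mu_gi = log beta_g + sum_f alpha_gf log lambda_if - const,

    Cov[log mu_g, log mu_g'] = sum_f phi_f alpha_gf alpha_g'f,
    Var[log mu_g]            = sum_f phi_f alpha_gf^2,

giving the pairwise association measure

    rho_gg' = sum_f phi_f alpha_gf alpha_g'f /
              sqrt( (sum_f phi_f alpha_gf^2)(sum_f phi_f alpha_g'f^2) ).

Any 0/0 — a gene with no active factor — is defined as exactly 0,
including that gene's diagonal entry, so inactive genes can never form
edges.  rho is computed at every retained MCMC iteration from the current
(alpha, phi); edge inference is based on its posterior:

* posterior mean rho_hat per pair;
* an equal-tailed credible interval at level 1 - alpha* (default 95%);
  a pair is an edge when the interval excludes zero;
* an approximate p-value a* = 2 min(#neg, #pos)/M over M pooled draws —
  the size of the smallest equal-tailed interval containing zero.
  Equal-tailed intervals (rather than HPD) are used deliberately: they
  make the CI rule and the a* ranking exactly dual up to M-sample
  discreteness.

AUC for benchmark evaluation ranks all unordered pairs by 1/a*, breaking
ties by |rho_hat| and giving remaining ties an average rank.  No
multiple-testing correction is applied to the CI rule.

## Posterior sampling

A Metropolis-within-Gibbs sweep visits, in fixed order: beta (conjugate
Gamma), theta (conjugate Beta), alpha (exact three-way categorical per
entry), h1 (Normal), h2 (InverseGamma), phi (Metropolis), lambda
(Metropolis).  Two derivations deserve note:

* **alpha weights.**  The three unnormalized conditional weights are
  derived directly from the joint density (Poisson likelihood times the
  Bernoulli prior).  Besides the mean-sum terms, the +1 and -1 weights
  carry the data-dependent factors `prod_i lambda_if^{y_gi}` and
  `exp{-phi_f/2 sum_i y_gi}`, which do not cancel across the three
  choices.  The implemented weights are verified against brute-force
  enumeration of the joint in the tests.  All weights are computed on the
  log scale and normalized by log-sum-exp.  Within one factor the gene
  conditionals are mutually independent given everything else, so a whole
  column is drawn jointly; this is equivalent to any one-at-a-time scan
  order.
* **lambda proposal.**  The conditional is
  p(lam) ∝ lam^{kappa-1} exp{-(tau lam + chi/lam + log^2 lam / phi_f)/2} —
  a generalized inverse Gaussian (GIG) shape with an extra lognormal
  term.  The proposal is an independence draw from GIG(kappa, b tau,
  b chi) with b = 0.9, shrinking both rates to thicken the tails;
  Metropolis–Hastings acceptance corrects the difference.  Stationarity
  is proposal-independent (checked at b = 0.9 and b = 1.0).  Boundary
  limits: chi = 0 with kappa > 0 uses the Gamma(kappa, b tau/2) limit;
  tau = 0 with kappa < 0 the InverseGamma(-kappa, b chi/2) limit;
  remaining degenerate combinations fall back to a lognormal-prior
  independence proposal; tau = chi = 0 (inactive factor) is an exact
  prior draw.

phi uses a lognormal random walk: log phi_c ~ Normal(log phi, sigma^2)
with the phi_c/phi Hastings correction.  sigma starts at 0.3 and is
adapted every 50 sweeps toward a 25–45% acceptance rate during the
pre-retention window only, so the retained draws come from a fixed
kernel.  An inactive factor's phi is drawn exactly from its
Lognormal(h1, h2) prior.

GIG variates are generated by a vectorized mode-shifted
ratio-of-uniforms sampler (the bounding rectangle comes from the closed
form roots of a cubic); rare parameter corners that exhaust the rejection
loop fall back to `scipy.stats.geninvgauss`, which also serves as the
reference distribution in the tests.

### Numerical choices

* The sampler maintains W = mu/beta as a dense G x N matrix updated
  multiplicatively when single loadings, scores, or scales change, with a
  full recomputation every 100 sweeps (default) to bound floating-point
  drift; incremental and recomputed values agree to 1e-8 relative in
  tests.
* Gamma distributions are shape/rate; InverseGamma shape/scale.
* phi is truncated at 700 (`PHI_MAX`) and prior draws of log phi and log
  lambda are clamped to [-30, 30].  Both guards bind only in regimes the
  data can never support (variances of order e^30) and keep every
  exponential finite.
* Randomness: each chain derives per-update-block substreams from one
  root seed, so enabling or disabling diagnostics cannot change draws,
  and chain results are independent of execution order.  Chains run
  sequentially.

## Warm starts: stochastic EM

One-at-a-time loading updates cannot split or merge factors, so chains
started at random tend to stick in local modes.  Each chain is therefore
warm-started: from a dispersed random state (baselines at jittered gene
means; loadings iid with P(+1) = P(-1) = 0.1; phi and scores from their
priors at h1 = 0, h2 = 1), 100 full MCMC sweeps are run, then 2,000
stochastic-EM sweeps in which beta is set to its conditional mode
((a-1)/rate, floored at 1e-4 for all-zero genes), alpha to the argmax of
its three conditional probabilities, and phi to the 1-D maximizer of its
conditional (bounded search on log phi), while theta, h1, h2 and the
scores are still sampled.  The last 200 EM iterations are averaged
(continuous parameters) or majority-voted (each loading; ties broken
uniformly at random) into the chain's initial state.

## Model selection

For each candidate number of factors F, eight chains are run (defaults)
and the five with the highest mean retained conditional log-likelihood
log p(Y | beta, alpha, phi, lambda) are kept.  The marginal likelihood
with the scores integrated out is intractable, so this conditional
quantity stands in for it — both for chain ranking and for the deviance
D = -2 log p(Y | ...) entering

    DIC = mean(D) + var(D)/2,

with the sample variance (n-1 denominator) pooled over retained chains;
half the posterior deviance variance estimates the effective parameter
count.  The grid F in {5, 8, 10, 12, 15, 18, 20, 22, 25} is the default;
if the grid maximum wins, one extension by +3 is fitted and compared.
DIC here typically prefers more factors than the generating number —
surplus factors let the sampler explore split factor structures — so the
selected F should be read as an upper working dimension, not an estimate
of the true factor count.

Posterior predictive datasets (PPDs) regenerate counts from retained
(beta, alpha, phi) draws with the factor scores redrawn from their
Lognormal(0, phi_f) priors, and summarize per-gene mean, variance, and
zero proportion — the model's check that it reproduces the
overdispersion and zero-inflation of the observed data.

## Synthetic data

`simulate_counts` draws from the model itself under fixed block loading
designs: G = 50 genes in ten groups of five, all genes of a group sharing
one loading row; beta_g ~ Gamma(3, 0.5) (shape/rate, mean 6);
lambda_if ~ Lognormal(0, phi_f).  Two canonical designs ship with the
package:

* `sim10` — 10 factors, scales {0.20, 0.35, 0.50, 0.65, 0.80} each used
  twice; communities of 4 + 3 + 2 groups each share one factor (with
  mixed signs) plus private factors; exactly 350 true edges (100
  within-group + 250 between-group pairs).
* `sim15` — 15 factors, each scale used three times; communities of
  4 + 4 + 2 groups; exactly 425 true edges.

The exact published wiring of such block designs is generally not
recoverable from edge counts alone; these designs are canonical choices
satisfying all structural constraints (group count, factor count, scale
multiset, edge totals, mixed association signs).  Benchmark numbers
obtained on them are therefore statistical reproductions — same
generative law and structure class, not bit-identical layouts.

`simulate_norta` produces counts whose generative process is *not* the
factor model: per-gene zero-inflated negative binomial marginals coupled
by a Gaussian copula (NORTA: correlated standard normals pushed through
each gene's ZINB quantile function).  The latent correlation defaults to
the log-mean correlation matrix of the matching block design and is
repaired by eigenvalue clipping if a user-supplied matrix is not PSD.
ZINB parameters are user-supplied; `synthetic_zinb_params` provides a
synthetic stand-in set with scRNA-seq-like ranges (it is not estimated
from any real dataset).

What the generators do not emulate: library-size differences between
cells, batch effects, gene-length biases, pseudotime drift, and
dropout that depends on expression magnitude.  Passing recovery tests on
these simulations shows the estimator works when its structural
assumptions (or the ZINB/copula family) hold, not that it is robust to
those real-data artifacts.

## Test-suite problem sizes

The statistical acceptance tests run at sizes chosen to keep the default
suite fast while preserving the regimes of interest: joint-distribution
sampler validation at G = 4, N = 30, F = 2 with proper moderately
informative hyperpriors (the diffuse defaults have essentially
non-integrable prior-predictive moments, which would make a
moment-matching test meaningless; the code paths are identical);
grid-oracle checks of the phi and lambda kernels at 1e5 single-site
iterations; and network recovery on the `sim10` design at N = 125 and
N = 500 with a halved iteration schedule (warm-up 50, EM 1,000, window
100; 2,000 MCMC sweeps retaining 500), four chains keeping three, and
the reduced grid F in {10, 15, 25} without boundary extension.

## Limitations

* DIC and chain ranking condition on the factor scores; models with very
  different effective score dimensionality are compared on a quantity
  that penalizes them only through the deviance spread.
* The Poisson conditional has no gene-level dispersion parameter; all
  overdispersion must be carried by the factors.
* Runtime scales linearly in G, N, F per sweep; exploratory use on
  thousands of genes is impractical — pre-select a focused gene panel
  (typically ≤ ~100 genes).
* No normalization or library-size correction is applied; counts are
  modeled as-is.
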