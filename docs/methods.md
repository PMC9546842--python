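# Methods

This note records the statistical choices behind `silobayes` in one place:
the model, the priors, the sampling algorithm, the convergence and
model-selection machinery, the posterior summaries, and the diversity
statistics. It also states where the package deliberately departs from the
most literal reading of common practice, and why.

## Data and design

The package targets counts of taxa (OTUs) in a two-grain factorial silage
experiment: grain (corn, sorghum) × inoculant (CTRL, Inoc1, Inoc2) ×
fermentation period (0, 3, 7, 21, 90, 360 days) × replicate. Models are
fitted **separately per grain**, so grain never appears as a model term; the
CLI `fit` command splits the table by grain and runs one chain each.

For a single grain with T taxa, P periods and I inoculants, the linear
predictor for the latent log-abundance is

```
l = X b + Z1 u1 + Z2 u2 + Z3 u3 + Z4 u4 + e
```

where

- `X b` holds the intercept and reference-coded period and inoculant
  contrasts (reference levels: period 0 and CTRL), giving
  `1 + (P−1) + (I−1)` columns;
- `u1` is a taxon effect (T levels), `u2` taxon × period (T·P), `u3`
  taxon × inoculant (T·I), and `u4` taxon × period × inoculant (T·P·I),
  each with its own variance `σk²`;
- `e ~ N(0, σe² I)` is an observation-level Gaussian residual, which makes
  the count model a Poisson-lognormal: it absorbs overdispersion relative
  to the pure Poisson.

Absent (taxon, sample) pairs are densified as zero counts: in
sequencing-derived tables a missing pair means "not observed," which is a
zero, not missing data.

## Observation families

Four families share the latent structure (log link except where noted):

- **normal** — identity link, `y_i ~ N(l_i, σ²)`; in this case the latent
  layer is the observation itself and the model is a plain Gaussian mixed
  model.
- **poisson** — `y_i ~ Poisson(exp(l_i))`.
- **zip** (zero-inflated Poisson) — with probability π the count is a
  structural zero, otherwise Poisson.
- **hurdle** (zero-altered Poisson, alias `zap`) — zero with probability π,
  otherwise a zero-truncated Poisson. The two zero-modified families differ
  in whether the count process can also produce zeros (zip: yes; hurdle:
  no).

All likelihoods are computed in log space (`logaddexp`, `expm1`, `gammaln`)
so extreme rates stay finite.

## Priors

- Fixed effects: `b ~ N(0, 10^8 · I)` — effectively flat.
- Block variances: `σk² ~ IG(α/2, αβ/2)` with `α = β = 0.001` for the
  u-blocks, a standard vague inverse-gamma.
- Error variance: the package default keeps `α = 0.001, β = 10^8`, i.e.
  `IG(0.0005, 50000)`. **This prior is only sensible for very large
  datasets**: its prior mass sits at enormous variances, and at a few
  hundred observations it dominates the likelihood and inflates `σe²` by
  orders of magnitude. It is retained as the default for fidelity to the
  protocol the package mirrors, but every desk-scale study in the test
  suite and the acceptance script overrides it with the diffuse
  `hyper={"e": (0.001, 0.001)}`. Users fitting small data should do the
  same (via `ModelSpec(hyper=...)` or the CLI `--config` file).
- Zero probability: `π ~ Beta(1, 1)`.

## Sampling algorithm

The sampler is Metropolis-within-Gibbs. Conditional on the latent vector
`l`, everything is conjugate and is drawn exactly:

- `b` and each `u` block from their Gaussian full conditionals (Cholesky of
  the precision; the u-blocks use a fast path exploiting the diagonal
  `Z'Z` of incidence matrices);
- each `σk²` from its inverse-gamma full conditional;
- π from a Beta (for hurdle, directly conjugate to the zero/positive
  split; for zip, via structural-zero indicator augmentation).

The latent sites are **not** conjugate under the count families, so each
site gets a random-walk Metropolis step targeting
`p(l_i) ∝ family(y_i | l_i, π) · N(l_i | μ_i, σe²)`. Sites are
conditionally independent, so the whole vector is proposed and accepted
element-wise in one vectorized pass. The proposal scale adapts by
Robbins–Monro (`γ_t = t^−0.6`) toward a 0.44 acceptance rate during
burn-in and is frozen afterwards, preserving the correct stationary
distribution.

For zip, the latent update uses the zero-marginalized mixture likelihood
(partially collapsed over the structural-zero indicators), which mixes
better than conditioning on the indicators.

The default run protocol is 2,000,000 sweeps, 100,000 burn-in, thinning 10;
desk-scale work overrides these (the CLI default is 20,000/5,000/10).

Correctness of the transition kernel is tested three ways: two-sample
Kolmogorov–Smirnov tests of each conjugate update against its closed-form
conditional; invariance of the Metropolis step checked against 1-D
quadrature of an exact single-site posterior; and a "getting it right"
successive-conditional simulation test of the full sweep.

## Convergence diagnostics

Geweke's diagnostic compares the means of the first 10% and last 50% of
each scalar chain, studentized by spectral density estimates at frequency
zero from AIC-selected autoregressive fits. A near-unit-root AR fit
(coefficients summing to ≥ 0.999) would make the spectral variance explode
and mask genuine non-stationarity, so in that case the window variance is
used instead — deterministic trends are then flagged with very large |z|.
Constant (degenerate) chains raise an explicit error rather than returning
a silent 0/0.

## Model selection

Candidate models are scored by DIC = Dbar + pD with pD = Dbar − Dhat;
smallest wins, with ties broken toward fewer random-effect blocks and then
by family name.

The default deviance is **marginal in the observation-level residual**:
the Poisson(-mixture) likelihood is integrated over `e ~ N(0, σe²)` by
31-node Gauss–Hermite quadrature, so the deviance is a function of
`μ = Xb + Σ Zk uk`, `σe²` and π. The reason is practical and checked
empirically: the conditional-on-`l` DIC lets a plain Poisson model chase
structural zeros through its free latent sites and it systematically beats
zero-modified families on zero-inflated data, selecting the wrong family.
The marginal DIC restores the correct selection direction in both
directions (Poisson data → Poisson; zero-heavy data → zip/hurdle). The
conditional variant remains available (`variant="conditional"`).

Structure search is restricted to block subsets respecting marginality
(u4 only with u2 and u3; interactions only with u1).

## Posterior summaries

Each (inoculant, period) cell receives posterior draws of its linear
predictor with the taxon-level random-effect contributions averaged
(balanced over taxa), exponentiated draw-wise for response-scale output,
so the reported mean is `E[exp(l)]`, not `exp(E[l])`.

Two cells are declared different when the equal-tailed credibility interval
of the difference of their draws excludes zero. Letter codes come from an
insert-and-absorb compact letter display over the pairwise flags: cells
sorted by descending mean share a letter iff not flagged different.
Comparisons run in two directions — inoculants within each period, or
periods within each inoculant.

The per-cell CV is the posterior standard deviation (n−1 denominator over
retained draws) divided by the posterior mean, on the same scale as the
mean.

## Diversity statistics

- **Chao1**: `S_obs + F1²/(2 F2)` when doubletons exist, and the
  bias-corrected `S_obs + F1(F1−1)/(2(F2+1))` when `F2 = 0`.
- **Gini–Simpson**: `1 − Σ p_i²`, with the inverse form `1/Σ p_i²` behind a
  flag.
- **Pielou's J**: Shannon entropy over `ln(observed richness)`; undefined
  (error) for single-taxon samples.
- **Rarefaction**: samples are standardized to a common depth by
  subsampling reads without replacement (sequential multivariate
  hypergeometric draws); rarefaction curves default to the exact
  closed-form expectation `E[S_d] = Σ_i (1 − C(N−n_i, d)/C(N, d))`,
  computed via log-gamma, which is non-decreasing and concave in depth.

## Synthetic data

`simulate_dataset` draws from exactly the model above (each u-block from
`N(0, σk²)`, residual, then the chosen family), so parameter-recovery and
selection studies are self-consistent. Named scenarios (`corn-like`,
`sorghum-like`, `zero-heavy`, `null`) fix documented effect sizes at the
study's factorial shape; the default desk-scale problem sizes (e.g. 6 taxa
× 3 replicates) are the package's own choice, small enough for minutes-long
studies yet large enough to estimate every block.

## Limitations

- `u4` (taxon × period × inoculant) and the residual `e` are weakly
  separated at one observation per cell-replicate; their variances are
  identified mainly through the prior and the Poisson mean-variance link.
  Posterior summaries that average over `u4` remain well-behaved, but the
  individual variance components should not be over-interpreted.
- The default error-variance prior is unusable at small n (see Priors).
- The credibility-interval separation rule makes no multiplicity
  adjustment beyond what the joint posterior provides; with many
  simultaneous comparisons some false flags are expected under the null
  unless the model pools across cells (the full four-block model is
  conservative in this respect).
- DIC is reported per chain; no accounting is made for Monte-Carlo error
  in Dbar, so very close DIC values should be treated as ties.
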