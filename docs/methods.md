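# Methods

## The model

`multimorb` estimates small-area period life tables in which health is a
three-state outcome: no chronic condition, exactly one, or two or more
(multiple morbidity).  Two linked hierarchical models are fitted per sex.

**Mortality.** Deaths over a multi-year period are binomial per area `a` and
five-year age band `x`,

    D_ax ~ Binomial(T_ax, rho_ax)
    logit(rho_ax) = gamma + b_x + r_a + u_ax + X_a' alpha

with `T_ax` person-years of exposure.  `b` is a first-order random walk over
age bands (`b_x ~ N(b_{x-1}, xi)`, diffuse normal on the initial effect);
`r` is an intrinsic conditional autoregressive (ICAR) field over the area
adjacency graph, shrinking each area toward the mean of its neighbours with
conditional variance `kappa / degree`; `u_ax` are age–area interactions with
band-level spike–slab structure (below); and `X_a` are standardized area
covariates — deprivation with separate coefficients under and over age 65,
a nursing-home indicator entering the mortality predictor for ages 80+ only,
and greenspace.

**Morbidity.** One-year prevalence counts by health state are multinomial,

    (H_ax0, H_ax1, H_ax2) ~ Multinomial(P_ax, pi_ax)
    pi_axj = exp(eta_axj) / sum_k exp(eta_axk),   eta_ax0 = 0
    eta_axk = delta_k + c_xk + s_ak + nu_axk + X_a' beta_k,   k = 1, 2

with the same structure per non-reference category: RW1 age curves `c_k`,
ICAR fields `s_k`, band-level spike–slab interactions `nu_k`, and covariate
blocks `beta_k` (deprivation again split at 65; nursing home and greenspace
at all ages — only the mortality predictor carries the 80+ restriction).

**Spike–slab interactions.** For each band `x` the whole interaction vector
is either drawn from a slab, `u_.x ~ N(0, phi_x)` per area, or is exactly
zero, governed by an inclusion bit `Omega_x ~ Bernoulli(Upsilon_x)` with
`Upsilon_x ~ Beta(1, 1)` per band.  Posterior `Pr(Omega_x = 1 | Y)` reports
whether age-specific area heterogeneity beyond the additive structure is
supported at that band.

**Priors.** N(0, variance 1000) on all fixed effects; Gamma(shape 1, rate
0.01) on every precision (1/xi, 1/kappa, 1/chi_k, 1/kappa_sk, and each slab
precision 1/phi).  The joint log prior includes the ICAR normalizing factor
`kappa^{-(A-G)/2}` (`G` = connected components); it is required for the
conjugate precision updates to target the same density.

## Identifiability

The ICAR prior is improper (flat in the constant direction), so the spatial
fields are constrained to sum to zero: after each sweep `r` (and each `s_k`)
is centered and the shift moved into the intercept, leaving the likelihood
unchanged.  The RW1 level is likewise only identified through the near-flat
prior on its initial value; the age curves are centered the same way, so the
reported `gamma` and `delta_k` are the identified levels (intercept plus
mean age effect).  Recovery tests compare against the correspondingly
transformed generating values.

## Sampling

A hand-written adaptive Metropolis-within-Gibbs sampler (no external PPL):

- fixed effects: scalar random-walk Metropolis, one full-likelihood slice
  per coefficient (deprivation proposals touch only their age range);
- age curves: per-band scalar Metropolis with the RW1 prior evaluated on
  the adjacent increments;
- spatial fields: single-site Metropolis per area against the pairwise ICAR
  prior, then re-centering;
- interactions: for an included band, simultaneous per-cell Metropolis
  (cells are conditionally independent given everything else); the inclusion
  bit is then drawn from its exact conditional, whose odds are the
  likelihood ratio of the band on versus off times `Upsilon/(1-Upsilon)` —
  the latent block keeps its slab prior as pseudo-prior, so prior terms
  cancel; excluded bands have their latents refreshed from the slab;
- variances: conjugate Gamma draws (for the ICAR scales, `n` = areas minus
  components and the pairwise quadratic form as the sum of squares); slab
  variances of excluded bands revert to their prior;
- retention probabilities: conjugate Beta draws per band.

Proposal scales adapt toward 0.44 acceptance by Robbins–Monro during
burn-in only, so retained draws form a time-homogeneous Markov chain.
Chains are initialized at empirical logit rates (fixed effects), zero
(random effects), 0.1 (variances) and all-included interaction bands, which
guarantees a finite posterior from the first sweep.  Defaults follow the
study protocol: two chains of 10,000 iterations with the second halves
retained; convergence is judged by the classical Brooks–Gelman–Rubin
potential scale reduction factor per fixed effect.

A known mixing limitation, documented rather than hidden: with the slab
pseudo-prior, a strongly-supported band that switches off re-enters slowly
(a freshly drawn latent vector is uncorrelated with the data).  A
data-informed pseudo-prior was tried and rejected — it makes flips mobile
but lets an included band collapse into the `phi -> 0` funnel and lock
itself in, producing spurious retention of null bands.  At the scales used
here the conservative behaviour is preferable; inclusion probabilities for
moderate-evidence bands should be read with this in mind.

## Life tables and health expectancies

Modelled rates are converted per posterior draw:

    q_x = rho_x / (1 + 0.5 rho_x)          (final band forced to q = 1)
    l_{x+1} = l_x (1 - q_x);  L_x = n (l_x - 0.5 l_x q_x);  E_x = sum L / l_x

The default death-probability convention (`"literal"`) applies the formula
without a band-width factor; the standard abridged form
`q = n rho / (1 + 0.5 n rho)` is available via `convention=
"abridged_standard"`.  Both close the open final band with the same
half-interval assumption (`L_X = 0.5 n l_X`), which falls out of the
recursion once `q_X = 1`.  `q` is capped at 1 with a warning (the literal
formula can reach 2).  Sullivan health expectancies weight person-years by
prevalence: `HLE1` by `pi_0`, `HLE2` by `1 - pi_2`, summed from the current
band upward — the only reading under which `HLE1 <= HLE2 <= E`, which is
asserted per draw.  Derived indicators: the complex morbidity ratio
`M1 = (E - HLE2)/(HLE2 - HLE1)` (NaN when the denominator vanishes) and the
expected proportion of ages 65–75 spent with multiple morbidity,
piecewise-linear in `HLE2`.  All functionals are computed per draw and only
then summarized, so credible intervals are exact posterior statements.

## Summaries

Directly standardized rates use the 2013 European Standard Population
aggregated to the 18 bands (module constant, sums to 100,000); the weighted
sum is normalized by the weight total so full-range and restricted-range
rates are on the same scale, and rates are reported per 1000.  Areas are
ranked into ten deprivation deciles (decile 1 least deprived; ties broken by
area id; the first `A mod 10` deciles take the extra area); any area
functional is averaged per decile per draw (unweighted across areas) before
summarizing.  Moran's I uses the graph's raw binary weights by default
(`morans_weights: row_standardized` is a config switch) and is applied per
draw of an area surface.

## Posterior predictive checks

Replicates `D_new ~ Bin(T, rho)`, `H_new ~ Mult(P, pi)` are drawn at each
retained draw.  Chi-square discrepancies follow the printed forms —
`sum (D - T rho)^2 / [T rho (1-rho)]` for deaths and
`sum_k (H_k - P pi_k)^2 / [P pi_k]` over all three (linearly dependent)
categories for health — with zero-variance cells skipped.  The posterior
predictive p-value is the fraction of draws with `F_new > F` (strict);
interval exceedance uses type-1 empirical quantiles of the integer
replicates and strict outside-ness, per outcome, excluding zero-denominator
cells.  Discreteness makes the 95% intervals conservative, so exceedance
well under 5% is the norm.

## Synthetic data

The generator emulates the study conditions: 258 areas by default (a 6 × 43
rook-contiguity lattice standing in for real small-area contiguity), 18
quinquennial bands 0–4 … 85+, about 40 residents of one sex per area–age
cell, deaths over 5 years, prevalence for 1 year.  Deprivation is an
ICAR-smoothed Gaussian field (z-scored) so it clusters like a real
deprivation index; nursing homes are Bernoulli(0.2); greenspace is a
z-scored uniform.  Generating fixed effects default to the reported
magnitudes (deprivation on mortality 0.25 under / 0.14 over 65; on
multimorbidity 0.29 / 0.16; on single-condition morbidity 0.05 / 0.09;
nursing home 0.10 on mortality; greenspace 0).  The RW1 age curves are
drawn around deterministic drifts shaped like human schedules (annual death
rates about 1e-3 in childhood rising to 0.15 at 85+; multimorbidity
prevalence about 1% young to 55% at 85+), so life-table output lands in a
realistic range; the drift does not alter the RW1 increment variance.
Interaction truth: slab SD 0.35, with bands switched on for mortality at
65+, single-condition morbidity at all ages and multimorbidity at 50+,
mirroring the reported retention pattern.

What the generator does *not* emulate: real geography and boundary effects,
migration, the construction of the deprivation index, age-profile detail
beyond an optional thinning of the 80+ bands, and any model misspecification
— so passing recovery tests show the estimator is correct under its own
assumptions, not that the model fits real registers.

## Scaled-down test conditions

The test suite exercises recovery on a 10 × 10 lattice with 2 chains × 2000
iterations (the package's choice of a desk-scale study; the full protocol is
2 × 10,000 at 258 areas), predictive checks on every 10th retained draw
(200 draws), and a 1e6-lifeline cohort microsimulation as the life-table
oracle.  At that scale two phenomena are expected and documented: joint
coverage of a dozen 95% intervals on a single dataset is not guaranteed
even for a perfect sampler, and covariate coefficients that live on few
cells (nursing home: ~20 areas × 2 bands) absorb the realized projection of
the spatial and interaction fields — the classical spatial-confounding
effect of ICAR models — so their intervals can exclude the generating value
while correctly covering the likelihood-identified combination.

## Numerical choices

Exposure is rounded to the nearest integer for binomial pmf evaluation;
likelihood ratios use the exponential-family form `D eta - T softplus(eta)`.
Softmax probabilities subtract the row maximum.  Variances are clipped to
[1e-10, 1e10].  Zero-exposure and zero-population cells contribute zero to
every likelihood and are excluded from predictive-check denominators.
Isolated areas are legal, warned about, and contribute nothing to the ICAR
quadratic form.  All randomness flows from a single integer seed per run
(chains draw independent sub-streams), and fixed seeds give byte-identical
output files.
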