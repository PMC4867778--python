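# multimorb

Bayesian spatial life tables for multiple morbidity: how many years can a
resident of a given neighbourhood expect to live, to live free of any
chronic condition, and to live before acquiring two or more conditions —
and how steeply do those expectancies fall with area deprivation?

Healthy-life-expectancy analyses usually treat health as a binary state.
This package models it as three states (no condition / one / two-plus) with
a multinomial likelihood, jointly with a binomial mortality model, across
small areas: for the public-health analyst comparing neighbourhood disease
burdens, and for the methodologist who wants a transparent, fully tested
implementation of the machinery.

## The model

Per sex, area `a` and five-year age band `x` (0–4 … 85+):

```
D_ax ~ Binomial(T_ax, rho_ax)        logit(rho_ax) = gamma + b_x + r_a + u_ax + X_a' alpha
H_ax ~ Multinomial(P_ax, pi_ax)      eta_axk = delta_k + c_xk + s_ak + nu_axk + X_a' beta_k
```

with random-walk age curves `b, c`, intrinsic CAR (ICAR) spatial fields
`r, s` over the area adjacency graph, band-level spike–slab age–area
interactions `u, nu` (a whole band's interaction vector is retained or set
exactly to zero, `Omega_x ~ Bern(Upsilon_x)`), and standardized area
covariates (deprivation with an under/over-65 split, nursing-home presence,
greenspace).  A hand-written adaptive Metropolis-within-Gibbs sampler
(Brooks–Gelman–Rubin diagnostics, conjugate variance and retention updates)
produces posterior draws, which are pushed per draw through a multinomial
Sullivan life table:

```
q_x = rho_x / (1 + 0.5 rho_x)            E  = total life expectancy
HLE1 = sum pi_0 L_x / l                  years free of any condition
HLE2 = sum (1 - pi_2) L_x / l            years free of multiple morbidity
M1 = (E - HLE2) / (HLE2 - HLE1)          complex morbidity ratio
M2 = proportion of ages 65-75 expected in multiple morbidity
```

plus ESP2013 directly standardized rates, deprivation-decile tables,
posterior Moran's I, and chi-square posterior predictive checks.  Because
the study's register data are not public, a first-class synthetic generator
reproduces the full generative structure at any lattice scale.

## Worked example

```python
import multimorb as mm

cfg = mm.SyntheticConfig(n_rows=6, n_cols=6, seed=1)      # 36 areas, 18 bands
ds = mm.simulate_dataset(cfg)
draws = mm.run_chains(ds.table, ds.covariates, ds.graph,
                      mm.McmcConfig(n_chains=2, n_iter=2000, burn_in=1000, seed=1))
print("worst fixed-effect PSRF:", round(max(draws.psrf.values()), 3))

res = mm.life_table_draws(draws.rho.astype(float), draws.pi.astype(float))
area0 = mm.summarize_life_tables(res).iloc[0]
print(f"area 0: E0 = {area0.E0_mean:.1f} ({area0.E0_lo:.1f}, {area0.E0_hi:.1f}) years")
print(f"        HLE2 = {area0.HLE2_mean:.1f} ({area0.HLE2_lo:.1f}, {area0.HLE2_hi:.1f}) years")
print(f"        M1 = {area0.M1_mean:.2f}, M2 = {area0.M2_mean:.2f}")

r_morb = mm.standardized_rate(draws.pi[..., 2].astype(float), mm.StandardWeights())
print("Moran's I of standardized multimorbidity: %.2f (%.2f, %.2f)"
      % mm.posterior_morans_i(r_morb[::5], ds.graph))
```

prints

```
worst fixed-effect PSRF: 1.185
area 0: E0 = 85.2 (84.6, 85.8) years
        HLE2 = 72.8 (71.0, 74.7) years
        M1 = 0.63, M2 = 0.22
Moran's I of standardized multimorbidity: 0.03 (-0.08, 0.15)
```

Read: residents of area 0 can expect 85.2 years of life, 72.8 of them
before multiple morbidity; per expected year lived with exactly one
condition they spend 0.63 years with two or more; 22% of the 65–75 window
is expected in multiple morbidity.  On this small, weakly clustered toy the
multimorbidity surface shows no significant spatial autocorrelation (the
credible interval for Moran's I straddles its null value −1/35).

The same pipeline runs from a shell — `multimorb simulate | fit |
lifetable | summarize | ppc`, each taking `--config run.yaml` and
`--seed` — writing CSV/JSON outputs (counts and chains, per-area expectancy
draws and summaries, decile tables, `morans_i.json`, `ppc.json`).

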