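"""Linear predictors, probabilities, likelihood and prior of the joint model."""

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import binom, gamma as gamma_dist, multinomial, norm

import multimorb as mm
from multimorb.spatial import icar_quadratic


def make_mortality(n_areas=3, n_bands=18, **over):
    base = dict(
        gamma=0.0, b=np.zeros(n_bands), r=np.zeros(n_areas),
        u_latent=np.zeros((n_areas, n_bands)), omega_u=np.ones(n_bands, dtype=int),
        upsilon_u=0.5, phi_u=np.full(n_bands, 0.1), alpha=np.zeros(4),
        xi=0.1, kappa=0.1,
    )
    base.update(over)
    return mm.MortalityParams(**base)


def make_morbidity(n_areas=3, n_bands=18, **over):
    base = dict(
        delta=np.zeros(2), c=np.zeros((n_bands, 2)), s=np.zeros((n_areas, 2)),
        nu_latent=np.zeros((n_areas, n_bands, 2)), omega_nu=np.ones((n_bands, 2), dtype=int),
        upsilon_nu=np.array([0.5, 0.5]), phi_nu=np.full((n_bands, 2), 0.1),
        beta=np.zeros((4, 2)), chi=np.array([0.1, 0.1]), kappa_s=np.array([0.1, 0.1]),
    )
    base.update(over)
    return mm.MorbidityParams(**base)


def make_cov(n_areas=3, seed=0):
    rng = np.random.default_rng(seed)
    dep = rng.standard_normal(n_areas)
    green = rng.standard_normal(n_areas)
    z = lambda v: (v - v.mean()) / v.std()
    return mm.CovariateTable(z(dep), (rng.random(n_areas) < 0.3).astype(float), z(green))


class TestMortalityRate:
    def test_all_zero_parameters_give_half(self):
        assert mm.mortality_rate(make_mortality(), make_cov(), 0, 0) == pytest.approx(0.5)

    def test_intercept_inverts_logit(self):
        mort = make_mortality(gamma=float(logit(0.01)))
        assert mm.mortality_rate(mort, make_cov(), 1, 5) == pytest.approx(0.01)

    def test_hand_computed_linear_predictor(self):
        # gamma=-4, b_x=1, r_a=0.5, X alpha=-0.3 -> logistic(-2.8)
        cov = make_cov()
        mort = make_mortality(gamma=-4.0)
        mort.b[2] = 1.0
        mort.r[1] = 0.5
        mort.alpha[3] = -0.3 / cov.greenspace[1]  # only greenspace active in young bands
        assert mm.mortality_rate(mort, cov, 1, 2) == pytest.approx(expit(-2.8), rel=1e-12)

    def test_age_modifier_boundaries_per_band(self):
        """Deprivation splits at 65 (bands 1-13 vs 14-18); nursing home only 80+."""
        cov = make_cov()
        a = 0
        mort_u = make_mortality(alpha=np.array([1.0, 0.0, 0.0, 0.0]))
        mort_o = make_mortality(alpha=np.array([0.0, 1.0, 0.0, 0.0]))
        mort_n = make_mortality(alpha=np.array([0.0, 0.0, 1.0, 0.0]))
        eta_u = logit(mm.mortality_rates(mort_u, cov))[a]
        eta_o = logit(mm.mortality_rates(mort_o, cov))[a]
        eta_n = logit(mm.mortality_rates(mort_n, cov))[a]
        for x in range(18):
            assert eta_u[x] == pytest.approx(cov.deprivation[a] if x < 13 else 0.0, abs=1e-12)
            assert eta_o[x] == pytest.approx(cov.deprivation[a] if x >= 13 else 0.0, abs=1e-12)
            assert eta_n[x] == pytest.approx(cov.nursing_home[a] if x >= 16 else 0.0, abs=1e-12)

    def test_morbidity_nursing_home_not_age_restricted(self):
        cov = mm.CovariateTable(
            np.array([-1.0, 1.0]), np.array([1.0, 0.0]), np.array([-1.0, 1.0])
        )
        morb = make_morbidity(n_areas=2, beta=np.array([[0, 0], [0, 0], [1.0, 0], [0, 0]], float))
        pi = mm.health_prob_matrix(morb, cov)
        eta1 = np.log(pi[..., 1] / pi[..., 0])
        assert np.allclose(eta1[0], 1.0) and np.allclose(eta1[1], 0.0)


class TestHealthProbs:
    def test_symmetric_logits_give_uniform(self):
        assert mm.health_probs(make_morbidity(), make_cov(), 0, 0) == pytest.approx((1 / 3,) * 3)

    def test_log_two_logit_gives_quarter_half_quarter(self):
        morb = make_morbidity(delta=np.array([np.log(2.0), 0.0]))
        assert mm.health_probs(morb, make_cov(), 2, 7) == pytest.approx((0.25, 0.5, 0.25))

    def test_extreme_logit_is_overflow_safe(self):
        morb = make_morbidity(delta=np.array([1000.0, 0.0]))
        p = mm.health_probs(morb, make_cov(), 0, 0)
        assert np.isfinite(p).all() and p[1] == pytest.approx(1.0)

    def test_rows_always_sum_to_one(self, rng):
        morb = make_morbidity(delta=rng.standard_normal(2) * 3)
        morb.c += rng.standard_normal(morb.c.shape)
        pi = mm.health_prob_matrix(morb, make_cov())
        assert np.allclose(pi.sum(axis=-1), 1.0, atol=1e-12)
        assert np.all(pi > 0)


def _brute_force_loglik(mort, morb, cov, data):
    """Independent oracle: textbook pmfs cell by cell via scipy.stats."""
    total = 0.0
    rho = mm.mortality_rates(mort, cov)
    pi = mm.health_prob_matrix(morb, cov)
    for a in range(data.n_areas):
        for x in range(data.n_bands):
            t = int(round(data.exposure[a, x]))
            if t > 0:
                total += binom.logpmf(int(data.deaths[a, x]), t, rho[a, x])
            p = int(data.pop[a, x])
            if p > 0:
                total += multinomial.logpmf(data.health[a, x].astype(int), p, pi[a, x])
    return total


class TestLogLikelihood:
    def test_matches_brute_force_oracle_on_toy(self, toy_dataset):
        ds = toy_dataset
        got = mm.log_likelihood(ds.mortality_truth, ds.morbidity_truth, ds.covariates, ds.table)
        want = _brute_force_loglik(ds.mortality_truth, ds.morbidity_truth, ds.covariates, ds.table)
        assert got == pytest.approx(want, abs=1e-10)

    def test_zero_exposure_cells_contribute_nothing(self):
        cov = make_cov(2, seed=1)
        data = mm.AreaAgeTable(
            deaths=np.zeros((2, 18)), exposure=np.zeros((2, 18)),
            pop=np.zeros((2, 18)), health=np.zeros((2, 18, 3)),
        )
        assert mm.log_likelihood(make_mortality(2), make_morbidity(2), cov, data) == 0.0

    def test_empirical_rates_maximize_binomial_part(self, rng):
        """Cellwise, the binomial log pmf peaks at rho = D/T."""
        t, d = 50, 17
        grid = np.linspace(0.05, 0.95, 181)
        vals = binom.logpmf(d, t, grid)
        assert grid[np.argmax(vals)] == pytest.approx(d / t, abs=0.005)

    def test_deviance_doubles_with_counts(self):
        """2*(ll(rho_hat) - ll(rho)) doubles when all counts and exposures double."""
        d, t = 12, 100
        rho = 0.07
        dev1 = 2 * (binom.logpmf(d, t, d / t) - binom.logpmf(d, t, rho))
        dev2 = 2 * (binom.logpmf(2 * d, 2 * t, d / t) - binom.logpmf(2 * d, 2 * t, rho))
        assert dev2 == pytest.approx(2 * dev1, rel=1e-9)


def _brute_force_logprior(mort, morb, graph, hyper=mm.Hyperpriors()):
    """Term-by-term oracle using scipy.stats densities directly."""
    v0 = hyper.fixed_effect_variance
    g_pdf = lambda x: gamma_dist.logpdf(x, hyper.precision_shape, scale=1.0 / hyper.precision_rate)
    n_pdf = lambda x, v: norm.logpdf(x, scale=np.sqrt(v))
    rank = graph.n_areas - graph.n_components()
    lp = n_pdf(mort.gamma, v0) + sum(n_pdf(a, v0) for a in mort.alpha)
    lp += n_pdf(mort.b[0], v0) + sum(n_pdf(db, mort.xi) for db in np.diff(mort.b))
    lp += -0.5 * rank * np.log(2 * np.pi * mort.kappa) - icar_quadratic(mort.r, graph) / (2 * mort.kappa)
    for x in range(len(mort.b)):
        if mort.omega_u[x]:
            lp += sum(n_pdf(u, mort.phi_u[x]) for u in mort.u_latent[:, x])
        lp += np.log(mort.upsilon_u[x] if mort.omega_u[x] else 1 - mort.upsilon_u[x])
        lp += g_pdf(1 / mort.phi_u[x])
    lp += g_pdf(1 / mort.xi) + g_pdf(1 / mort.kappa)
    for k in range(2):
        lp += n_pdf(morb.delta[k], v0) + sum(n_pdf(b, v0) for b in morb.beta[:, k])
        lp += n_pdf(morb.c[0, k], v0) + sum(n_pdf(dc, morb.chi[k]) for dc in np.diff(morb.c[:, k]))
        lp += -0.5 * rank * np.log(2 * np.pi * morb.kappa_s[k]) - icar_quadratic(
            morb.s[:, k], graph) / (2 * morb.kappa_s[k])
        for x in range(morb.c.shape[0]):
            if morb.omega_nu[x, k]:
                lp += sum(n_pdf(v, morb.phi_nu[x, k]) for v in morb.nu_latent[:, x, k])
            lp += np.log(morb.upsilon_nu[x, k] if morb.omega_nu[x, k] else 1 - morb.upsilon_nu[x, k])
            lp += g_pdf(1 / morb.phi_nu[x, k])
        lp += g_pdf(1 / morb.chi[k]) + g_pdf(1 / morb.kappa_s[k])
    return float(lp)


class TestLogPrior:
    def test_matches_term_by_term_oracle(self, toy_dataset):
        ds = toy_dataset
        got = mm.log_prior(ds.mortality_truth, ds.morbidity_truth, ds.graph)
        want = _brute_force_logprior(ds.mortality_truth, ds.morbidity_truth, ds.graph)
        assert got == pytest.approx(want, abs=1e-10)

    def test_retention_half_contributes_x_log_half_regardless_of_pattern(self, rng):
        g = mm.build_lattice_graph(2, 2)
        base = dict(n_areas=4)
        for pattern in (np.zeros(18, int), np.ones(18, int), (rng.random(18) < 0.5).astype(int)):
            m1 = make_mortality(omega_u=pattern.copy(), upsilon_u=0.5, **base)
            m2 = make_mortality(omega_u=pattern.copy(), upsilon_u=0.5 + 1e-14, **base)
            lp = mm.log_prior(m1, make_morbidity(4), g)
            # swapping the pattern changes only slab terms; the Bernoulli part is constant
            alt = make_mortality(omega_u=np.roll(pattern, 3), upsilon_u=0.5, **base)
            lp_alt = mm.log_prior(alt, make_morbidity(4), g)
            assert lp == pytest.approx(lp_alt, abs=1e-9)  # all-zero latents: slab terms shift bands only

    def test_zero_state_prior_is_zero_argument_constant(self):
        g = mm.build_lattice_graph(2, 2)
        mort = make_mortality(n_areas=4, omega_u=np.zeros(18, int))
        morb = make_morbidity(n_areas=4, omega_nu=np.zeros((18, 2), int))
        got = mm.log_prior(mort, morb, g)
        want = _brute_force_logprior(mort, morb, g)
        assert got == pytest.approx(want, abs=1e-10) and np.isfinite(got)

    def test_log_posterior_finite_on_valid_state(self, toy_dataset):
        ds = toy_dataset
        lp = mm.log_posterior(
            ds.mortality_truth, ds.morbidity_truth, ds.covariates, ds.table, ds.graph
        )
        assert np.isfinite(lp)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            make_mortality(xi=0.0)


class TestDataContainers:
    def test_table_round_trips_through_frame(self, toy_dataset):
        df = toy_dataset.table.to_frame()
        back = mm.AreaAgeTable.from_frame(df)
        assert np.array_equal(back.deaths, toy_dataset.table.deaths)
        assert np.array_equal(back.health, toy_dataset.table.health)

    def test_health_must_sum_to_pop(self):
        with pytest.raises(ValueError, match="sum to pop"):
            mm.AreaAgeTable(
                deaths=np.zeros((1, 2)), exposure=np.ones((1, 2)),
                pop=np.full((1, 2), 5.0), health=np.ones((1, 2, 3)),
            )

    def test_covariates_must_be_standardized(self):
        with pytest.raises(ValueError, match="standardized"):
            mm.CovariateTable(np.array([1.0, 2.0, 3.0]), np.zeros(3), np.array([-1.0, 0.0, 1.0]) / np.std([-1, 0, 1]))
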