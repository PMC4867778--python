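"""Hierarchical binomial mortality and multinomial morbidity model.

Deaths per area-age cell are binomial, D_ax ~ Bin(T_ax, rho_ax), with
logit(rho_ax) = gamma + b_x + r_a + u_ax + X_a alpha: a random-walk age
curve b, an ICAR spatial field r, band-level spike-slab age-area
interactions u, and standardized area covariates (deprivation with an
under/over-65 effect modifier, nursing-home presence restricted to ages
over 80, greenspace).

Health-state counts (none / one / two-plus chronic conditions) are
multinomial, H_ax ~ Mult(P_ax, pi_ax), with baseline-category logits
eta_axk = delta_k + c_xk + s_ak + nu_axk + X_a beta_k for k in {1, 2}
(category 0 is the reference, eta_ax0 = 0), mirroring the mortality
structure per category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, xlogy

from .spatial import AdjacencyGraph, icar_quadratic

__all__ = [
    "AreaAgeTable",
    "CovariateTable",
    "MortalityParams",
    "MorbidityParams",
    "Hyperpriors",
    "band_masks",
    "mortality_rates",
    "mortality_rate",
    "health_prob_matrix",
    "health_probs",
    "log_likelihood",
    "log_prior",
    "log_posterior",
]

#: coefficient order shared by the mortality alpha block and each beta_k block
COEF_NAMES = ("dep_under65", "dep_over65", "nursing_home", "greenspace")


# -- data containers ------------------------------------------------------


@dataclass
class AreaAgeTable:
    """Observed counts per (area, age band): deaths, exposure, health states.

    ``deaths``/``exposure`` are [A, X]; ``pop`` is the prevalence denominator
    [A, X]; ``health`` is [A, X, 3] with categories (no condition, one
    condition, two or more).  Exposure may be real person-years; all other
    entries are nonnegative integers with ``health.sum(-1) == pop``.
    """

    deaths: np.ndarray
    exposure: np.ndarray
    pop: np.ndarray
    health: np.ndarray

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float)
        self.pop = np.asarray(self.pop, dtype=float)
        self.health = np.asarray(self.health, dtype=float)
        a, x = self.deaths.shape
        if self.exposure.shape != (a, x) or self.pop.shape != (a, x):
            raise ValueError("deaths, exposure, pop must share shape [A, X]")
        if self.health.shape != (a, x, 3):
            raise ValueError("health must have shape [A, X, 3]")
        if np.any(self.deaths < 0) or np.any(self.exposure < 0) or np.any(self.health < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.deaths > self.exposure + 1e-9):
            raise ValueError("deaths exceed exposure in some cell")
        if not np.allclose(self.health.sum(axis=-1), self.pop):
            raise ValueError("health categories must sum to pop in every cell")

    @property
    def n_areas(self) -> int:
        return self.deaths.shape[0]

    @property
    def n_bands(self) -> int:
        return self.deaths.shape[1]

    def to_frame(self) -> pd.DataFrame:
        a, x = np.meshgrid(np.arange(self.n_areas), np.arange(1, self.n_bands + 1), indexing="ij")
        return pd.DataFrame(
            {
                "area_id": a.ravel(),
                "age_band": x.ravel(),
                "deaths": self.deaths.ravel().astype(int),
                "exposure": self.exposure.ravel(),
                "pop": self.pop.ravel().astype(int),
                "h0": self.health[:, :, 0].ravel().astype(int),
                "h1": self.health[:, :, 1].ravel().astype(int),
                "h2": self.health[:, :, 2].ravel().astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AreaAgeTable":
        df = df.sort_values(["area_id", "age_band"])
        areas = df["area_id"].unique()
        bands = df["age_band"].unique()
        a, x = len(areas), len(bands)
        if len(df) != a * x:
            raise ValueError("counts table must be a complete area x age grid")
        shape = (a, x)
        health = np.stack(
            [df[c].to_numpy(float).reshape(shape) for c in ("h0", "h1", "h2")], axis=-1
        )
        return cls(
            deaths=df["deaths"].to_numpy(float).reshape(shape),
            exposure=df["exposure"].to_numpy(float).reshape(shape),
            pop=df["pop"].to_numpy(float).reshape(shape),
            health=health,
        )


@dataclass
class CovariateTable:
    """Standardized area covariates (deprivation, nursing home 0/1, greenspace)."""

    deprivation: np.ndarray
    nursing_home: np.ndarray
    greenspace: np.ndarray

    def __post_init__(self) -> None:
        self.deprivation = np.asarray(self.deprivation, dtype=float)
        self.nursing_home = np.asarray(self.nursing_home, dtype=float)
        self.greenspace = np.asarray(self.greenspace, dtype=float)
        n = self.deprivation.shape[0]
        if self.nursing_home.shape != (n,) or self.greenspace.shape != (n,):
            raise ValueError("covariate columns must share length")
        for name, col in (("deprivation", self.deprivation), ("greenspace", self.greenspace)):
            if abs(col.mean()) > 1e-9 or abs(col.std() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be standardized (mean 0, SD 1)")
        if not set(np.unique(self.nursing_home)).issubset({0.0, 1.0}):
            raise ValueError("nursing_home must be binary 0/1")

    @property
    def n_areas(self) -> int:
        return self.deprivation.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area_id": np.arange(self.n_areas),
                "deprivation": self.deprivation,
                "nursing_home": self.nursing_home.astype(int),
                "greenspace": self.greenspace,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CovariateTable":
        df = df.sort_values("area_id")
        return cls(
            deprivation=df["deprivation"].to_numpy(float),
            nursing_home=df["nursing_home"].to_numpy(float),
            greenspace=df["greenspace"].to_numpy(float),
        )


# -- parameter states -----------------------------------------------------


@dataclass
class MortalityParams:
    """One parameter state of the mortality model.

    ``u_latent`` stores the interaction values whether or not a band is
    retained; the effective interaction is ``u = omega_u * u_latent`` (bands
    with omega 0 contribute exactly zero, the spike).  ``alpha`` follows
    :data:`COEF_NAMES`.
    """

    gamma: float
    b: np.ndarray            # [X] RW1 age effects, variance xi
    r: np.ndarray            # [A] ICAR area effects, scale kappa
    u_latent: np.ndarray     # [A, X]
    omega_u: np.ndarray      # [X] 0/1 band inclusion
    upsilon_u: np.ndarray    # [X] per-band retention probability, Beta(1,1) prior
    phi_u: np.ndarray        # [X] slab variances
    alpha: np.ndarray        # [4]
    xi: float
    kappa: float

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.u_latent = np.asarray(self.u_latent, dtype=float)
        self.omega_u = np.asarray(self.omega_u, dtype=int)
        self.phi_u = np.asarray(self.phi_u, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        x = self.b.shape[0]
        self.upsilon_u = np.broadcast_to(np.asarray(self.upsilon_u, dtype=float), (x,)).copy()
        if self.xi <= 0 or self.kappa <= 0 or np.any(self.phi_u <= 0):
            raise ValueError("variance parameters must be positive")
        if np.any(self.upsilon_u < 0) or np.any(self.upsilon_u > 1):
            raise ValueError("retention probabilities must lie in [0, 1]")

    @property
    def u(self) -> np.ndarray:
        return self.u_latent * self.omega_u[None, :]

    def copy(self) -> "MortalityParams":
        return MortalityParams(
            self.gamma, self.b.copy(), self.r.copy(), self.u_latent.copy(),
            self.omega_u.copy(), self.upsilon_u, self.phi_u.copy(),
            self.alpha.copy(), self.xi, self.kappa,
        )


@dataclass
class MorbidityParams:
    """One parameter state of the morbidity model, per category k in {1, 2}."""

    delta: np.ndarray        # [2] intercepts
    c: np.ndarray            # [X, 2] RW1 age effects, variances chi
    s: np.ndarray            # [A, 2] ICAR area effects, scales kappa_s
    nu_latent: np.ndarray    # [A, X, 2]
    omega_nu: np.ndarray     # [X, 2]
    upsilon_nu: np.ndarray   # [X, 2] per-band retention (a [2] input is broadcast)
    phi_nu: np.ndarray       # [X, 2] slab variances
    beta: np.ndarray         # [4, 2] following COEF_NAMES
    chi: np.ndarray          # [2]
    kappa_s: np.ndarray      # [2]

    def __post_init__(self) -> None:
        for name in ("delta", "c", "s", "nu_latent", "phi_nu", "beta", "chi", "kappa_s"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.omega_nu = np.asarray(self.omega_nu, dtype=int)
        x = self.c.shape[0]
        ups = np.asarray(self.upsilon_nu, dtype=float)
        if ups.shape == (2,):  # one probability per category, shared across bands
            ups = np.broadcast_to(ups[None, :], (x, 2))
        self.upsilon_nu = np.broadcast_to(ups, (x, 2)).copy()
        if np.any(self.chi <= 0) or np.any(self.kappa_s <= 0) or np.any(self.phi_nu <= 0):
            raise ValueError("variance parameters must be positive")
        if np.any(self.upsilon_nu < 0) or np.any(self.upsilon_nu > 1):
            raise ValueError("retention probabilities must lie in [0, 1]")

    @property
    def nu(self) -> np.ndarray:
        return self.nu_latent * self.omega_nu[None, :, :]

    def copy(self) -> "MorbidityParams":
        return MorbidityParams(
            self.delta.copy(), self.c.copy(), self.s.copy(), self.nu_latent.copy(),
            self.omega_nu.copy(), self.upsilon_nu.copy(), self.phi_nu.copy(),
            self.beta.copy(), self.chi.copy(), self.kappa_s.copy(),
        )


@dataclass(frozen=True)
class Hyperpriors:
    """Prior settings: Gamma(shape, rate) on precisions, N(0, var) on fixed effects."""

    precision_shape: float = 1.0
    precision_rate: float = 0.01
    fixed_effect_variance: float = 1000.0


# -- linear predictors ----------------------------------------------------


def band_masks(n_bands: int, band_width: float = 5.0) -> dict[str, np.ndarray]:
    """Boolean band masks for the age effect modifiers.

    Band x (0-based) spans ages [x*w, (x+1)*w); under-65 means start age < 65,
    nursing-home exposure (frail elderly) means start age >= 80.  With 18
    five-year bands this gives bands 1-13 / 14-18 / 17-18 in 1-based terms.
    """
    start = np.arange(n_bands) * band_width
    return {
        "under65": start < 65.0,
        "over65": start >= 65.0,
        "nursing": start >= 80.0,
        "all": np.ones(n_bands, dtype=bool),
    }


def covariate_effect(
    coefs: np.ndarray, cov: CovariateTable, n_bands: int, restrict_nursing: bool, band_width: float = 5.0
) -> np.ndarray:
    """[A, X] contribution X_a * coef with age effect modification.

    Deprivation uses the under/over-65 coefficient split; the nursing-home
    term is restricted to ages over 80 when ``restrict_nursing`` (mortality).
    """
    m = band_masks(n_bands, band_width)
    dep = cov.deprivation[:, None] * (
        coefs[0] * m["under65"][None, :] + coefs[1] * m["over65"][None, :]
    )
    nh_mask = m["nursing"] if restrict_nursing else m["all"]
    nh = coefs[2] * cov.nursing_home[:, None] * nh_mask[None, :]
    green = coefs[3] * cov.greenspace[:, None] * np.ones(n_bands)[None, :]
    return dep + nh + green


def mortality_linear_predictor(
    mort: MortalityParams, cov: CovariateTable, band_width: float = 5.0
) -> np.ndarray:
    x = mort.b.shape[0]
    return (
        mort.gamma
        + mort.b[None, :]
        + mort.r[:, None]
        + mort.u
        + covariate_effect(mort.alpha, cov, x, restrict_nursing=True, band_width=band_width)
    )


def mortality_rates(mort: MortalityParams, cov: CovariateTable, band_width: float = 5.0) -> np.ndarray:
    """Death rates rho_ax = logistic(linear predictor), shape [A, X]."""
    return expit(mortality_linear_predictor(mort, cov, band_width))


def mortality_rate(mort: MortalityParams, cov: CovariateTable, a: int, x: int) -> float:
    """Death rate for a single (area, band) cell; band ``x`` is 0-based."""
    return float(mortality_rates(mort, cov)[a, x])


def morbidity_linear_predictors(
    morb: MorbidityParams, cov: CovariateTable, band_width: float = 5.0
) -> np.ndarray:
    """Baseline-category logits eta_axk, shape [A, X, 2] (eta_ax0 = 0 implied)."""
    x = morb.c.shape[0]
    eta = np.empty((cov.n_areas, x, 2))
    for k in range(2):
        eta[:, :, k] = (
            morb.delta[k]
            + morb.c[None, :, k]
            + morb.s[:, None, k]
            + morb.nu[:, :, k]
            + covariate_effect(morb.beta[:, k], cov, x, restrict_nursing=False, band_width=band_width)
        )
    return eta


def _softmax3(eta: np.ndarray) -> np.ndarray:
    """[..., 2] logits (reference category 0) -> [..., 3] probabilities."""
    full = np.concatenate([np.zeros(eta.shape[:-1] + (1,)), eta], axis=-1)
    full = full - full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def health_prob_matrix(
    morb: MorbidityParams, cov: CovariateTable, band_width: float = 5.0
) -> np.ndarray:
    """Multinomial probabilities pi_axj, shape [A, X, 3], rows summing to 1."""
    return _softmax3(morbidity_linear_predictors(morb, cov, band_width))


def health_probs(morb: MorbidityParams, cov: CovariateTable, a: int, x: int) -> tuple[float, float, float]:
    p = health_prob_matrix(morb, cov)[a, x]
    return float(p[0]), float(p[1]), float(p[2])


# -- likelihood and prior -------------------------------------------------


def log_likelihood(
    mort: MortalityParams,
    morb: MorbidityParams,
    cov: CovariateTable,
    data: AreaAgeTable,
    band_width: float = 5.0,
) -> float:
    """Binomial + multinomial log likelihood summed over cells.

    Cells with zero exposure (deaths) or zero population (health) contribute
    exactly 0.  Real-valued exposure is rounded to the nearest integer for
    the binomial pmf.
    """
    t = np.rint(data.exposure)
    d = data.deaths
    rho = mortality_rates(mort, cov, band_width)
    ll = float(
        np.sum(
            gammaln(t + 1) - gammaln(d + 1) - gammaln(t - d + 1)
            + xlogy(d, rho) + xlogy(t - d, 1.0 - rho)
        )
    )
    pi = health_prob_matrix(morb, cov, band_width)
    h = data.health
    ll += float(
        np.sum(gammaln(data.pop + 1) - gammaln(h + 1).sum(axis=-1) + xlogy(h, pi).sum(axis=-1))
    )
    return ll


def _norm_logpdf(x: np.ndarray | float, var: float | np.ndarray) -> np.ndarray | float:
    return -0.5 * np.log(2.0 * np.pi * var) - 0.5 * np.asarray(x) ** 2 / var


def _rw1_log_prior(path: np.ndarray, var: float, init_var: float) -> float:
    lp = float(_norm_logpdf(path[0], init_var))
    if path.shape[0] > 1:
        lp += float(np.sum(_norm_logpdf(np.diff(path), var)))
    return lp


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return float(shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x)


def _icar_log_prior(vec: np.ndarray, graph: AdjacencyGraph, kappa: float) -> float:
    # proper density on the contrast space up to a kappa-free constant:
    # the kappa^{-(A-G)/2} factor matters for the precision updates
    rank = graph.n_areas - graph.n_components()
    return -0.5 * rank * np.log(2.0 * np.pi * kappa) - icar_quadratic(vec, graph) / (2.0 * kappa)


def _bernoulli_logpmf(omega: np.ndarray, upsilon) -> float:
    upsilon = np.asarray(upsilon, dtype=float)
    omega = np.asarray(omega, dtype=float)
    return float(np.sum(xlogy(omega, upsilon) + xlogy(1.0 - omega, 1.0 - upsilon)))


def log_prior(
    mort: MortalityParams,
    morb: MorbidityParams,
    graph: AdjacencyGraph,
    hyper: Hyperpriors = Hyperpriors(),
) -> float:
    """Joint log prior over both parameter blocks (up to kappa-free constants).

    Terms: diffuse normals on fixed effects; RW1 increments for the age
    curves (diffuse initial effect); ICAR pairwise forms for the spatial
    fields including their kappa^{-rank/2} normalization; slab normals for
    retained interaction bands only (excluded bands sit on the spike);
    Bernoulli terms for the inclusion bits; Beta(1,1) on retention (zero);
    Gamma(shape, rate) on every precision, evaluated on the precision scale.
    """
    v0 = hyper.fixed_effect_variance
    sh, rt = hyper.precision_shape, hyper.precision_rate
    lp = float(_norm_logpdf(mort.gamma, v0))
    lp += float(np.sum(_norm_logpdf(mort.alpha, v0)))
    lp += _rw1_log_prior(mort.b, mort.xi, v0)
    lp += _icar_log_prior(mort.r, graph, mort.kappa)
    for x in range(mort.b.shape[0]):
        if mort.omega_u[x] == 1:
            lp += float(np.sum(_norm_logpdf(mort.u_latent[:, x], mort.phi_u[x])))
    lp += _bernoulli_logpmf(mort.omega_u, mort.upsilon_u)
    lp += _gamma_logpdf(1.0 / mort.xi, sh, rt)
    lp += _gamma_logpdf(1.0 / mort.kappa, sh, rt)
    for x in range(mort.phi_u.shape[0]):
        lp += _gamma_logpdf(1.0 / mort.phi_u[x], sh, rt)

    lp += float(np.sum(_norm_logpdf(morb.delta, v0)))
    lp += float(np.sum(_norm_logpdf(morb.beta, v0)))
    for k in range(2):
        lp += _rw1_log_prior(morb.c[:, k], morb.chi[k], v0)
        lp += _icar_log_prior(morb.s[:, k], graph, morb.kappa_s[k])
        for x in range(morb.c.shape[0]):
            if morb.omega_nu[x, k] == 1:
                lp += float(np.sum(_norm_logpdf(morb.nu_latent[:, x, k], morb.phi_nu[x, k])))
            lp += _gamma_logpdf(1.0 / morb.phi_nu[x, k], sh, rt)
        lp += _bernoulli_logpmf(morb.omega_nu[:, k], morb.upsilon_nu[:, k])
        lp += _gamma_logpdf(1.0 / morb.chi[k], sh, rt)
        lp += _gamma_logpdf(1.0 / morb.kappa_s[k], sh, rt)
    return lp


def log_posterior(
    mort: MortalityParams,
    morb: MorbidityParams,
    cov: CovariateTable,
    data: AreaAgeTable,
    graph: AdjacencyGraph,
    hyper: Hyperpriors = Hyperpriors(),
) -> float:
    return log_likelihood(mort, morb, cov, data) + log_prior(mort, morb, graph, hyper)
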