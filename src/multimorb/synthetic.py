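"""Synthetic small-area mortality/morbidity data with the model's structure.

The study data (an NHS primary-care register and national mortality extracts
for 258 neighbourhoods) are not public.  This generator produces datasets
with exactly the generative structure the model assumes — binomial deaths and
multinomial health-state counts driven by random-walk age curves, ICAR
spatial fields, band-level spike-slab interactions and standardized area
covariates — at a configurable lattice scale, together with the generating
("truth") parameters, so estimation, life-table and summary stages are
testable end to end.

Default magnitudes: fixed covariate effects follow the study's reported
regression coefficients (deprivation on mortality 0.25 under / 0.14 over 65;
deprivation on multimorbidity 0.29 under / 0.16 over 65; on single-condition
morbidity 0.05 / 0.09; nursing home on mortality 0.10; greenspace 0).  The
RW1 age curves are drawn around deterministic drifts shaped like human
mortality and chronic-condition schedules (death rates ~1e-3/yr in childhood
rising to ~0.15/yr at 85+, multimorbidity prevalence ~1% young to ~55% at
85+), so the downstream life tables land in a realistic range.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .model import AreaAgeTable, CovariateTable, MortalityParams, MorbidityParams
from .model import health_prob_matrix, mortality_rates
from .spatial import AdjacencyGraph, build_lattice_graph, sample_icar, write_adjacency

__all__ = [
    "TrueValues",
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_covariates",
    "simulate_true_params",
    "simulate_counts",
    "simulate_dataset",
    "write_dataset",
]

# log-odds of the annual death rate by five-year band (0-4 ... 85+),
# a smoothed England-like schedule; the generator drifts the RW1 around it
_MORT_SCHEDULE = (-6.5, -8.5, -8.3, -7.6, -7.3, -7.1, -6.9, -6.6, -6.3,
                  -5.9, -5.5, -5.1, -4.7, -4.2, -3.7, -3.1, -2.5, -1.8)
# baseline-category logits for one condition (eta1) and two-plus (eta2)
_ETA1_SCHEDULE = (-3.5, -3.4, -3.2, -3.0, -2.7, -2.4, -2.1, -1.9, -1.7,
                  -1.5, -1.3, -1.1, -0.95, -0.8, -0.65, -0.55, -0.5, -0.45)
_ETA2_SCHEDULE = (-6.2, -6.0, -5.6, -5.1, -4.6, -4.1, -3.6, -3.1, -2.6,
                  -2.2, -1.8, -1.4, -1.0, -0.6, -0.2, 0.2, 0.5, 0.7)


@dataclass
class TrueValues:
    """Generating parameter values for one synthetic dataset (one sex).

    Age-band tuples must match ``n_age_bands``.  ``*_trend`` are the
    deterministic drifts added to the RW1 mean paths (variances ``xi`` /
    ``chi`` still govern the stochastic increments, so Var(b_X - b_1) =
    (X-1) xi regardless of the drift).  ``omega_*_bands`` give the 0-based
    bands whose age-area interaction block is switched on; when a band set
    is None the inclusion bits are drawn Bernoulli(upsilon) instead.
    """

    gamma: float = _MORT_SCHEDULE[0]
    b_trend: tuple = tuple(v - _MORT_SCHEDULE[0] for v in _MORT_SCHEDULE)
    alpha: tuple = (0.25, 0.14, 0.10, 0.0)      # dep<65, dep>=65, nursing, green
    delta: tuple = (0.0, 0.0)
    c1_trend: tuple = _ETA1_SCHEDULE
    c2_trend: tuple = _ETA2_SCHEDULE
    beta1: tuple = (0.05, 0.09, 0.0, 0.0)
    beta2: tuple = (0.29, 0.16, 0.0, 0.0)
    xi: float = 0.01
    kappa: float = 0.1
    chi: tuple = (0.01, 0.01)
    kappa_s: tuple = (0.15, 0.15)
    slab_sd: float = 0.35
    omega_u_bands: tuple | None = tuple(range(13, 18))       # mortality: 65+
    omega_nu1_bands: tuple | None = tuple(range(18))         # one condition: all
    omega_nu2_bands: tuple | None = tuple(range(10, 18))     # two-plus: 50+
    upsilon_u: float = 0.5
    upsilon_nu: tuple = (0.5, 0.5)


@dataclass
class SyntheticConfig:
    """Scale and truth of one synthetic study (one sex).

    Defaults emulate the study region: a lattice of 6 x 43 = 258 areas, 18
    quinquennial bands 0-4 ... 85+, ~40 residents of one sex per area-age
    cell, deaths accumulated over a 5-year period and prevalence for 1 year.
    """

    n_rows: int = 6
    n_cols: int = 43
    n_age_bands: int = 18
    band_width_years: float = 5.0
    pop_per_area_age: int = 40
    mortality_period_years: int = 5
    age_profile: str = "uniform"            # or "realistic": thins bands 80-84, 85+
    covariate_smoothing: float = 0.7        # ICAR share of the deprivation field
    nursing_home_prob: float = 0.2
    true_values: TrueValues = field(default_factory=TrueValues)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols < 2:
            raise ValueError("need at least 2 areas")
        tv = self.true_values
        if min(tv.xi, tv.kappa, *tv.chi, *tv.kappa_s) <= 0 or tv.slab_sd <= 0:
            raise ValueError("all variance parameters must be positive")
        for p in (tv.upsilon_u, *tv.upsilon_nu):
            if not 0.0 <= p <= 1.0:
                raise ValueError("retention probabilities must lie in [0, 1]")
        for name in ("b_trend", "c1_trend", "c2_trend"):
            if len(getattr(tv, name)) != self.n_age_bands:
                raise ValueError(f"{name} must have length n_age_bands={self.n_age_bands}")

    @property
    def n_areas(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class SyntheticDataset:
    graph: AdjacencyGraph
    covariates: CovariateTable
    mortality_truth: MortalityParams
    morbidity_truth: MorbidityParams
    table: AreaAgeTable
    config: SyntheticConfig


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def simulate_covariates(
    config: SyntheticConfig, graph: AdjacencyGraph, rng: np.random.Generator
) -> CovariateTable:
    """Standardized covariates: spatially smooth deprivation, nursing homes, greenspace.

    Deprivation mixes an ICAR draw (weight ``covariate_smoothing``) with white
    noise and is z-scored, giving a spatially autocorrelated field like a real
    deprivation index; nursing-home presence is Bernoulli; greenspace is a
    z-scored uniform.
    """
    w = config.covariate_smoothing
    smooth = sample_icar(graph, 1.0, rng)
    smooth = smooth / max(smooth.std(), 1e-12)
    dep = w * smooth + (1.0 - w) * rng.standard_normal(graph.n_areas)
    return CovariateTable(
        deprivation=_zscore(dep),
        nursing_home=(rng.random(graph.n_areas) < config.nursing_home_prob).astype(float),
        greenspace=_zscore(rng.random(graph.n_areas)),
    )


def _rw1_path(trend: np.ndarray, var: float, rng: np.random.Generator) -> np.ndarray:
    path = np.array(trend, dtype=float)
    steps = rng.normal(0.0, np.sqrt(var), size=len(trend) - 1)
    path[1:] += np.cumsum(steps)
    return path


def _omega_vector(bands: tuple | None, upsilon: float, x: int, rng: np.random.Generator) -> np.ndarray:
    if bands is not None:
        om = np.zeros(x, dtype=int)
        om[list(bands)] = 1
        return om
    return (rng.random(x) < upsilon).astype(int)


def simulate_true_params(
    config: SyntheticConfig, graph: AdjacencyGraph, rng: np.random.Generator
) -> tuple[MortalityParams, MorbidityParams]:
    """Draw generating parameters: RW1 age paths, centered ICAR fields, spike-slab bands."""
    tv = config.true_values
    x = config.n_age_bands
    a = graph.n_areas

    b = _rw1_path(np.asarray(tv.b_trend), tv.xi, rng)
    r = sample_icar(graph, tv.kappa, rng)
    omega_u = _omega_vector(tv.omega_u_bands, tv.upsilon_u, x, rng)
    u_latent = rng.normal(0.0, tv.slab_sd, size=(a, x))
    phi_u = np.full(x, tv.slab_sd**2)
    mort = MortalityParams(
        gamma=tv.gamma, b=b, r=r, u_latent=u_latent, omega_u=omega_u,
        upsilon_u=tv.upsilon_u, phi_u=phi_u,
        alpha=np.asarray(tv.alpha, dtype=float), xi=tv.xi, kappa=tv.kappa,
    )

    c = np.column_stack(
        [
            _rw1_path(np.asarray(tv.c1_trend), tv.chi[0], rng),
            _rw1_path(np.asarray(tv.c2_trend), tv.chi[1], rng),
        ]
    )
    s = np.column_stack([sample_icar(graph, tv.kappa_s[k], rng) for k in range(2)])
    omega_nu = np.column_stack(
        [
            _omega_vector(tv.omega_nu1_bands, tv.upsilon_nu[0], x, rng),
            _omega_vector(tv.omega_nu2_bands, tv.upsilon_nu[1], x, rng),
        ]
    )
    nu_latent = rng.normal(0.0, tv.slab_sd, size=(a, x, 2))
    morb = MorbidityParams(
        delta=np.asarray(tv.delta, dtype=float), c=c, s=s, nu_latent=nu_latent,
        omega_nu=omega_nu, upsilon_nu=np.asarray(tv.upsilon_nu, dtype=float),
        phi_nu=np.full((x, 2), tv.slab_sd**2),
        beta=np.column_stack([np.asarray(tv.beta1, float), np.asarray(tv.beta2, float)]),
        chi=np.asarray(tv.chi, dtype=float), kappa_s=np.asarray(tv.kappa_s, dtype=float),
    )
    return mort, morb


def population_grid(config: SyntheticConfig) -> np.ndarray:
    """Annual population per (area, band).  The realistic profile thins 80-84/85+."""
    p = np.full((config.n_areas, config.n_age_bands), float(config.pop_per_area_age))
    if config.age_profile == "realistic" and config.n_age_bands >= 2:
        p[:, -2] = np.rint(p[:, -2] * 0.6)
        p[:, -1] = np.rint(p[:, -1] * 0.4)
    elif config.age_profile != "uniform":
        raise ValueError(f"unknown age_profile {config.age_profile!r}")
    return p


def simulate_counts(
    mort: MortalityParams,
    morb: MorbidityParams,
    covariates: CovariateTable,
    populations: np.ndarray,
    rng: np.random.Generator,
    mortality_period_years: int = 5,
    band_width: float = 5.0,
) -> AreaAgeTable:
    """Draw D ~ Bin(T, rho) and H ~ Mult(P, pi) with T = P * period."""
    populations = np.asarray(populations, dtype=float)
    if np.any(populations < 0):
        raise ValueError("populations must be nonnegative")
    t = np.rint(populations * mortality_period_years)
    rho = mortality_rates(mort, covariates, band_width)
    pi = health_prob_matrix(morb, covariates, band_width)
    assert np.all((rho >= 0) & (rho <= 1)) and np.all(pi >= 0)
    deaths = rng.binomial(t.astype(int), rho)
    flat_p = np.rint(populations).astype(int).ravel()
    flat_pi = pi.reshape(-1, 3)
    health = rng.multinomial(flat_p, flat_pi).reshape(populations.shape + (3,))
    return AreaAgeTable(deaths=deaths, exposure=t, pop=np.rint(populations), health=health)


def simulate_dataset(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Full pipeline input: graph, covariates, truth, and counts, reproducible by seed."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    graph = build_lattice_graph(config.n_rows, config.n_cols)
    cov = simulate_covariates(config, graph, rng)
    mort, morb = simulate_true_params(config, graph, rng)
    table = simulate_counts(
        mort, morb, cov, population_grid(config), rng,
        mortality_period_years=config.mortality_period_years,
        band_width=config.band_width_years,
    )
    return SyntheticDataset(graph, cov, mort, morb, table, config)


def write_dataset(ds: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write counts.csv, covariates.csv, adjacency.csv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.csv",
        "covariates": out / "covariates.csv",
        "adjacency": out / "adjacency.csv",
        "truth": out / "truth.json",
    }
    ds.table.to_frame().to_csv(paths["counts"], index=False)
    ds.covariates.to_frame().to_csv(paths["covariates"], index=False)
    write_adjacency(ds.graph, paths["adjacency"], dialect="edge-list-csv")
    mt, mb = ds.mortality_truth, ds.morbidity_truth
    truth = {
        "config": {
            **{k: v for k, v in asdict(ds.config).items() if k != "true_values"},
            "true_values": asdict(ds.config.true_values),
        },
        "mortality": {
            "gamma": mt.gamma, "b": mt.b.tolist(), "r": mt.r.tolist(),
            "u": mt.u.tolist(), "omega_u": mt.omega_u.tolist(),
            "phi_u": mt.phi_u.tolist(), "alpha": mt.alpha.tolist(),
            "xi": mt.xi, "kappa": mt.kappa,
        },
        "morbidity": {
            "delta": mb.delta.tolist(), "c": mb.c.tolist(), "s": mb.s.tolist(),
            "nu": mb.nu.tolist(), "omega_nu": mb.omega_nu.tolist(),
            "phi_nu": mb.phi_nu.tolist(), "beta": mb.beta.tolist(),
            "chi": mb.chi.tolist(), "kappa_s": mb.kappa_s.tolist(),
        },
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
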