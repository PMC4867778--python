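"""Posterior predictive checks: chi-square discrepancy p-values and interval coverage.

For each retained draw, replicate data Y_new are sampled from the fitted
cell distributions (binomial deaths, multinomial health counts).  Two checks
follow the classical recipes: (a) the posterior predictive p-value is the
proportion of draws where the chi-square discrepancy of the replicate,
F_new, strictly exceeds that of the observed data, F, both evaluated at the
draw's parameters — extreme values (below 0.05 or above 0.95) flag model
discrepancy; (b) the percentage of observed cells falling strictly outside
the central 95% interval of their replicates, per outcome (deaths, one
condition, two-plus conditions) — 5% or less is expected from a
well-specified model, typically less because counts are discrete.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .model import AreaAgeTable

logger = logging.getLogger(__name__)

__all__ = [
    "replicate",
    "chisq_discrepancy",
    "deaths_chisq",
    "health_chisq",
    "ppp_value",
    "interval_exceedance",
    "PpcResult",
    "run_ppc",
]


def replicate(
    rho: np.ndarray, pi: np.ndarray, data: AreaAgeTable, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Replicated counts at one draw: D_new ~ Bin(T, rho), H_new ~ Mult(P, pi)."""
    t = np.rint(data.exposure).astype(int)
    d_new = rng.binomial(t, np.asarray(rho, dtype=float))
    p = np.rint(data.pop).astype(int).ravel()
    pv = np.asarray(pi, dtype=float).reshape(-1, 3)
    pv = pv / pv.sum(axis=1, keepdims=True)
    h_new = rng.multinomial(p, pv).reshape(data.pop.shape + (3,))
    return d_new, h_new


def chisq_discrepancy(counts: np.ndarray, expected: np.ndarray, variance: np.ndarray) -> float:
    """F = sum (count - expected)^2 / variance over cells with positive variance.

    Cells with zero variance (zero denominators or degenerate probabilities)
    are skipped; the number skipped is logged at debug level.
    """
    counts = np.asarray(counts, dtype=float)
    expected = np.asarray(expected, dtype=float)
    variance = np.asarray(variance, dtype=float)
    ok = variance > 0
    skipped = counts.size - int(ok.sum())
    if skipped:
        logger.debug("chi-square discrepancy skipped %d zero-variance cell(s)", skipped)
    dev = counts[ok] - expected[ok]
    return float(np.sum(dev * dev / variance[ok]))


def deaths_chisq(deaths: np.ndarray, exposure: np.ndarray, rho: np.ndarray) -> float:
    """Binomial fit measure sum (D - T rho)^2 / [T rho (1 - rho)]."""
    t = np.rint(np.asarray(exposure, dtype=float))
    rho = np.asarray(rho, dtype=float)
    return chisq_discrepancy(deaths, t * rho, t * rho * (1.0 - rho))


def health_chisq(health: np.ndarray, pop: np.ndarray, pi: np.ndarray) -> float:
    """Multinomial fit measure sum_k (H_k - P pi_k)^2 / [P pi_k], all 3 categories."""
    p = np.asarray(pop, dtype=float)[..., None]
    pi = np.asarray(pi, dtype=float)
    return chisq_discrepancy(health, p * pi, p * pi)


def ppp_value(
    rho_draws: np.ndarray,
    pi_draws: np.ndarray,
    data: AreaAgeTable,
    which: str,
    rng: np.random.Generator,
) -> float:
    """Posterior predictive p-value: the fraction of draws with F_new > F."""
    if which not in ("deaths", "health"):
        raise ValueError("which must be 'deaths' or 'health'")
    n = rho_draws.shape[0]
    exceed = 0
    for i in range(n):
        d_new, h_new = replicate(rho_draws[i], pi_draws[i], data, rng)
        if which == "deaths":
            f = deaths_chisq(data.deaths, data.exposure, rho_draws[i])
            f_new = deaths_chisq(d_new, data.exposure, rho_draws[i])
        else:
            f = health_chisq(data.health, data.pop, pi_draws[i])
            f_new = health_chisq(h_new, data.pop, pi_draws[i])
        exceed += int(f_new > f)
    return exceed / n


def interval_exceedance(
    rho_draws: np.ndarray,
    pi_draws: np.ndarray,
    data: AreaAgeTable,
    rng: np.random.Generator,
    level: float = 0.95,
) -> dict:
    """Percent of observed cells strictly outside the central predictive interval.

    Interval endpoints are empirical inverse-CDF (type-1) quantiles of the
    replicated counts across draws; a cell counts as outside only if the
    observation is strictly below the lower or strictly above the upper
    endpoint.  Cells with zero denominator are excluded.  Returns
    percentages per outcome: deaths, one condition, two-plus conditions.
    """
    n = rho_draws.shape[0]
    d_reps = np.empty((n,) + data.deaths.shape)
    h_reps = np.empty((n,) + data.health.shape)
    for i in range(n):
        d_reps[i], h_reps[i] = replicate(rho_draws[i], pi_draws[i], data, rng)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2

    def _pct(reps: np.ndarray, obs: np.ndarray, denom: np.ndarray) -> float:
        lo = np.quantile(reps, lo_q, axis=0, method="inverted_cdf")
        hi = np.quantile(reps, hi_q, axis=0, method="inverted_cdf")
        keep = denom > 0
        outside = (obs < lo) | (obs > hi)
        return 100.0 * float(outside[keep].mean())

    return {
        "deaths": _pct(d_reps, data.deaths, np.rint(data.exposure)),
        "one_condition": _pct(h_reps[..., 1], data.health[..., 1], data.pop),
        "two_plus_conditions": _pct(h_reps[..., 2], data.health[..., 2], data.pop),
    }


@dataclass
class PpcResult:
    """Posterior predictive check summary (chi-square p-values, 95% exceedance %)."""

    ppp_deaths: float
    ppp_health: float
    pct_outside_deaths: float
    pct_outside_one_condition: float
    pct_outside_two_plus: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def run_ppc(
    rho_draws: np.ndarray,
    pi_draws: np.ndarray,
    data: AreaAgeTable,
    rng: np.random.Generator,
) -> PpcResult:
    """All checks from stored posterior draws of the cell rates (>= 100 draws)."""
    if rho_draws.shape[0] < 100:
        raise ValueError("need >= 100 retained draws for stable predictive checks")
    ppp_d = ppp_value(rho_draws, pi_draws, data, "deaths", rng)
    ppp_h = ppp_value(rho_draws, pi_draws, data, "health", rng)
    exc = interval_exceedance(rho_draws, pi_draws, data, rng)
    return PpcResult(
        ppp_deaths=ppp_d,
        ppp_health=ppp_h,
        pct_outside_deaths=exc["deaths"],
        pct_outside_one_condition=exc["one_condition"],
        pct_outside_two_plus=exc["two_plus_conditions"],
    )
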