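"""Abridged life tables and multinomial Sullivan health expectancies.

From modelled age-specific death rates rho_x the life table uses equal-width
bands with an average fraction 0.5 of each interval survived:

    q_x   = rho_x / (1 + 0.5 rho_x)          (death probability; see below)
    l_x+1 = l_x (1 - q_x),  l_1 = 1          (survivors at band start)
    L_x   = n (l_x - 0.5 d_x), d_x = l_x q_x (person-years lived in band)
    E_x   = sum_{y >= x} L_y / l_x           (expectancy at band start)

The final open band is forced to q = 1, so the same recursion gives it
L_X = 0.5 n l_X — the equal-width / half-interval assumption applied to
every band.  Two conventions for q are available: ``literal`` (the default,
no band-width factor) and the standard abridged form ``abridged_standard``
q = n rho / (1 + 0.5 n rho).

Health expectancies weight person-years by health-state prevalence
(Sullivan's method extended to three states): HLE1 uses pi_0 (free of any
condition), HLE2 uses 1 - pi_2 (free of multiple conditions), both summed
from the current band onward and divided by l_x.  Derived indicators:

    M1 = (E - HLE2) / (HLE2 - HLE1)   expected years with multiple morbidity
                                      per expected year with one condition
    M2 = piecewise-linear proportion of the 65-75 window spent in multiple
         morbidity: 1 below 65, (75 - HLE2)/10 between, 0 at or above 75.

All quantities are computed per posterior draw and only then summarized, so
credible intervals for E, HLE, M1 and M2 are exact posterior functionals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "death_prob",
    "build_life_table",
    "sullivan_hle",
    "complex_morbidity_ratio",
    "multimorbidity_window_proportion",
    "LifeTableResult",
    "life_table_draws",
    "summarize_life_tables",
]


def death_prob(rho: np.ndarray, band_width: float = 5.0, convention: str = "literal") -> np.ndarray:
    """Per-band death probabilities q from rates rho; the final band is forced to 1.

    ``literal``: q = rho / (1 + 0.5 rho).  ``abridged_standard``:
    q = n rho / (1 + 0.5 n rho).  Values are capped at 1 (the literal formula
    can exceed 1 for rho > 2) with a warning.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("death rates must be nonnegative")
    if convention == "literal":
        q = rho / (1.0 + 0.5 * rho)
    elif convention == "abridged_standard":
        q = band_width * rho / (1.0 + 0.5 * band_width * rho)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if np.any(q > 1.0):
        logger.warning("death probabilities exceeded 1 in %d cell(s); capped", int(np.sum(q > 1.0)))
        q = np.minimum(q, 1.0)
    q = q.copy()
    q[..., -1] = 1.0
    return q


def build_life_table(q: np.ndarray, band_width: float = 5.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Survivors l, person-years L and expectancies E from death probabilities q.

    Operates on the last axis, so ``q`` may be [X] or [draws, areas, X].
    Requires q in [0, 1] with the last band equal to 1 (closed-out table).
    """
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("death probabilities must lie in [0, 1]")
    if not np.allclose(q[..., -1], 1.0):
        raise ValueError("final band must have q = 1")
    surv = np.cumprod(1.0 - q, axis=-1)
    ell = np.concatenate([np.ones(q.shape[:-1] + (1,)), surv[..., :-1]], axis=-1)
    d = ell * q
    big_l = band_width * (ell - 0.5 * d)
    rev_cum = np.cumsum(big_l[..., ::-1], axis=-1)[..., ::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(ell > 0, rev_cum / np.where(ell > 0, ell, 1.0), 0.0)
    return ell, big_l, e


def sullivan_hle(
    pi: np.ndarray, ell: np.ndarray, big_l: np.ndarray, from_band: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Health expectancies at the start of ``from_band`` (0-based).

    ``pi`` is [..., X, 3]; HLE1 weights person-years by pi_0, HLE2 by
    1 - pi_2.  The sum runs from the current band to the oldest band — the
    only reading consistent with HLE <= E.
    """
    pi = np.asarray(pi, dtype=float)
    if not np.allclose(pi.sum(axis=-1), 1.0):
        raise ValueError("health-state probabilities must sum to 1")
    lx = ell[..., from_band]
    if np.any(lx <= 0):
        raise ValueError("no survivors at the reference band")
    sl = slice(from_band, None)
    hle1 = np.sum(pi[..., sl, 0] * big_l[..., sl], axis=-1) / lx
    hle2 = np.sum((1.0 - pi[..., sl, 2]) * big_l[..., sl], axis=-1) / lx
    return hle1, hle2


def complex_morbidity_ratio(e, hle1, hle2):
    """M1 = (E - HLE2) / (HLE2 - HLE1); NaN (undefined) when HLE2 = HLE1."""
    e = np.asarray(e, dtype=float)
    hle1 = np.asarray(hle1, dtype=float)
    hle2 = np.asarray(hle2, dtype=float)
    den = hle2 - hle1
    bad = den == 0
    if np.any(bad):
        logger.warning("complex morbidity ratio undefined (HLE2 == HLE1) in %d case(s)", int(np.sum(bad)))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, (e - hle2) / np.where(bad, 1.0, den))
    return float(out) if out.ndim == 0 else out


def multimorbidity_window_proportion(hle2, window: tuple[float, float] = (65.0, 75.0)):
    """Expected proportion of the (lo, hi) age window spent in multiple morbidity.

    1 if multiple morbidity is expected before the window opens, 0 if after
    it closes, linear in between: e.g. HLE2 = 67 gives 0.8 on the 65-75
    window.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    h = np.asarray(hle2, dtype=float)
    out = np.clip((hi - h) / (hi - lo), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class LifeTableResult:
    """Per-draw, per-area life-table functionals (reference age: birth)."""

    e0: np.ndarray     # [n_draws, A]
    hle1: np.ndarray
    hle2: np.ndarray
    m1: np.ndarray
    m2: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n, a = self.e0.shape
        draw, area = np.meshgrid(np.arange(n), np.arange(a), indexing="ij")
        return pd.DataFrame(
            {
                "area_id": area.ravel(),
                "draw": draw.ravel(),
                "E0": self.e0.ravel(),
                "HLE1": self.hle1.ravel(),
                "HLE2": self.hle2.ravel(),
                "M1": self.m1.ravel(),
                "M2": self.m2.ravel(),
            }
        )


def life_table_draws(
    rho: np.ndarray,
    pi: np.ndarray,
    band_width: float = 5.0,
    convention: str = "literal",
    window: tuple[float, float] = (65.0, 75.0),
) -> LifeTableResult:
    """Life tables and health expectancies for posterior draws of cell rates.

    ``rho`` is [n_draws, A, X]; ``pi`` is [n_draws, A, X, 3].  Returns the
    headline functionals at birth for every draw and area.
    """
    rho = np.asarray(rho, dtype=float)
    pi = np.asarray(pi, dtype=float)
    q = death_prob(rho, band_width, convention)
    ell, big_l, e = build_life_table(q, band_width)
    hle1, hle2 = sullivan_hle(pi, ell, big_l, from_band=0)
    e0 = e[..., 0]
    return LifeTableResult(
        e0=e0,
        hle1=hle1,
        hle2=hle2,
        m1=complex_morbidity_ratio(e0, hle1, hle2),
        m2=multimorbidity_window_proportion(hle2, window),
    )


def summarize_life_tables(result: LifeTableResult, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean and central credible interval per area for each functional."""
    qs = [(1 - level) / 2, 1 - (1 - level) / 2]
    rows = {}
    for name in ("E0", "HLE1", "HLE2", "M1", "M2"):
        arr = getattr(result, name.lower() if name != "E0" else "e0")
        rows[f"{name}_mean"] = np.nanmean(arr, axis=0)
        lo, hi = np.nanquantile(arr, qs, axis=0)
        rows[f"{name}_lo"] = lo
        rows[f"{name}_hi"] = hi
    df = pd.DataFrame(rows)
    df.insert(0, "area_id", np.arange(df.shape[0]))
    return df
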