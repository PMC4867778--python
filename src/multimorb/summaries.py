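"""Direct age standardization, deprivation deciles, and posterior spatial summaries.

Standardized rates weight the modelled age-specific rates by the 2013
European Standard Population: R_a = sum_x w_x pi_ax2 / sum_x w_x, computed
per posterior draw (full or restricted age range; the normalized form keeps
both consistent, and rates are conventionally reported per 1000).  Areas are
ranked into ten deprivation deciles (decile 1 least deprived) and any
per-area posterior functional is aggregated per decile per draw before
summarizing, so decile credible intervals are exact.  Posterior Moran's I
applies the spatial autocorrelation statistic to each draw of an area
surface and summarizes the draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial import AdjacencyGraph, morans_i

__all__ = [
    "ESP2013_WEIGHTS_18",
    "StandardWeights",
    "standardized_rate",
    "decile_assign",
    "decile_table",
    "decile_ratio",
    "posterior_morans_i",
    "rate_deprivation_correlation",
]

#: 2013 European Standard Population aggregated to the 18 quinquennial bands
#: 0-4 ... 85+ (0 and 1-4 merged into the first band; 85-89, 90-94 and 95+
#: merged into the last).  Sums to 100000.
ESP2013_WEIGHTS_18 = np.array(
    [5000, 5500, 5500, 5500, 6000, 6000, 6500, 7000, 7000,
     7000, 7000, 6500, 6000, 5500, 5000, 4000, 2500, 2500],
    dtype=float,
)
assert ESP2013_WEIGHTS_18.sum() == 100000


@dataclass(frozen=True)
class StandardWeights:
    """Positive age-band weights for direct standardization, with provenance."""

    values: np.ndarray = field(default_factory=lambda: ESP2013_WEIGHTS_18.copy())
    provenance: str = "ESP2013 aggregated to 18 bands (0-4 ... 85+)"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values <= 0):
            raise ValueError("standard weights must be positive")


def standardized_rate(
    rates: np.ndarray,
    weights: StandardWeights | np.ndarray | None = None,
    band_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """Directly standardized rate sum_x w_x rate_x / sum_x w_x over the last axis.

    ``band_range`` is an inclusive (first, last) pair of 0-based band
    indices; None uses the full range.  Invariant to rescaling the weights.
    """
    rates = np.asarray(rates, dtype=float)
    w = np.asarray(weights.values if isinstance(weights, StandardWeights) else
                   (ESP2013_WEIGHTS_18 if weights is None else weights), dtype=float)
    x = rates.shape[-1]
    if w.shape != (x,):
        raise ValueError(f"weights must have length {x}")
    if band_range is None:
        sel = slice(None)
    else:
        lo, hi = band_range
        if not (0 <= lo <= hi < x):
            raise ValueError("empty or out-of-range band_range")
        sel = slice(lo, hi + 1)
    ws = w[sel]
    return np.sum(rates[..., sel] * ws, axis=-1) / ws.sum()


def decile_assign(scores: np.ndarray) -> np.ndarray:
    """Deprivation decile labels 1..10 per area; 1 = least deprived.

    Rank-based split into ten near-equal groups (the first ``A mod 10``
    groups take the extra area).  Ties are broken by area id, so labels are
    deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    a = scores.shape[0]
    if a < 10:
        raise ValueError("need at least 10 areas for decile assignment")
    order = np.lexsort((np.arange(a), scores))
    sizes = [a // 10 + (1 if d < a % 10 else 0) for d in range(10)]
    labels = np.empty(a, dtype=int)
    start = 0
    for d, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = d
        start += size
    return labels


def decile_table(
    draws: np.ndarray, labels: np.ndarray, level: float = 0.95
) -> pd.DataFrame:
    """Per-decile posterior mean and credible interval of an area functional.

    ``draws`` is [n_draws, A].  For each draw the functional is averaged
    (unweighted) over the decile's areas; the resulting per-decile draws are
    then summarized.
    """
    draws = np.asarray(draws, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if draws.ndim != 2 or draws.shape[1] != labels.shape[0]:
        raise ValueError("draws must be [n_draws, n_areas] matching labels")
    qs = [(1 - level) / 2, 1 - (1 - level) / 2]
    rows = []
    for d in range(1, 11):
        sel = labels == d
        if not sel.any():
            raise ValueError(f"decile {d} is empty")
        per_draw = draws[:, sel].mean(axis=1)
        lo, hi = np.nanquantile(per_draw, qs)
        rows.append({"decile": d, "mean": float(np.nanmean(per_draw)),
                     "lo": float(lo), "hi": float(hi)})
    return pd.DataFrame(rows)


def decile_ratio(values: np.ndarray | pd.Series, numerator: int = 10, denominator: int = 1) -> float:
    """Ratio of decile-level values, most over least deprived by default.

    ``values`` is indexed by decile 1..10 (a length-10 array or a Series of
    a decile table's means).
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (10,):
        raise ValueError("expected one value per decile")
    den = v[denominator - 1]
    if den == 0:
        raise ValueError("denominator decile value is zero")
    return float(v[numerator - 1] / den)


def posterior_morans_i(
    draws: np.ndarray, graph: AdjacencyGraph, level: float = 0.95, row_standardize: bool = False
) -> tuple[float, float, float]:
    """Moran's I applied per posterior draw of an area surface, then summarized.

    Returns (mean, lower, upper) of the central credible interval.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need >= 2 draws of the area surface")
    vals = np.array([morans_i(row, graph, row_standardize) for row in draws])
    lo, hi = np.quantile(vals, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(vals.mean()), float(lo), float(hi)


def rate_deprivation_correlation(rates: np.ndarray, deprivation: np.ndarray) -> float:
    """Pearson correlation between area posterior-mean rates and deprivation."""
    rates = np.asarray(rates, dtype=float)
    deprivation = np.asarray(deprivation, dtype=float)
    if rates.std() == 0 or deprivation.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(rates, deprivation)[0, 1])
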