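"""PANSS five-factor scoring, (0,1] rescaling, and score discretization.

The Positive and Negative Syndrome Scale (PANSS) has 30 items (P1-P7,
N1-N7, G1-G16), each rated 1 (absent) to 7 (extreme).  The consensus
five-factor model groups 20 of these items into positive, negative,
disorganized, excited and depressed dimensions; the factor total is the
plain item sum, so a factor with ``n`` items has attainable totals in
``[n, 7n]``.

A total ``y`` is mapped onto the open-ish unit interval by

    y_rescaled = (y - n + 1) / (7n - n + 1)

which is strictly positive at ``y = n`` and exactly 1 at ``y = 7n`` (ceiling
scores are representable but rejected by the beta likelihood, which needs
the open interval).  Conversely, a fitted continuous beta distribution is
mapped back to integer-score probabilities by slicing its CDF at bin edges
placed midway between consecutive rescaled scores, with the outer edges
pinned at exactly 0 and 1 so the masses telescope to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import family

__all__ = [
    "FactorDefinition",
    "FACTORS",
    "FACTOR_NAMES",
    "get_factor",
    "factor_total",
    "factor_totals",
    "rescale",
    "unrescale",
    "score_bin_edges",
    "discretize_pmf",
    "discrete_cdf_interval",
]


@dataclass(frozen=True)
class FactorDefinition:
    """A named PANSS factor: its item codes and attainable score range."""

    name: str
    items: tuple[str, ...]

    def __post_init__(self):
        if len(self.items) == 0:
            raise ValueError("a factor needs at least one item")
        if len(set(self.items)) != len(self.items):
            raise ValueError(f"duplicate items in factor {self.name!r}")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def min_total(self) -> int:
        return self.n_items

    @property
    def max_total(self) -> int:
        return 7 * self.n_items

    @property
    def levels(self) -> np.ndarray:
        """All attainable integer totals, ``n .. 7n``."""
        return np.arange(self.min_total, self.max_total + 1)


POSITIVE = FactorDefinition("positive", ("P1", "P3", "P5", "G9"))
NEGATIVE = FactorDefinition("negative", ("N1", "N2", "N3", "N4", "N6", "G7"))
DISORGANIZED = FactorDefinition("disorganized", ("P2", "N5", "G11"))
EXCITED = FactorDefinition("excited", ("P4", "P7", "G8", "G14"))
DEPRESSED = FactorDefinition("depressed", ("G2", "G3", "G6"))

FACTORS: dict[str, FactorDefinition] = {
    f.name: f for f in (POSITIVE, NEGATIVE, DISORGANIZED, EXCITED, DEPRESSED)
}
FACTOR_NAMES = tuple(FACTORS)


def get_factor(factor: str | FactorDefinition) -> FactorDefinition:
    if isinstance(factor, FactorDefinition):
        return factor
    try:
        return FACTORS[factor]
    except KeyError:
        raise KeyError(
            f"unknown factor {factor!r}; expected one of {sorted(FACTORS)}"
        ) from None


def _check_item_scores(scores: np.ndarray, item: str):
    arr = np.asarray(scores, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"missing or non-finite score for item {item!r}")
    if np.any(arr != np.round(arr)) or np.any(arr < 1) or np.any(arr > 7):
        raise ValueError(f"item {item!r} scores must be integers in [1, 7]")


def factor_total(item_scores, factor: str | FactorDefinition) -> int:
    """Sum one admission's item scores over a factor's items.

    ``item_scores`` maps item code -> integer rating in [1, 7]; every item of
    the factor must be present.
    """
    fac = get_factor(factor)
    total = 0
    for item in fac.items:
        if item not in item_scores:
            raise ValueError(f"missing score for item {item!r} of factor {fac.name!r}")
        _check_item_scores(np.asarray(item_scores[item]), item)
        total += int(item_scores[item])
    return total


def factor_totals(items: pd.DataFrame, factor: str | FactorDefinition) -> np.ndarray:
    """Vectorized :func:`factor_total` over a raw-item table (one row per admission)."""
    fac = get_factor(factor)
    cols = []
    for item in fac.items:
        if item not in items.columns:
            raise ValueError(f"missing column for item {item!r} of factor {fac.name!r}")
        _check_item_scores(items[item].to_numpy(), item)
        cols.append(items[item].to_numpy(dtype=int))
    return np.sum(cols, axis=0)


def _check_totals(y, fac: FactorDefinition):
    arr = np.asarray(y, dtype=float)
    if np.any(arr != np.round(arr)) or np.any(arr < fac.min_total) or np.any(arr > fac.max_total):
        raise ValueError(
            f"totals for factor {fac.name!r} must be integers in "
            f"[{fac.min_total}, {fac.max_total}]"
        )
    return arr


def rescale(y, factor: str | FactorDefinition):
    """Rescale integer totals to (0, 1]: ``(y - n + 1) / (6n + 1)``."""
    fac = get_factor(factor)
    arr = _check_totals(y, fac)
    n = fac.n_items
    out = (arr - n + 1.0) / (6 * n + 1.0)
    return float(out) if np.isscalar(y) else out


def unrescale(r, factor: str | FactorDefinition):
    """Map a value in (0, 1] back to the nearest attainable total (ties go down)."""
    fac = get_factor(factor)
    arr = np.asarray(r, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValueError("rescaled values must lie in (0, 1]")
    n = fac.n_items
    y_star = arr * (6 * n + 1.0) + n - 1.0
    lo = np.clip(np.floor(y_star), fac.min_total, fac.max_total)
    hi = np.clip(np.ceil(y_star), fac.min_total, fac.max_total)
    d_lo = np.abs(arr - (lo - n + 1.0) / (6 * n + 1.0))
    d_hi = np.abs((hi - n + 1.0) / (6 * n + 1.0) - arr)
    out = np.where(d_lo <= d_hi, lo, hi).astype(int)
    return int(out) if np.isscalar(r) else out


def score_bin_edges(factor: str | FactorDefinition) -> np.ndarray:
    """CDF slice points for the attainable totals: length ``6n + 2``.

    Interior edges sit midway between consecutive rescaled scores; the outer
    edges are exactly 0 and 1, so CDF differences telescope to a proper pmf.
    """
    fac = get_factor(factor)
    n = fac.n_items
    n_levels = 6 * n + 1
    edges = (np.arange(n_levels + 1) + 0.5) / (6 * n + 1.0)
    edges[0] = 0.0
    edges[-1] = 1.0
    return edges


def discretize_pmf(mu, sigma, factor: str | FactorDefinition):
    """Probability mass over attainable totals implied by a fitted beta.

    ``P(Y = y) = F(u(y)) - F(l(y))`` with F the beta CDF and the bin edges of
    :func:`score_bin_edges`.  Scalar (mu, sigma) give a 1-d pmf over the
    factor's levels; vectors give one pmf per row.
    """
    fac = get_factor(factor)
    edges = score_bin_edges(fac)
    mu_arr = np.asarray(mu, dtype=float)
    sigma_arr = np.asarray(sigma, dtype=float)
    scalar = mu_arr.ndim == 0 and sigma_arr.ndim == 0
    mu_arr, sigma_arr = np.broadcast_arrays(np.atleast_1d(mu_arr), np.atleast_1d(sigma_arr))
    cdf_at_edges = family.cdf(
        edges[np.newaxis, :], mu_arr[:, np.newaxis], sigma_arr[:, np.newaxis]
    )
    pmf = np.diff(cdf_at_edges, axis=1)
    return pmf[0] if scalar else pmf


def discrete_cdf_interval(y, mu, sigma, factor: str | FactorDefinition):
    """Discretized-CDF interval ``(P(Y <= y-1), P(Y <= y))`` per observation.

    This is the jump of the discrete predictive CDF at the observed total,
    the ingredient of the non-randomized probability integral transform.
    """
    fac = get_factor(factor)
    arr = _check_totals(y, fac)
    edges = score_bin_edges(fac)
    idx = (arr - fac.min_total).astype(int)
    f_lo = family.cdf(edges[idx], mu, sigma)
    f_hi = family.cdf(edges[idx + 1], mu, sigma)
    return f_lo, f_hi
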