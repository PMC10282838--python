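"""Model interpretation: selection frequencies and partial dependence.

Because the outer loop of the nested cross-validation refits the model on
heavily overlapping training sets, the set of selected predictors is
summarized as a *variable selection frequency*: the fraction of refitted
models in which any base learner of a variable updated a given additive
predictor at least once.  Marginal effects are summarized by Friedman
partial dependence — set the variable to a grid value in every training
row, predict, and average — either on the distribution-parameter scale
(mu or sigma) or, after discretization, as a probability mass over the
attainable integer scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boosting import BetaBoostResults, SelectionRecord
from .design import ALL_VARS, BINARY_VARS
from .scale import FactorDefinition, get_factor, discretize_pmf

__all__ = [
    "selection_frequency",
    "PartialDependenceCurve",
    "default_grid",
    "partial_dependence_param",
    "partial_dependence_scores",
    "plot_curve",
]


def _history_of(model) -> list[SelectionRecord]:
    if isinstance(model, BetaBoostResults):
        return model.history
    return list(model)


def selection_frequency(models) -> pd.DataFrame:
    """Fraction of fitted models selecting each (variable, parameter) pair.

    ``models`` is a non-empty list of :class:`BetaBoostResults` (or raw
    selection histories).  Returns a DataFrame indexed by variable with
    ``mu`` and ``sigma`` columns of proportions in [0, 1].
    """
    models = list(models)
    if not models:
        raise ValueError("need at least one fitted model")
    counts = pd.DataFrame(0.0, index=list(ALL_VARS), columns=["mu", "sigma"])
    for m in models:
        chosen = {(r.variable, r.parameter) for r in _history_of(m)}
        for var, param in chosen:
            if var in counts.index:
                counts.loc[var, param] += 1.0
    return counts / len(models)


@dataclass
class PartialDependenceCurve:
    """Averaged prediction as a function of one covariate.

    ``values`` holds the averaged parameter (mu or sigma) per grid point;
    for the score-probability variant, ``score_pmf`` is a (grid x score)
    matrix whose rows each sum to 1 over ``scores``.
    """

    variable: str
    grid: np.ndarray
    parameter: str | None = None
    values: np.ndarray | None = None
    scores: np.ndarray | None = None
    score_pmf: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        if self.score_pmf is None:
            return pd.DataFrame(
                {
                    "variable": self.variable,
                    "grid": self.grid,
                    "parameter": self.parameter,
                    "value": self.values,
                }
            )
        g, s = np.meshgrid(self.grid, self.scores, indexing="ij")
        return pd.DataFrame(
            {
                "variable": self.variable,
                "grid": g.ravel(),
                "score": s.ravel().astype(int),
                "probability": self.score_pmf.ravel(),
            }
        )


def default_grid(data: pd.DataFrame, variable: str, n: int = 50) -> np.ndarray:
    """Binary variables get {0, 1}; numerics 50 points between the 1st and 99th percentile."""
    if variable not in ALL_VARS:
        raise ValueError(f"unknown variable {variable!r}")
    if variable in BINARY_VARS:
        return np.array([0.0, 1.0])
    col = data[variable].to_numpy(dtype=float)
    lo, hi = np.percentile(col, [1, 99])
    return np.linspace(lo, hi, n)


def partial_dependence_param(
    results: BetaBoostResults,
    variable: str,
    data: pd.DataFrame,
    parameter: str = "mu",
    grid: np.ndarray | None = None,
) -> PartialDependenceCurve:
    """Marginal effect of one variable on a predicted distribution parameter."""
    if parameter not in ("mu", "sigma"):
        raise ValueError("parameter must be 'mu' or 'sigma'")
    if variable not in ALL_VARS:
        raise ValueError(f"unknown variable {variable!r}")
    grid = default_grid(data, variable) if grid is None else np.asarray(grid, dtype=float)
    values = np.empty(grid.size)
    work = data.copy()
    for i, g in enumerate(grid):
        work[variable] = g
        values[i] = float(results.predict(work)[parameter].mean())
    return PartialDependenceCurve(
        variable=variable, grid=grid, parameter=parameter, values=values
    )


def partial_dependence_scores(
    results: BetaBoostResults,
    variable: str,
    data: pd.DataFrame,
    factor: str | FactorDefinition,
    grid: np.ndarray | None = None,
) -> PartialDependenceCurve:
    """Marginal effect of one variable on the probability of each integer score."""
    fac = get_factor(factor)
    if variable not in ALL_VARS:
        raise ValueError(f"unknown variable {variable!r}")
    grid = default_grid(data, variable) if grid is None else np.asarray(grid, dtype=float)
    pmf = np.empty((grid.size, fac.levels.size))
    work = data.copy()
    for i, g in enumerate(grid):
        work[variable] = g
        pred = results.predict(work)
        pmf[i] = discretize_pmf(
            pred["mu"].to_numpy(), pred["sigma"].to_numpy(), fac
        ).mean(axis=0)
    return PartialDependenceCurve(
        variable=variable, grid=grid, scores=fac.levels, score_pmf=pmf
    )


def plot_curve(curve: PartialDependenceCurve, ax=None, **kwargs):
    """Plot a partial-dependence curve (parameter scale) or heatmap (score scale)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if curve.score_pmf is None:
        ax.plot(curve.grid, curve.values, **kwargs)
        ax.set_ylabel(curve.parameter)
    else:
        mesh = ax.pcolormesh(curve.grid, curve.scores, curve.score_pmf.T, **kwargs)
        ax.figure.colorbar(mesh, ax=ax, label="probability")
        ax.set_ylabel("total score")
    ax.set_xlabel(curve.variable)
    return ax
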