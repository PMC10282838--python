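"""Internal validation: mstop selection, nested CV, metrics, PIT, loess.

The tuning parameter ``mstop`` is chosen by k-fold cross-validation of the
held-out predictive risk (mean per-observation negative log-likelihood)
along the boosting path.  Internal validation nests that choice inside a
repeated outer cross-validation: for every (repeat, outer fold) the model is
tuned on the outer-training part, refitted at the tuned ``mstop``, and
scored on both parts.  Train-minus-test differences in pseudo R^2 (and
test-minus-train in RMSE) estimate the optimism of the apparent fit.

Probabilistic calibration is assessed with non-randomized probability
integral transform (PIT) histograms for the discretized predictive
distributions: each observation spreads unit mass uniformly over the jump
``[P(Y <= y-1), P(Y <= y)]`` of its discrete predictive CDF; under a
calibrated model the aggregated histogram is uniform, and depleted top bins
signal over-forecasting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit

from . import family
from .boosting import BetaBoostLSS, MAX_MSTOP
from .scale import FactorDefinition, get_factor, discrete_cdf_interval, rescale

__all__ = [
    "make_folds",
    "pseudo_r2",
    "rmse_logit",
    "select_mstop",
    "nested_cv",
    "NestedCVResult",
    "PITHistogram",
    "pit_histogram_from_intervals",
    "pit_histogram",
    "loess_smooth",
]

logger = logging.getLogger(__name__)


def make_folds(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold labels 0..k-1 partitioning ``n`` rows with sizes differing by <= 1."""
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n folds")
    return rng.permutation(np.arange(n) % k)


def pseudo_r2(y_rescaled, eta_mu_hat) -> float:
    """Squared Pearson correlation between logit(y) and the fitted eta_mu."""
    y = np.asarray(y_rescaled, dtype=float)
    eta = np.asarray(eta_mu_hat, dtype=float)
    if y.size < 3:
        raise ValueError("pseudo R^2 needs at least 3 observations")
    ly = logit(y)
    if np.std(ly) == 0.0 or np.std(eta) == 0.0:
        logger.warning("constant vector in pseudo R^2; returning 0")
        return 0.0
    r = np.corrcoef(ly, eta)[0, 1]
    return float(r * r)


def rmse_logit(y_rescaled, eta_mu_hat) -> float:
    """Root mean squared error on the rescaled-and-logit-transformed outcome scale."""
    y = np.asarray(y_rescaled, dtype=float)
    eta = np.asarray(eta_mu_hat, dtype=float)
    return float(np.sqrt(np.mean((logit(y) - eta) ** 2)))


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def select_mstop(
    df: pd.DataFrame,
    factor: str | FactorDefinition,
    grid=None,
    k: int = 10,
    seed: int = 0,
    mstop_max: int = MAX_MSTOP,
    step_length: float = 0.1,
    return_path: bool = False,
):
    """Cross-validated number of boosting iterations.

    For each fold the model is fitted on the remaining folds up to
    ``max(grid)`` while the held-out mean negative log-likelihood is
    recorded along the whole path; the returned value is the grid point
    minimizing the fold-average (ties go to the smallest ``mstop``).
    By default the grid is every integer ``1..mstop_max``.
    """
    fac = get_factor(factor)
    grid = np.arange(1, mstop_max + 1) if grid is None else np.asarray(grid, dtype=int)
    if grid.size == 0 or grid.min() < 1 or grid.max() > MAX_MSTOP:
        raise ValueError(f"grid must be a non-empty subset of [1, {MAX_MSTOP}]")
    grid = np.sort(grid)
    m_max = int(grid.max())
    rng = np.random.default_rng(seed)
    folds = make_folds(len(df), k, rng)
    paths = []
    for fold in range(k):
        train = df.iloc[folds != fold]
        test = df.iloc[folds == fold]
        y_test = rescale(test[f"{fac.name}_dis"].to_numpy(), fac)
        if np.all(train[f"{fac.name}_dis"].to_numpy() == train[f"{fac.name}_dis"].iloc[0]):
            logger.warning("constant outcome in a CV training fold; fold retained")
        model = BetaBoostLSS.from_cohort(train, fac, step_length=step_length)
        res = model.fit(m_max, test_sets=[(test, y_test)])
        paths.append(res.test_nll_paths_[0])
    avg = np.mean(paths, axis=0)
    risk_at_grid = avg[grid - 1]
    best = int(grid[int(np.argmin(risk_at_grid))])
    if return_path:
        return best, pd.DataFrame({"mstop": grid, "cv_risk": risk_at_grid})
    return best


@dataclass(frozen=True)
class PITHistogram:
    """Aggregated non-randomized PIT masses over equal bins on [0, 1]."""

    edges: np.ndarray
    masses: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lower": self.edges[:-1], "upper": self.edges[1:], "mass": self.masses}
        )


def pit_histogram_from_intervals(f_lo, f_hi, bins: int = 10) -> PITHistogram:
    """Aggregate per-observation CDF jumps into a PIT histogram.

    Each observation spreads unit mass uniformly over ``[F_lo, F_hi]``; the
    histogram records the mean mass per bin (masses sum to 1).
    """
    f_lo = np.atleast_1d(np.asarray(f_lo, dtype=float))
    f_hi = np.atleast_1d(np.asarray(f_hi, dtype=float))
    if f_lo.size == 0:
        raise ValueError("no observations")
    edges = np.linspace(0.0, 1.0, bins + 1)
    width = f_hi - f_lo
    masses = np.zeros(bins)
    degenerate = width <= 1e-14
    if np.any(degenerate):
        idx = np.minimum((f_lo[degenerate] * bins).astype(int), bins - 1)
        np.add.at(masses, idx, 1.0)
    ok = ~degenerate
    if np.any(ok):
        lo = f_lo[ok][:, None]
        hi = f_hi[ok][:, None]
        overlap = np.clip(
            np.minimum(hi, edges[None, 1:]) - np.maximum(lo, edges[None, :-1]), 0.0, None
        )
        masses += (overlap / (hi - lo)).sum(axis=0)
    masses /= f_lo.size
    return PITHistogram(edges=edges, masses=masses)


def pit_histogram(
    predictions: pd.DataFrame,
    observed_scores,
    factor: str | FactorDefinition,
    bins: int = 10,
) -> PITHistogram:
    """PIT histogram for discretized beta predictions of integer totals.

    ``predictions`` must carry per-row ``mu`` and ``sigma`` columns (as
    returned by ``BetaBoostResults.predict``).
    """
    fac = get_factor(factor)
    f_lo, f_hi = discrete_cdf_interval(
        np.asarray(observed_scores),
        predictions["mu"].to_numpy(),
        predictions["sigma"].to_numpy(),
        fac,
    )
    return pit_histogram_from_intervals(f_lo, f_hi, bins=bins)


@dataclass
class NestedCVResult:
    """Everything the outer loop produced, plus summaries.

    ``records`` has one row per (repeat, fold) with the tuned mstop and the
    train/test pseudo R^2 and RMSE; ``selection`` flags which variable
    updated which additive predictor in each refit; the pooled test-set PIT
    intervals live in ``pit_lo``/``pit_hi``.
    """

    factor: str
    records: pd.DataFrame
    selection: pd.DataFrame
    pit_lo: np.ndarray
    pit_hi: np.ndarray
    seed: int
    n_failed: int = 0
    test_eta_mu: np.ndarray = field(default_factory=lambda: np.empty(0))
    test_true_mu: np.ndarray = field(default_factory=lambda: np.empty(0))
    test_mu: np.ndarray = field(default_factory=lambda: np.empty(0))

    def optimism(self) -> pd.Series:
        """Mean optimism: train - test for pseudo R^2, test - train for RMSE."""
        rec = self.records
        return pd.Series(
            {
                "pseudo_r2_train": rec["r2_train"].mean(),
                "pseudo_r2_test": rec["r2_test"].mean(),
                "optimism_pseudo_r2": (rec["r2_train"] - rec["r2_test"]).mean(),
                "rmse_train": rec["rmse_train"].mean(),
                "rmse_test": rec["rmse_test"].mean(),
                "optimism_rmse": (rec["rmse_test"] - rec["rmse_train"]).mean(),
            }
        )

    def pit_histogram(self, bins: int = 10) -> PITHistogram:
        return pit_histogram_from_intervals(self.pit_lo, self.pit_hi, bins=bins)

    def selection_frequency(self) -> pd.DataFrame:
        """Per (variable, parameter): fraction of refits selecting it at least once."""
        n_models = len(self.records)
        freq = (
            self.selection.groupby(["variable", "parameter"])["selected"]
            .sum()
            .unstack(fill_value=0)
            / n_models
        )
        return freq

    def summary(self) -> str:
        opt = self.optimism()
        lines = [
            f"Nested cross-validation, factor={self.factor!r}",
            f"fits: {len(self.records)} (failed: {self.n_failed})",
            f"mean mstop: {self.records['mstop'].mean():.1f}",
            f"pseudo R^2  train {opt['pseudo_r2_train']:.3f}  test {opt['pseudo_r2_test']:.3f}"
            f"  optimism {opt['optimism_pseudo_r2']:+.3f}",
            f"RMSE        train {opt['rmse_train']:.3f}  test {opt['rmse_test']:.3f}"
            f"  optimism {opt['optimism_rmse']:+.3f}",
        ]
        return "\n".join(lines)


def nested_cv(
    df: pd.DataFrame,
    factor: str | FactorDefinition,
    repeats: int = 100,
    k: int = 10,
    inner_k: int = 10,
    grid=None,
    mstop_max: int = MAX_MSTOP,
    seed: int = 0,
    step_length: float = 0.1,
    truth: pd.DataFrame | None = None,
) -> NestedCVResult:
    """Repeated nested cross-validation of the full fitting procedure.

    Every (repeat, outer fold) tunes ``mstop`` on the outer-training part by
    inner ``inner_k``-fold CV (re-randomized per outer fold from the master
    seed), refits at the tuned value, and records train/test metrics,
    per-variable selection flags, and the test-set PIT intervals.  If a
    synthetic ``truth`` table with a ``true_mu_<factor>`` column is passed,
    the true and predicted test-set means are pooled too (for parameter
    recovery checks).
    """
    fac = get_factor(factor)
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    master = np.random.SeedSequence(seed)
    rec_rows, sel_rows = [], []
    pit_lo, pit_hi = [], []
    test_eta_mu, test_true_mu, test_mu = [], [], []
    n_failed = 0
    from .design import ALL_VARS  # local import to avoid cycle at module load

    for rep, rep_ss in enumerate(master.spawn(repeats)):
        fold_ss, *fold_children = rep_ss.spawn(k + 1)
        rng = np.random.default_rng(fold_ss)
        folds = make_folds(len(df), k, rng)
        for fold in range(k):
            train = df.iloc[folds != fold]
            test = df.iloc[folds == fold]
            try:
                mstop = select_mstop(
                    train,
                    fac,
                    grid=grid,
                    k=inner_k,
                    seed=_child_seed(fold_children[fold]),
                    mstop_max=mstop_max,
                    step_length=step_length,
                )
                model = BetaBoostLSS.from_cohort(train, fac, step_length=step_length)
                res = model.fit(mstop)
            except (ValueError, FloatingPointError) as exc:
                logger.warning("fold (%d, %d) failed: %s", rep, fold, exc)
                n_failed += 1
                continue
            y_train = model.y
            y_test = rescale(test[f"{fac.name}_dis"].to_numpy(), fac)
            eta_test = res.eta(test)
            pred_test = res.predict(test)
            rec_rows.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "mstop": mstop,
                    "n_train": len(train),
                    "n_test": len(test),
                    "r2_train": pseudo_r2(y_train, res.eta_mu_),
                    "r2_test": pseudo_r2(y_test, eta_test["eta_mu"]),
                    "rmse_train": rmse_logit(y_train, res.eta_mu_),
                    "rmse_test": rmse_logit(y_test, eta_test["eta_mu"]),
                }
            )
            chosen = {(r.variable, r.parameter) for r in res.history}
            for var in ALL_VARS:
                for param in ("mu", "sigma"):
                    sel_rows.append(
                        {
                            "repeat": rep,
                            "fold": fold,
                            "variable": var,
                            "parameter": param,
                            "selected": (var, param) in chosen,
                        }
                    )
            lo, hi = discrete_cdf_interval(
                test[f"{fac.name}_dis"].to_numpy(),
                pred_test["mu"].to_numpy(),
                pred_test["sigma"].to_numpy(),
                fac,
            )
            pit_lo.append(lo)
            pit_hi.append(hi)
            test_eta_mu.append(eta_test["eta_mu"].to_numpy())
            test_mu.append(pred_test["mu"].to_numpy())
            if truth is not None:
                test_true_mu.append(
                    truth.iloc[folds == fold][f"true_mu_{fac.name}"].to_numpy()
                )

    return NestedCVResult(
        factor=fac.name,
        records=pd.DataFrame(rec_rows),
        selection=pd.DataFrame(sel_rows),
        pit_lo=np.concatenate(pit_lo) if pit_lo else np.empty(0),
        pit_hi=np.concatenate(pit_hi) if pit_hi else np.empty(0),
        seed=seed,
        n_failed=n_failed,
        test_eta_mu=np.concatenate(test_eta_mu) if test_eta_mu else np.empty(0),
        test_true_mu=np.concatenate(test_true_mu) if test_true_mu else np.empty(0),
        test_mu=np.concatenate(test_mu) if test_mu else np.empty(0),
    )


def loess_smooth(x, y, span: float = 0.75, degree: int = 2, n_grid: int = 100):
    """Locally weighted least-squares smoother on an equally spaced grid.

    Tricube-weighted local polynomial (quadratic by default) regression
    evaluated at ``n_grid`` points over the range of ``x``.  Returns
    ``(grid, fitted)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("loess needs at least 10 observations")
    q = int(np.ceil(span * n))
    if q < degree + 2:
        raise ValueError("span too small for a local polynomial fit")
    grid = np.linspace(x.min(), x.max(), n_grid)
    fitted = np.empty(n_grid)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        dq = np.partition(d, q - 1)[q - 1]
        if dq <= 0.0:
            w = (d == 0).astype(float)
        else:
            w = np.clip(1.0 - (d / dq) ** 3, 0.0, None) ** 3
        sw = np.sqrt(w)
        xc = x - x0
        B = np.column_stack([xc**p for p in range(degree + 1)])
        coef, *_ = np.linalg.lstsq(B * sw[:, None], y * sw, rcond=None)
        fitted[i] = coef[0]
    return grid, fitted
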