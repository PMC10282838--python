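"""Covariate encoding and equal-complexity base learners.

The candidate predictors are 17 admission variables: nine binaries (sex,
diagnosis, prior clozapine trial, current clozapine, antipsychotic
polypharmacy, antidepressant, mood stabilizer, benzodiazepine,
anticholinergic) and eight numerics (year of admission, age, total
antipsychotic utilization PDD:DDD, and the five admission factor totals).
Binaries are 0/1 dummies; numerics are mean-centered with the training
constants stored so new data are centered identically.

Every candidate variable gets a linear base learner, every numeric variable
additionally a P-spline base learner, and every base learner is calibrated
to one effective degree of freedom (trace of its smoother matrix) so the
boosting algorithm has no built-in preference for flexible components.

P-splines use the centered reparameterization: the penalty null space
(constant and linear trends, which are already carried by the model offset
and the linear base learner) is removed by an eigendecomposition of the
second-order difference penalty, and the remaining directions carry a ridge
penalty.  In this basis the effective degrees of freedom can be driven all
the way to zero, so a df-1 calibration always has a solution.
"""

from __future__ import annotations

import abc
import logging

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "BINARY_VARS",
    "NUMERIC_VARS",
    "ALL_VARS",
    "EncodedDesign",
    "BaseLearner",
    "LinearBaseLearner",
    "InterceptBaseLearner",
    "PSplineBaseLearner",
    "build_baselearners",
]

BINARY_VARS = (
    "sex_male",
    "schizoaffective",
    "prior_clozapine",
    "clozapine",
    "polypharmacy",
    "antidepressant",
    "mood_stabilizer",
    "benzodiazepine",
    "anticholinergic",
)
NUMERIC_VARS = (
    "year",
    "age",
    "pdd_ddd",
    "positive_adm",
    "negative_adm",
    "disorganized_adm",
    "excited_adm",
    "depressed_adm",
)
ALL_VARS = BINARY_VARS + NUMERIC_VARS


class EncodedDesign:
    """Encoded covariate matrix plus the metadata to re-apply the encoding.

    Columns follow ``ALL_VARS`` order: binaries as 0/1 dummies (not
    centered), numerics mean-centered with the constants recorded here.
    """

    def __init__(self, matrix: np.ndarray, centers: dict[str, float]):
        self.matrix = matrix
        self.centers = centers
        self.columns = ALL_VARS
        self.kinds = {v: ("binary" if v in BINARY_VARS else "numeric") for v in ALL_VARS}

    @classmethod
    def from_cohort(cls, df: pd.DataFrame) -> "EncodedDesign":
        centers = {
            v: float(np.mean(cls._raw_column(df, v))) for v in NUMERIC_VARS
        }
        design = cls.__new__(cls)
        design.centers = centers
        design.columns = ALL_VARS
        design.kinds = {
            v: ("binary" if v in BINARY_VARS else "numeric") for v in ALL_VARS
        }
        design.matrix = design.transform(df)
        return design

    @staticmethod
    def _raw_column(df: pd.DataFrame, var: str) -> np.ndarray:
        if var not in df.columns:
            raise ValueError(f"missing covariate column {var!r}")
        col = df[var].to_numpy(dtype=float)
        if np.any(~np.isfinite(col)):
            raise ValueError(
                f"missing values in column {var!r}; apply listwise deletion first"
            )
        if var in BINARY_VARS and not np.isin(col, (0.0, 1.0)).all():
            raise ValueError(f"binary column {var!r} contains levels outside {{0, 1}}")
        return col

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        """Encode new rows with the training centering constants."""
        cols = []
        for var in ALL_VARS:
            col = self._raw_column(df, var)
            if var in NUMERIC_VARS:
                col = col - self.centers[var]
            cols.append(col)
        return np.column_stack(cols)

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]

    def index(self, var: str) -> int:
        return ALL_VARS.index(var)

    def column(self, var: str) -> np.ndarray:
        return self.matrix[:, self.index(var)]


def _solve_df(eigvals: np.ndarray, df: float, log10_bounds=(-12.0, 12.0)) -> float:
    """Find lambda with ``sum(d / (d + lambda)) = df`` by bisection on log10-lambda."""
    d = eigvals[eigvals > 1e-12]

    def trace(lam: float) -> float:
        return float(np.sum(d / (d + lam)))

    lo, hi = log10_bounds
    # widen the bracket if the target is not straddled
    while trace(10.0**lo) < df and lo > -30:
        lo -= 2.0
    while trace(10.0**hi) > df and hi < 30:
        hi += 2.0
    if not (trace(10.0**lo) >= df >= trace(10.0**hi)):
        raise RuntimeError(
            f"df={df} not attainable: trace range "
            f"[{trace(10.0**hi):.3g}, {trace(10.0**lo):.3g}]"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if trace(10.0**mid) > df:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-13:
            break
    lam = 10.0 ** (0.5 * (lo + hi))
    if abs(trace(lam) - df) > 1e-8:
        raise RuntimeError(f"df calibration failed: trace={trace(lam)!r} target={df}")
    return lam


class BaseLearner(abc.ABC):
    """A penalized least-squares component bound to one training covariate.

    ``fit`` solves the penalized normal equations at the lambda fixed during
    construction; ``design_matrix`` evaluates the basis on new (encoded)
    covariate values so accumulated coefficients can be applied to new data.
    """

    name: str
    kind: str
    df: float

    @abc.abstractmethod
    def design_matrix(self, x: np.ndarray) -> np.ndarray: ...

    @abc.abstractmethod
    def trace(self) -> float:
        """Effective degrees of freedom: trace of the smoother matrix."""

    def fit(self, z: np.ndarray):
        """Penalized LS fit to a working response ``z``.

        Returns ``(coef, fitted, sse)``.
        """
        coef = self._solver @ z
        fitted = self.design_ @ coef
        resid = z - fitted
        return coef, fitted, float(resid @ resid)


class LinearBaseLearner(BaseLearner):
    """A single-column linear component (optionally with intercept).

    Without intercept (the default used in the candidate set) the smoother
    is the rank-1 projection onto the column, whose trace is exactly 1 with
    no penalty.  With ``intercept=True`` both columns carry a ridge penalty
    calibrated so the smoother trace equals ``df``.
    """

    kind = "linear"

    def __init__(self, x: np.ndarray, name: str, intercept: bool = False, df: float = 1.0):
        x = np.asarray(x, dtype=float)
        if float(x @ x) <= 0.0:
            raise ValueError(f"covariate {name!r} is identically zero; cannot build learner")
        self.name = name
        self.df = df
        self.intercept = intercept
        if intercept:
            B = np.column_stack([np.ones_like(x), x])
            gram = B.T @ B
            eigvals = np.linalg.eigvalsh(gram)
            self.lambda_ = _solve_df(eigvals, df)
            self._solver = np.linalg.solve(gram + self.lambda_ * np.eye(2), B.T)
        else:
            if df != 1.0:
                raise ValueError("an intercept-free single column has df fixed at 1")
            B = x[:, np.newaxis]
            self.lambda_ = 0.0
            self._solver = B.T / float(x @ x)
        self.design_ = B

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.intercept:
            return np.column_stack([np.ones_like(x), x])
        return x[:, np.newaxis]

    def trace(self) -> float:
        return float(np.trace(self.design_ @ self._solver))


class InterceptBaseLearner(BaseLearner):
    """A constant (intercept-only) component.

    The unpenalized projection onto the constant column has trace exactly 1,
    so it competes on equal footing with the covariate learners.  Its job is
    offset adaptation: the global model offsets are never refit, but the
    level of each additive predictor that best fits the data drifts as the
    other components accumulate (most visibly for the scale parameter, whose
    intercept-only estimate shrinks as the location model explains outcome
    variance).  Without this component the drift is absorbed by whichever
    covariate happens to fit it best, which misattributes global adjustments
    to individual variables.
    """

    kind = "intercept"
    name = "(intercept)"

    def __init__(self, n: int, df: float = 1.0):
        if df != 1.0:
            raise ValueError("the intercept learner has df fixed at 1")
        self.df = df
        self.lambda_ = 0.0
        self.design_ = np.ones((n, 1))
        self._solver = np.full((1, n), 1.0 / n)

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        return np.ones((np.asarray(x).shape[0], 1))

    def trace(self) -> float:
        return 1.0


class PSplineBaseLearner(BaseLearner):
    """Centered cubic P-spline with a second-order difference penalty.

    Twenty knots are equally spaced over the observed range.  The penalty
    null space (constant + linear) is removed, the remainder is
    ridge-penalized, and lambda is calibrated so trace(S) = ``df``.  Values
    outside the training range are evaluated by linear extension of the
    boundary basis, which keeps partial-dependence grids and held-out folds
    from extrapolating wildly.
    """

    kind = "pspline"

    def __init__(
        self,
        x: np.ndarray,
        name: str,
        n_knots: int = 20,
        degree: int = 3,
        diff_order: int = 2,
        df: float = 1.0,
    ):
        x = np.asarray(x, dtype=float)
        self.name = name
        self.df = df
        self.xmin = float(np.min(x))
        self.xmax = float(np.max(x))
        if self.xmax - self.xmin < 1e-12:
            raise ValueError(f"covariate {name!r} is constant; cannot place spline knots")
        h = (self.xmax - self.xmin) / (n_knots - 1)
        knots = self.xmin + h * np.arange(-degree, n_knots + degree)
        n_basis = len(knots) - degree - 1
        self._spline = BSpline(knots, np.eye(n_basis), degree, extrapolate=True)
        self._dspline = self._spline.derivative()

        D = np.diff(np.eye(n_basis), diff_order, axis=0)
        penalty = D.T @ D
        w, U = np.linalg.eigh(penalty)
        # null space of the difference penalty = polynomials of degree < diff_order
        self._transform = U[:, diff_order:] / np.sqrt(w[diff_order:])

        B = self.design_matrix(x)
        d, V = np.linalg.eigh(B.T @ B)
        self.lambda_ = _solve_df(d, df)
        self._eigvals = d
        self._solver = (V * (1.0 / (d + self.lambda_))) @ V.T @ B.T
        self.design_ = B

    def _raw_basis(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, self.xmin, self.xmax)
        B = self._spline(xc)
        below = x < self.xmin
        above = x > self.xmax
        if np.any(below):
            B[below] += np.outer(x[below] - self.xmin, self._dspline(self.xmin))
        if np.any(above):
            B[above] += np.outer(x[above] - self.xmax, self._dspline(self.xmax))
        return B

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        return self._raw_basis(x) @ self._transform

    def trace(self) -> float:
        d = self._eigvals
        return float(np.sum(d / (d + self.lambda_)))


def build_baselearners(
    design: EncodedDesign, n_knots: int = 20, df: float = 1.0
) -> list[BaseLearner]:
    """The candidate set: 17 linear learners + 8 P-splines, each with df = 1.

    Covariate learners are intercept-free (the model offset carries the
    global level; the boosting engine adds a dedicated
    :class:`InterceptBaseLearner` for offset adaptation).  The same list
    serves both additive predictors; the boosting engine keeps separate
    accumulated coefficients per predictor.
    """
    constant = [
        v for v in ALL_VARS if np.ptp(design.column(v)) < 1e-12
    ]
    if constant:
        # possible in tiny CV folds; a constant column carries no
        # information (its job is done by the intercept component)
        logging.getLogger(__name__).warning(
            "skipping base learners for constant column(s): %s", constant
        )
    learners: list[BaseLearner] = [
        LinearBaseLearner(design.column(v), v)
        for v in ALL_VARS
        if v not in constant
    ]
    learners.extend(
        PSplineBaseLearner(design.column(v), v, n_knots=n_knots, df=df)
        for v in NUMERIC_VARS
        if v not in constant
    )
    return learners
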