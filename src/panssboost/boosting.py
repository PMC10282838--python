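"""Non-cyclic component-wise gradient boosting for location-scale beta regression.

Both distribution parameters of the beta outcome carry their own additive
predictor (``eta_mu``, ``eta_sigma``) under logit links.  In each iteration
the negative-gradient vector of the empirical risk (summed negative beta
log-likelihood) is computed for each predictor and every base learner is
fitted to it by penalized least squares; each fit, damped by the step
length ``nu = 0.1``, is a candidate update.  The accepted update is the
single (predictor, learner) candidate whose realized damped risk is lowest
— an exhaustive greedy rule, so only one predictor changes per iteration
and early stopping performs variable selection on top of shrinkage.  The offsets initialize both predictors from an
intercept-only method-of-moments fit and are never refit.

The public surface follows the model/results idiom: :class:`BetaBoostLSS`
is built from data, ``fit`` returns a :class:`BetaBoostResults` carrying the
offsets, accumulated coefficients, selection history and prediction methods.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit

from . import family
from .design import (
    EncodedDesign,
    BaseLearner,
    InterceptBaseLearner,
    build_baselearners,
)
from .scale import FactorDefinition, get_factor, rescale

__all__ = ["init_offsets", "BetaBoostLSS", "BetaBoostResults", "SelectionRecord"]

logger = logging.getLogger(__name__)

#: risk differences below this are ties (resolved toward mu, then lower index)
RISK_TIE_TOL = 1e-12

MAX_MSTOP = 1000


def init_offsets(y_rescaled: np.ndarray) -> tuple[float, float]:
    """Method-of-moments intercepts for both additive predictors.

    ``offset_mu = logit(mean(y))`` and ``offset_sigma = logit(sigma_hat)``
    with ``sigma_hat^2 = s^2 / (ybar (1 - ybar))`` from the unbiased sample
    variance, clipped to [1e-6, 1 - 1e-6].
    """
    y = np.asarray(y_rescaled, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError("offsets need outcomes strictly inside (0, 1)")
    ybar = float(np.mean(y))
    s2 = float(np.var(y, ddof=1)) if y.size > 1 else 0.0
    sigma2 = s2 / (ybar * (1.0 - ybar))
    clipped = np.clip(sigma2, 1e-6, 1.0 - 1e-6)
    if clipped != sigma2:
        logger.warning("sigma offset clipped (nearly constant outcome)")
    return float(logit(ybar)), float(logit(np.sqrt(clipped)))


@dataclass(frozen=True)
class SelectionRecord:
    """One boosting update: which predictor and base learner, and the risk after."""

    iteration: int
    parameter: str  # "mu" or "sigma"
    variable: str
    kind: str
    risk: float


class BetaBoostLSS:
    """Boosted location-scale beta regression model.

    Parameters
    ----------
    y_rescaled : array-like in (0, 1)
        Rescaled factor totals.  Values equal to 1 (ceiling scores) violate
        the open-interval support of the beta likelihood and are rejected.
    design : EncodedDesign
        Encoded covariates (training centering constants recorded inside).
    baselearners : list of BaseLearner, optional
        Defaults to the standard candidate set (17 linear + 8 P-spline,
        each calibrated to one degree of freedom).
    step_length : float
        The damping factor nu applied to every accepted base-learner fit.
    intercept_learner : bool
        Add a dedicated intercept component per predictor for offset
        adaptation (the offsets themselves are never refit).  It does not
        count as a candidate variable.
    """

    def __init__(
        self,
        y_rescaled,
        design: EncodedDesign,
        baselearners: list[BaseLearner] | None = None,
        step_length: float = 0.1,
        intercept_learner: bool = True,
    ):
        y = np.asarray(y_rescaled, dtype=float)
        if np.any(y >= 1.0):
            raise ValueError(
                f"{int(np.sum(y >= 1.0))} outcome(s) at the ceiling (rescaled = 1); "
                "the beta likelihood requires the open interval (0, 1)"
            )
        if np.any(y <= 0.0):
            raise ValueError("rescaled outcomes must be strictly positive")
        if design.matrix.shape[0] != y.size:
            raise ValueError("design and outcome lengths differ")
        self.y = y
        self.design = design
        self.baselearners = (
            baselearners if baselearners is not None else build_baselearners(design)
        )
        self.learners_ = list(self.baselearners)
        if intercept_learner:
            self.learners_.append(InterceptBaseLearner(y.size))
        self.step_length = float(step_length)
        self.factor: FactorDefinition | None = None

    def _bases_for(self, df: pd.DataFrame) -> list[np.ndarray]:
        """Per-learner design matrices for new rows (training centering applied)."""
        X = self.design.transform(df)
        ones = np.ones((len(df), 1))
        return [
            ones if bl.kind == "intercept"
            else bl.design_matrix(X[:, self.design.index(bl.name)])
            for bl in self.learners_
        ]

    @classmethod
    def from_cohort(
        cls,
        df: pd.DataFrame,
        factor: str | FactorDefinition,
        step_length: float = 0.1,
        baselearners=None,
        design: EncodedDesign | None = None,
        intercept_learner: bool = True,
    ) -> "BetaBoostLSS":
        """Build the model for one factor from a cohort table.

        Expects the discharge total in column ``<factor>_dis`` and the full
        covariate schema (see :mod:`panssboost.design`).
        """
        fac = get_factor(factor)
        out_col = f"{fac.name}_dis"
        if out_col not in df.columns:
            raise ValueError(f"missing outcome column {out_col!r}")
        y = rescale(df[out_col].to_numpy(), fac)
        if design is None:
            design = EncodedDesign.from_cohort(df)
        model = cls(
            y,
            design,
            baselearners=baselearners,
            step_length=step_length,
            intercept_learner=intercept_learner,
        )
        model.factor = fac
        model.y_int = df[out_col].to_numpy(dtype=int)
        return model

    # -- fitting ---------------------------------------------------------

    def fit(self, mstop: int, test_sets=None) -> "BetaBoostResults":
        """Run ``mstop`` boosting iterations from the method-of-moments offsets.

        ``test_sets`` is an optional list of ``(df, y_rescaled)`` pairs whose
        mean held-out negative log-likelihood is tracked along the whole
        path (used for cross-validated selection of ``mstop``).
        """
        if not (0 <= mstop <= MAX_MSTOP):
            raise ValueError(f"mstop must lie in [0, {MAX_MSTOP}]")
        y = self.y
        nu = self.step_length
        learners = self.learners_
        offset_mu, offset_sigma = init_offsets(y)
        eta = {
            "mu": np.full(y.size, offset_mu),
            "sigma": np.full(y.size, offset_sigma),
        }
        coef = {
            "mu": [np.zeros(bl.design_.shape[1]) for bl in learners],
            "sigma": [np.zeros(bl.design_.shape[1]) for bl in learners],
        }

        # held-out tracking
        test = []
        if test_sets:
            for df_test, y_test in test_sets:
                bases = self._bases_for(df_test)
                test.append(
                    {
                        "y": np.asarray(y_test, dtype=float),
                        "bases": bases,
                        "eta_mu": np.full(len(df_test), offset_mu),
                        "eta_sigma": np.full(len(df_test), offset_sigma),
                        "nll_path": np.empty(mstop),
                    }
                )

        history: list[SelectionRecord] = []
        risk_path = np.empty(mstop)
        for m in range(1, mstop + 1):
            grads = dict(zip(("mu", "sigma"), family.neg_gradients(y, eta["mu"], eta["sigma"])))
            best = {}
            for param in ("mu", "sigma"):
                g = grads[param]
                fits = [bl.fit(g) for bl in learners]
                # exhaustive greedy: realized risk of every damped candidate
                cand = eta[param][:, None] + nu * np.column_stack(
                    [f[1] for f in fits]
                )
                if param == "mu":
                    risks = family.candidate_risks(y, cand, eta["sigma"], "mu")
                else:
                    risks = family.candidate_risks(y, eta["mu"], cand, "sigma")
                j = int(np.argmin(risks))  # ties resolve to the earlier learner
                best[param] = {
                    "j": j,
                    "coef": fits[j][0],
                    "fitted": fits[j][1],
                    "risk": float(risks[j]),
                }

            # non-cyclic choice by realized damped risk; ties go to mu
            if best["sigma"]["risk"] < best["mu"]["risk"] - RISK_TIE_TOL:
                param = "sigma"
            else:
                param = "mu"
            sel = best[param]
            j = sel["j"]
            eta[param] = eta[param] + nu * sel["fitted"]
            coef[param][j] = coef[param][j] + nu * sel["coef"]
            bl = learners[j]
            history.append(SelectionRecord(m, param, bl.name, bl.kind, sel["risk"]))
            risk_path[m - 1] = sel["risk"]
            if not np.isfinite(sel["risk"]):
                raise FloatingPointError(
                    f"non-finite risk at iteration {m} updating {param} with {bl.name!r}"
                )
            for t in test:
                t[f"eta_{param}"] = t[f"eta_{param}"] + nu * (t["bases"][j] @ sel["coef"])
                t["nll_path"][m - 1] = family.mean_nll(t["y"], t["eta_mu"], t["eta_sigma"])

        return BetaBoostResults(
            model=self,
            offset_mu=offset_mu,
            offset_sigma=offset_sigma,
            coef=coef,
            history=history,
            mstop=mstop,
            eta_mu=eta["mu"],
            eta_sigma=eta["sigma"],
            risk_path=risk_path,
            test_nll_paths=[t["nll_path"] for t in test],
        )


class BetaBoostResults:
    """Fitted boosted beta regression: offsets, coefficients, history, predictions."""

    def __init__(
        self,
        model: BetaBoostLSS,
        offset_mu: float,
        offset_sigma: float,
        coef: dict[str, list[np.ndarray]],
        history: list[SelectionRecord],
        mstop: int,
        eta_mu: np.ndarray,
        eta_sigma: np.ndarray,
        risk_path: np.ndarray,
        test_nll_paths: list[np.ndarray],
    ):
        self.model = model
        self.offset_mu = offset_mu
        self.offset_sigma = offset_sigma
        self.coef = coef
        self.history = history
        self.mstop = mstop
        self.eta_mu_ = eta_mu
        self.eta_sigma_ = eta_sigma
        self.risk_path_ = risk_path
        self.test_nll_paths_ = test_nll_paths

    # -- prediction ------------------------------------------------------

    def eta(self, df: pd.DataFrame | None = None) -> pd.DataFrame:
        """Additive predictors for new rows (or the training rows)."""
        learners = self.model.learners_
        if df is None:
            bases = [bl.design_ for bl in learners]
            n = self.model.y.size
        else:
            bases = self.model._bases_for(df)
            n = len(df)
        out = {}
        for param, offset in (("mu", self.offset_mu), ("sigma", self.offset_sigma)):
            eta = np.full(n, offset)
            for j, bl in enumerate(learners):
                c = self.coef[param][j]
                if np.any(c != 0.0):
                    eta = eta + bases[j] @ c
            out[param] = eta
        return pd.DataFrame({"eta_mu": out["mu"], "eta_sigma": out["sigma"]})

    def predict(self, df: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-row distribution parameters (mu, sigma) on the response scale."""
        eta = self.eta(df)
        mu, sigma = family.params_from_eta(
            eta["eta_mu"].to_numpy(), eta["eta_sigma"].to_numpy()
        )
        return pd.DataFrame({"mu": mu, "sigma": sigma})

    # -- bookkeeping -----------------------------------------------------

    def selection_table(self) -> pd.DataFrame:
        """The selection history as a tidy table (exportable as CSV)."""
        return pd.DataFrame(
            [
                {
                    "iteration": r.iteration,
                    "parameter": r.parameter,
                    "variable": r.variable,
                    "kind": r.kind,
                    "risk": r.risk,
                }
                for r in self.history
            ],
            columns=["iteration", "parameter", "variable", "kind", "risk"],
        )

    def selected_variables(
        self, parameter: str, include_intercept: bool = False
    ) -> list[str]:
        """Variables that updated the given additive predictor at least once.

        The engine's offset-adaptation component "(intercept)" is not a
        covariate and is excluded unless requested.
        """
        seen: list[str] = []
        for r in self.history:
            if r.parameter != parameter or r.variable in seen:
                continue
            if r.kind == "intercept" and not include_intercept:
                continue
            seen.append(r.variable)
        return seen

    def coefficient_table(self) -> pd.DataFrame:
        """Per (variable, parameter, kind): selection count and coefficient norm."""
        rows = []
        for param in ("mu", "sigma"):
            for j, bl in enumerate(self.model.learners_):
                c = self.coef[param][j]
                count = sum(
                    1
                    for r in self.history
                    if r.parameter == param and r.variable == bl.name and r.kind == bl.kind
                )
                rows.append(
                    {
                        "parameter": param,
                        "variable": bl.name,
                        "kind": bl.kind,
                        "n_selected": count,
                        "coef_l2": float(np.linalg.norm(c)),
                        "coef_linear": float(c[-1]) if bl.kind == "linear" else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        buf = io.StringIO()
        fac = self.model.factor.name if self.model.factor is not None else "(custom)"
        buf.write("Boosted location-scale beta regression\n")
        buf.write("=" * 54 + "\n")
        buf.write(f"outcome factor:     {fac}\n")
        buf.write(f"n observations:     {self.model.y.size}\n")
        buf.write(f"step length (nu):   {self.model.step_length}\n")
        buf.write(f"mstop:              {self.mstop}\n")
        buf.write(f"offset eta_mu:      {self.offset_mu:+.4f}\n")
        buf.write(f"offset eta_sigma:   {self.offset_sigma:+.4f}\n")
        if self.mstop:
            buf.write(f"final train risk:   {self.risk_path_[-1]:.4f}\n")
        tab = self.coefficient_table()
        tab = tab[tab["n_selected"] > 0]
        buf.write("\nselected components (updates, ||coef||):\n")
        if tab.empty:
            buf.write("  none\n")
        for _, row in tab.iterrows():
            buf.write(
                f"  eta_{row['parameter']:<6} {row['variable']:<18} "
                f"{row['kind']:<8} {row['n_selected']:>4}  {row['coef_l2']:.4f}\n"
            )
        return buf.getvalue()
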