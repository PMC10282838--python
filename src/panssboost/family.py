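"""Beta distribution in the mean/scale parameterization.

The outcome model used throughout this package is a beta distribution
parameterized by its mean ``mu`` in (0, 1) and a scale ``sigma`` in (0, 1)
with ``Var(X) = mu * (1 - mu) * sigma**2``.  Both parameters are tied to
additive predictors (``eta_mu``, ``eta_sigma``) through logit links.  The
classical shape parameters follow from the mean/variance relations::

    s     = (1 - sigma**2) / sigma**2      (concentration, alpha + beta)
    alpha = mu * s
    beta  = (1 - mu) * s

This module provides the density, CDF, random draws and the analytic
derivatives of the log-likelihood with respect to both additive predictors
(the "negative gradients" consumed by component-wise boosting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, digamma, expit, gammaln, logit, xlog1py, xlogy

__all__ = [
    "BetaParams",
    "to_shapes",
    "loglik",
    "cdf",
    "neg_gradients",
    "params_from_eta",
    "empirical_risk",
    "rvs",
    "expit",
    "logit",
]

logger = logging.getLogger(__name__)

#: clip bound for mu/sigma inside gradient and risk evaluation
PARAM_EPS = 1e-10


def _validate_open_unit(x, name: str):
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ValueError(f"{name} must lie strictly inside (0, 1)")
    return x


def to_shapes(mu, sigma):
    """Map (mu, sigma) to the classical beta shapes (alpha, beta).

    Satisfies ``alpha + beta = (1 - sigma^2)/sigma^2`` and
    ``alpha / (alpha + beta) = mu``.
    """
    mu = _validate_open_unit(mu, "mu")
    sigma = _validate_open_unit(sigma, "sigma")
    s = (1.0 - sigma**2) / sigma**2
    return mu * s, (1.0 - mu) * s


def loglik(y, mu, sigma):
    """Log-density of the beta distribution at ``y`` (strictly inside (0,1))."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError("y must lie strictly inside (0, 1)")
    a, b = to_shapes(mu, sigma)
    return (
        gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
        + xlogy(a - 1.0, y)
        + xlog1py(b - 1.0, -y)
    )


def cdf(y, mu, sigma):
    """Regularized incomplete beta function at the (mu, sigma) shapes."""
    a, b = to_shapes(mu, sigma)
    y = np.clip(np.asarray(y, dtype=float), 0.0, 1.0)
    return betainc(a, b, y)


def rvs(mu, sigma, rng: np.random.Generator):
    """Random draws from Beta(mu, sigma)."""
    a, b = to_shapes(mu, sigma)
    return rng.beta(a, b)


def params_from_eta(eta_mu, eta_sigma):
    """Inverse-logit both additive predictors, clipping away the boundary.

    Values that would round onto 0 or 1 are clipped to ``PARAM_EPS`` so that
    likelihood evaluation stays finite; clipping is flagged in the log.
    """
    mu = expit(np.asarray(eta_mu, dtype=float))
    sigma = expit(np.asarray(eta_sigma, dtype=float))
    lo, hi = PARAM_EPS, 1.0 - PARAM_EPS
    if np.any(mu < lo) or np.any(mu > hi) or np.any(sigma < lo) or np.any(sigma > hi):
        logger.warning("distribution parameters clipped away from the (0,1) boundary")
    return np.clip(mu, lo, hi), np.clip(sigma, lo, hi)


def neg_gradients(y, eta_mu, eta_sigma):
    """Derivatives of the beta log-likelihood w.r.t. both additive predictors.

    Returns ``(g_mu, g_sigma)`` where ``g_mu = d l / d eta_mu`` and
    ``g_sigma = d l / d eta_sigma``, obtained by composing the beta score in
    (alpha, beta) with the chain rule through the shape map and the logistic
    inverse links.  These are the vectors the base learners are fitted to in
    each boosting iteration.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError("y must lie strictly inside (0, 1)")
    mu, sigma = params_from_eta(eta_mu, eta_sigma)
    s = (1.0 - sigma**2) / sigma**2
    a = mu * s
    b = (1.0 - mu) * s
    log_y = np.log(y)
    log_1my = np.log1p(-y)

    # d l / d mu = s * (logit(y) - psi(alpha) + psi(beta));   d mu / d eta = mu(1-mu)
    dl_dmu = s * (log_y - log_1my - digamma(a) + digamma(b))
    g_mu = dl_dmu * mu * (1.0 - mu)

    # d l / d s at fixed mu, with s = (1-sigma^2)/sigma^2:
    dl_ds = (
        digamma(s)
        - mu * digamma(a)
        - (1.0 - mu) * digamma(b)
        + mu * log_y
        + (1.0 - mu) * log_1my
    )
    # d s / d sigma * d sigma / d eta_sigma = (-2/sigma^3) * sigma(1-sigma)
    g_sigma = dl_ds * (-2.0 * (1.0 - sigma) / sigma**2)
    return g_mu, g_sigma


def candidate_risks(y, eta_mu, eta_sigma, updated: str) -> np.ndarray:
    """Empirical risk of many candidate predictor updates at once.

    One of ``eta_mu``/``eta_sigma`` (named by ``updated``) is an (n, L)
    matrix of candidate predictors, the other a length-n vector; returns the
    length-L vector of summed negative log-likelihoods.  Terms that do not
    depend on the updated parameter are computed once per row.
    """
    y = np.asarray(y, dtype=float)[:, None]
    log_y = np.log(y)
    log_1my = np.log1p(-y)
    if updated == "mu":
        mu = np.clip(expit(np.asarray(eta_mu, dtype=float)), PARAM_EPS, 1 - PARAM_EPS)
        sigma = np.clip(
            expit(np.asarray(eta_sigma, dtype=float)), PARAM_EPS, 1 - PARAM_EPS
        )
        s = ((1.0 - sigma**2) / sigma**2)[:, None]
        a = mu * s
        b = s - a
        gammaln_s = gammaln(s)
    elif updated == "sigma":
        mu = np.clip(
            expit(np.asarray(eta_mu, dtype=float)), PARAM_EPS, 1 - PARAM_EPS
        )[:, None]
        sigma = np.clip(expit(np.asarray(eta_sigma, dtype=float)), PARAM_EPS, 1 - PARAM_EPS)
        s = (1.0 - sigma**2) / sigma**2
        a = mu * s
        b = s - a
        gammaln_s = gammaln(s)
    else:  # pragma: no cover - internal misuse
        raise ValueError("updated must be 'mu' or 'sigma'")
    ll = gammaln_s - gammaln(a) - gammaln(b) + (a - 1.0) * log_y + (b - 1.0) * log_1my
    return -ll.sum(axis=0)


def empirical_risk(y, eta_mu, eta_sigma) -> float:
    """Sum of negative log-likelihoods at the inverse-linked predictors."""
    mu, sigma = params_from_eta(eta_mu, eta_sigma)
    return float(-np.sum(loglik(y, mu, sigma)))


def mean_nll(y, eta_mu, eta_sigma) -> float:
    """Mean per-observation negative log-likelihood (held-out predictive risk)."""
    mu, sigma = params_from_eta(eta_mu, eta_sigma)
    return float(-np.mean(loglik(y, mu, sigma)))


@dataclass(frozen=True)
class BetaParams:
    """A beta distribution (or a vector of them) in the (mu, sigma) scale.

    ``mu`` is the mean; ``sigma`` the scale with ``Var = mu(1-mu)sigma^2``.
    """

    mu: np.ndarray | float
    sigma: np.ndarray | float

    def __post_init__(self):
        _validate_open_unit(self.mu, "mu")
        _validate_open_unit(self.sigma, "sigma")

    @property
    def shapes(self):
        return to_shapes(self.mu, self.sigma)

    @property
    def alpha(self):
        return self.shapes[0]

    @property
    def beta_shape(self):
        return self.shapes[1]

    @property
    def mean(self):
        return np.asarray(self.mu, dtype=float)

    @property
    def var(self):
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        return mu * (1.0 - mu) * sigma**2
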