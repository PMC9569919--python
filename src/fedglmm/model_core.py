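"""The joint log-density g(mu, theta) of one site and its partial derivatives.

The model is a logistic regression with a site-level Gaussian random
intercept: conditional on the site effect mu_i, outcomes are Bernoulli with
log-odds X_ij beta + mu_i, and mu_i ~ Normal(0, tau) with tau the VARIANCE of
the random-intercept distribution.  A site's marginal likelihood is the
integral over mu of exp(g(mu, theta)) where

    g(mu, theta) = sum_j [ y_ij eta_ij - log(1 + e^{eta_ij}) ]
                   - mu^2 / (2 tau) - log(2 pi tau) / 2,
    eta_ij = X_ij beta + mu.

Everything downstream (mode finding, Laplace / adaptive Gauss-Hermite
approximation, implicit differentiation of the mode) consumes g and the
closed-form partials collected in :class:`GDerivatives`.  All evaluations use
the stable sigmoid / log1p forms, so nothing overflows for |eta| up to 1e4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .exceptions import DomainError, InputError

__all__ = [
    "SiteData",
    "Theta",
    "GDerivatives",
    "empty_site",
    "linear_predictor",
    "g_value_and_derivatives",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SiteData:
    """One site's design matrix, binary outcomes and sample size.

    ``X`` is n_i x p with column 0 the all-ones intercept; ``y`` is a length
    n_i vector in {0, 1}.  Validation happens at construction so downstream
    numerics can assume a clean site.
    """

    site_id: str
    X: np.ndarray
    y: np.ndarray
    n_i: int = field(init=False)

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=float).ravel()
        if X.ndim != 2:
            raise InputError(f"site {self.site_id}: X must be a 2-D matrix")
        if X.shape[0] != y.shape[0]:
            raise InputError(
                f"site {self.site_id}: X has {X.shape[0]} rows but y has {y.shape[0]} entries"
            )
        if X.size and not np.isfinite(X).all():
            raise InputError(f"site {self.site_id}: X contains non-finite values")
        if y.size and not np.isin(y, (0.0, 1.0)).all():
            raise InputError(f"site {self.site_id}: outcomes must all be 0 or 1")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "n_i", int(X.shape[0]))

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class Theta:
    """Global parameter theta = (beta, tau).

    ``beta``: fixed-effect coefficients (length p, intercept first).
    ``tau``: variance (not SD) of the Gaussian random-intercept distribution.
    """

    beta: np.ndarray
    tau: float

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=float).ravel()
        if not np.isfinite(beta).all():
            raise InputError("beta must be finite")
        tau = float(self.tau)
        if not (np.isfinite(tau) and tau > 0.0):
            raise DomainError(f"tau must be a positive finite variance, got {tau!r}")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "tau", tau)

    @property
    def p(self) -> int:
        return self.beta.shape[0]


@dataclass(frozen=True)
class GDerivatives:
    """g and its partial derivatives at one (site, theta, mu).

    Subscripts follow the usual convention: ``g_mu`` is dg/dmu, ``g_mubeta``
    the p-vector d2g/dmu dbeta, ``g_mumutau`` the scalar d3g/dmu2 dtau, etc.
    ``g_mumu`` is strictly negative for tau > 0 (the -1/tau prior curvature
    dominates), which is what makes the inner mode search well-posed.
    """

    g: float
    g_mu: float
    g_mumu: float
    g_mumumu: float
    g_beta: np.ndarray
    g_betabeta: np.ndarray
    g_mubeta: np.ndarray
    g_mumubeta: np.ndarray
    g_tau: float
    g_mutau: float
    g_mumutau: float


def empty_site(p: int, site_id: str = "empty") -> SiteData:
    """A site with zero patients and p covariate columns (intercept included)."""
    return SiteData(site_id=site_id, X=np.empty((0, int(p))), y=np.empty(0))


def linear_predictor(site: SiteData, beta: np.ndarray, mu: float) -> np.ndarray:
    """eta_ij = X_ij . beta + mu for every patient j of the site."""
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != site.p:
        raise InputError(
            f"beta has length {beta.shape[0]} but site {site.site_id} has p={site.p}"
        )
    return site.X @ beta + float(mu)


def g_value_and_derivatives(site: SiteData, theta: Theta, mu: float) -> GDerivatives:
    """Evaluate g(mu, theta) and all partials needed by the approximations.

    With pi_ij = expit(eta_ij) and w_ij = pi_ij (1 - pi_ij):

    * g_mu      = sum(y - pi) - mu/tau
    * g_mumu    = -sum(w) - 1/tau
    * g_mumumu  = -sum(w (1 - 2 pi))
    * g_beta    = X^T (y - pi)
    * g_betabeta = -X^T diag(w) X
    * g_mubeta  = -X^T w
    * g_mumubeta = -X^T [w (1 - 2 pi)]
    * g_tau     = -1/(2 tau) + mu^2/(2 tau^2)
    * g_mutau   = mu / tau^2
    * g_mumutau = 1 / tau^2

    The Bernoulli log-likelihood term uses logaddexp, so the value is finite
    for |eta| up to at least 1e4.
    """
    if theta.p != site.p:
        raise InputError(
            f"theta has p={theta.p} but site {site.site_id} has p={site.p}"
        )
    mu = float(mu)
    tau = theta.tau

    eta = linear_predictor(site, theta.beta, mu)
    pi = expit(eta)
    w = pi * (1.0 - pi)
    resid = site.y - pi

    # sum_j [y eta - log(1 + e^eta)], stable for large |eta|
    cond_loglik = float(np.sum(site.y * eta - np.logaddexp(0.0, eta)))
    prior = -0.5 * mu * mu / tau - 0.5 * (_LOG_2PI + math.log(tau))

    w_skew = w * (1.0 - 2.0 * pi)
    return GDerivatives(
        g=cond_loglik + prior,
        g_mu=float(resid.sum()) - mu / tau,
        g_mumu=-float(w.sum()) - 1.0 / tau,
        g_mumumu=-float(w_skew.sum()),
        g_beta=site.X.T @ resid,
        g_betabeta=-(site.X.T * w) @ site.X,
        g_mubeta=-site.X.T @ w,
        g_mumubeta=-site.X.T @ w_skew,
        g_tau=-0.5 / tau + 0.5 * mu * mu / (tau * tau),
        g_mutau=mu / (tau * tau),
        g_mumutau=1.0 / (tau * tau),
    )
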