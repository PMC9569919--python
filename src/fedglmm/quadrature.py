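"""Gauss-Hermite quadrature rules and the log-sum-exp primitive.

The marginal likelihood of a site integrates the conditional likelihood
against a Gaussian random-intercept density.  Adaptive Gauss-Hermite
quadrature evaluates that integral with K nodes placed at the roots of the
physicists' Hermite polynomial H_K, recentred and rescaled at the integrand's
mode; K = 1 is exactly the Laplace approximation.  The log-sum-exp shift is
what keeps the K-term exponential sum finite when individual log-integrand
values reach magnitudes of 10^4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import logsumexp as _scipy_logsumexp

from .exceptions import InputError

__all__ = ["QuadratureRule", "gh_rule", "logsumexp"]


@dataclass(frozen=True)
class QuadratureRule:
    """Nodes x_k and weights h_k of a K-point Gauss-Hermite rule.

    The rule integrates against the weight function exp(-x^2); the weights
    sum to sqrt(pi) and the nodes are symmetric about zero.
    """

    K: int
    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))


def gh_rule(K: int) -> QuadratureRule:
    """Return the K-point Gauss-Hermite rule (weight exp(-x^2)).

    Exact for polynomials of degree <= 2K - 1:
    sum_k h_k q(x_k) = integral q(x) exp(-x^2) dx.

    Parameters
    ----------
    K : int
        Quadrature order, >= 1.  K = 1 gives the single node 0 with weight
        sqrt(pi), which reduces adaptive quadrature to the Laplace
        approximation.
    """
    if not isinstance(K, (int, np.integer)) or K < 1:
        raise InputError(f"quadrature order K must be an integer >= 1, got {K!r}")
    nodes, weights = hermgauss(int(K))
    return QuadratureRule(K=int(K), nodes=nodes, weights=weights)


def logsumexp(terms) -> float:
    """Numerically stable log(sum(exp(terms))).

    Shifts by a = max(terms) so the largest exponent is zero; the identity
    a + log sum exp(terms - a) is exact in value, so no accuracy is lost.
    Entries may be -inf (they contribute nothing); an all -inf input returns
    -inf.

    Raises
    ------
    InputError
        If ``terms`` is empty or contains NaN/+inf.
    """
    v = np.asarray(terms, dtype=float)
    if v.size == 0:
        raise InputError("logsumexp of an empty vector is undefined")
    if np.isnan(v).any() or np.isposinf(v).any():
        raise InputError("logsumexp requires entries in [-inf, +inf)")
    return float(_scipy_logsumexp(v))
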