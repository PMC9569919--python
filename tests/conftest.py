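import math

import numpy as np
import pytest

from fedglmm.model_core import SiteData, Theta, g_value_and_derivatives


def random_site(rng, n=None, p=None, site_id="s", beta_scale=1.0):
    """A random small logistic site with an intercept column."""
    n = int(rng.integers(4, 25)) if n is None else n
    p = int(rng.integers(2, 6)) if p is None else p
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    eta = X @ (beta_scale * rng.normal(size=p))
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return SiteData(site_id=site_id, X=X, y=y)


def random_theta(rng, p, beta_scale=0.8):
    return Theta(beta_scale * rng.normal(size=p), float(rng.uniform(0.2, 3.0)))


def g_on_grid(site, theta, mus, chunk=20000):
    """Vectorized g(mu) over a grid, for grid-search and dense-integration oracles."""
    xb = site.X @ theta.beta
    out = np.empty(len(mus))
    log_prior_const = -0.5 * math.log(2 * math.pi * theta.tau)
    for lo in range(0, len(mus), chunk):
        mu = mus[lo : lo + chunk]
        eta = xb[:, None] + mu[None, :]
        ll = site.y[:, None] * eta - np.logaddexp(0.0, eta)
        out[lo : lo + chunk] = ll.sum(axis=0) - 0.5 * mu * mu / theta.tau + log_prior_const
    return out


def dense_site_loglik(site, theta, n_points=100001, half_width=12.0):
    """High-resolution trapezoid evaluation of log integral exp(g) dmu."""
    from scipy.special import logsumexp as lse

    from fedglmm.site_engine import find_mode

    mode = find_mode(site, theta)
    mus = np.linspace(
        mode.mu_hat - half_width * mode.omega_hat,
        mode.mu_hat + half_width * mode.omega_hat,
        n_points,
    )
    g = g_on_grid(site, theta, mus)
    w = np.zeros(n_points)
    w[0] = w[-1] = math.log(0.5)
    return float(lse(g + w) + math.log(mus[1] - mus[0]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
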