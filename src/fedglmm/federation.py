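"""Federated fitting loop: broadcast theta, collect summaries, Newton step.

Each round every site computes a :class:`~fedglmm.site_engine.SiteSummary` at
the current global theta; the coordinator sums them (the objective
sum_i l_i is linearly decomposable, so summation is the exact aggregate),
takes a ridge-regularized Newton step in beta and a backtracking gradient
ascent step in log(tau), and stops when the largest parameter change falls
below the convergence tolerance (default 1e-3).

``run_federated_fit`` pushes every summary through a JSON round-trip — the
simulated network — while ``fit_pooled`` evaluates the identical objective
directly; the two must agree to machine precision, which is the loss-less
property of the decomposition.  An L2 penalty grid sweep
(:func:`lambda_sweep`) selects the regularization strength on held-out
validation sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .exceptions import InputError, ProtocolError, SingularityError
from .model_core import SiteData, Theta
from .quadrature import QuadratureRule, gh_rule
from .site_engine import SiteSummary, site_loglik, site_summary

__all__ = [
    "FederationConfig",
    "Aggregates",
    "FitResult",
    "aggregate",
    "newton_step",
    "run_federated_fit",
    "fit_pooled",
    "lambda_sweep",
]

_MAX_RIDGE = 1e3
_MAX_CONDITION = 1e10
_MAX_HALVINGS = 30


@dataclass(frozen=True)
class FederationConfig:
    """Knobs of the federated fitting algorithm.

    method "la" is exactly "gh" with K forced to 1; ``lambda_grid`` is the
    penalty sweep 0..10 by 1; ``conv_tol`` bounds the largest change of any
    parameter (beta entries and log tau) between rounds; the adaptive ridge
    starts at ``ridge_init`` and grows by ``ridge_factor`` until the Newton
    system is positive definite and well conditioned.  ``fix_tau`` freezes
    the variance component (useful for degenerate single-site checks).
    """

    method: str = "gh"
    K: int = 2
    lambda_grid: tuple = tuple(float(v) for v in range(11))
    conv_tol: float = 1e-3
    max_rounds: int = 200
    ridge_init: float = 1e-6
    ridge_factor: float = 10.0
    seed: int = 0
    criterion: str = "validloglik"
    penalize_intercept: bool = True
    fix_tau: float | None = None
    inner_tol: float = 1e-8
    inner_max_iter: int = 100

    def __post_init__(self):
        if self.method not in ("la", "gh"):
            raise InputError(f"method must be 'la' or 'gh', got {self.method!r}")
        if self.conv_tol <= 0:
            raise InputError("conv_tol must be positive")
        if len(self.lambda_grid) == 0 or any(l < 0 for l in self.lambda_grid):
            raise InputError("lambda_grid must be non-empty and non-negative")
        if self.criterion not in ("validloglik", "aic", "bic"):
            raise InputError(f"unknown criterion {self.criterion!r}")

    def rule(self) -> QuadratureRule:
        return gh_rule(1 if self.method == "la" else self.K)


@dataclass(frozen=True)
class Aggregates:
    """Summed site statistics for one round."""

    loglik: float
    score_beta: np.ndarray
    hess_beta: np.ndarray
    score_tau: float


@dataclass
class FitResult:
    """Converged global estimates and everything needed for inference."""

    beta_hat: np.ndarray
    tau_hat: float
    mu_hats: np.ndarray
    cov_beta: np.ndarray
    loglik: float
    lambda_opt: float
    rounds: int
    converged: bool
    trace: list = field(default_factory=list)
    n_total: int = 0
    p: int = 0
    K: int = 1
    method: str = "gh"
    max_ridge_delta: float = 0.0

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "method": self.method,
            "K": self.K,
            "beta_hat": self.beta_hat.tolist(),
            "tau_hat": self.tau_hat,
            "mu_hats": self.mu_hats.tolist(),
            "cov_beta": self.cov_beta.tolist(),
            "loglik": self.loglik,
            "lambda_opt": self.lambda_opt,
            "rounds": self.rounds,
            "converged": self.converged,
            "n_total": self.n_total,
            "p": self.p,
            "max_ridge_delta": self.max_ridge_delta,
            "trace": self.trace,
        }


def aggregate(summaries: list[SiteSummary]) -> Aggregates:
    """Sum the per-site statistics of one round.

    The total objective is sum_i l_i, so element-wise summation is the exact
    aggregate; all messages must share p, K and lambda.
    """
    if not summaries:
        raise InputError("cannot aggregate an empty summary list")
    ref = summaries[0]
    for s in summaries[1:]:
        if s.p != ref.p or s.K != ref.K or s.lam != ref.lam:
            raise ProtocolError(
                f"site {s.site_id} sent (p={s.p}, K={s.K}, lambda={s.lam}) but the "
                f"round uses (p={ref.p}, K={ref.K}, lambda={ref.lam})"
            )
    return Aggregates(
        loglik=float(sum(s.loglik for s in summaries)),
        score_beta=np.sum([s.score_beta for s in summaries], axis=0),
        hess_beta=np.sum([s.hess_beta for s in summaries], axis=0),
        score_tau=float(sum(s.score_tau for s in summaries)),
    )


def _ridged_factor(hess: np.ndarray, config: FederationConfig):
    """Cholesky factor of -(H - delta I) for the smallest workable delta.

    Tries delta = 0 first, then ridge_init * ridge_factor^t, accepting the
    first delta for which the negated Hessian is positive definite and has
    condition estimate <= 1e10.
    """
    delta = 0.0
    t = 0
    while delta <= _MAX_RIDGE:
        A = -hess + delta * np.eye(hess.shape[0])
        try:
            chol = scipy.linalg.cho_factor(A)
        except scipy.linalg.LinAlgError:
            chol = None
        if chol is not None and np.linalg.cond(A) <= _MAX_CONDITION:
            return chol, delta
        delta = config.ridge_init * config.ridge_factor**t
        t += 1
    raise SingularityError(
        f"no ridge delta <= {_MAX_RIDGE} makes the Newton system positive definite"
    )


def newton_step(theta: Theta, agg: Aggregates, config: FederationConfig, eval_total):
    """One global update: ridged Newton in beta, backtracking ascent in log tau.

    beta moves along (-H + delta I)^{-1} s with the adaptive ridge delta;
    tau moves along its gradient on the log scale (the protocol only carries
    a first-order tau statistic).  The joint step is halved (<= 30 times)
    until the penalized total log-likelihood does not decrease; if no
    halving achieves that, the iterate is left unchanged and the stall is
    reported in the step info.

    ``eval_total`` maps a Theta to the penalized sum of site log-likelihoods
    and stands in for one broadcast/collect round of the network.

    Returns (new_theta, info_dict).
    """
    if not (
        np.isfinite(agg.score_beta).all()
        and np.isfinite(agg.hess_beta).all()
        and np.isfinite(agg.score_tau)
    ):
        raise InputError("aggregated statistics contain non-finite values")

    chol, delta = _ridged_factor(agg.hess_beta, config)
    d_beta = scipy.linalg.cho_solve(chol, agg.score_beta)
    if config.fix_tau is not None:
        d_logtau = 0.0
    else:
        d_logtau = float(np.clip(agg.score_tau * theta.tau, -1.0, 1.0))

    f_curr = agg.loglik
    log_tau = math.log(theta.tau)
    step = 1.0
    for halvings in range(_MAX_HALVINGS + 1):
        proposal = Theta(
            theta.beta + step * d_beta, math.exp(log_tau + step * d_logtau)
        )
        f_prop = eval_total(proposal)
        if f_prop >= f_curr - 1e-12:
            return proposal, {
                "ridge_delta": delta,
                "halvings": halvings,
                "stalled": False,
                "loglik": f_prop,
            }
        step *= 0.5
    return theta, {
        "ridge_delta": delta,
        "halvings": _MAX_HALVINGS,
        "stalled": True,
        "loglik": f_curr,
    }


def _check_sites(sites: list[SiteData]):
    if not sites:
        raise InputError("at least one site is required")
    p = sites[0].p
    for s in sites:
        if s.p != p:
            raise InputError(
                f"site {s.site_id} has p={s.p}, expected p={p} shared by all sites"
            )
    return p


def _fit(
    sites: list[SiteData],
    config: FederationConfig,
    lam: float,
    simulate_network: bool,
) -> FitResult:
    p = _check_sites(sites)
    rule = config.rule()
    theta = Theta(np.zeros(p), config.fix_tau if config.fix_tau is not None else 1.0)

    def collect(th: Theta) -> list[SiteSummary]:
        out = []
        for s in sites:
            summ = site_summary(
                s,
                th,
                rule,
                lam=lam,
                penalize_intercept=config.penalize_intercept,
                inner_tol=config.inner_tol,
                inner_max_iter=config.inner_max_iter,
            )
            if simulate_network:
                summ = SiteSummary.from_json(summ.to_json())
            out.append(summ)
        return out

    def eval_total(th: Theta) -> float:
        return float(
            sum(
                site_loglik(
                    s,
                    th,
                    rule,
                    lam=lam,
                    penalize_intercept=config.penalize_intercept,
                    inner_tol=config.inner_tol,
                    inner_max_iter=config.inner_max_iter,
                )
                for s in sites
            )
        )

    trace = []
    converged = False
    rounds = 0
    max_ridge = 0.0
    summaries = collect(theta)
    for rounds in range(1, config.max_rounds + 1):
        agg = aggregate(summaries)
        theta_new, info = newton_step(theta, agg, config, eval_total)
        delta_param = max(
            float(np.max(np.abs(theta_new.beta - theta.beta))),
            abs(math.log(theta_new.tau) - math.log(theta.tau)),
        )
        max_ridge = max(max_ridge, info["ridge_delta"])
        trace.append(
            {
                "round": rounds,
                "loglik": info["loglik"],
                "max_step": delta_param,
                "ridge_delta": info["ridge_delta"],
                "halvings": info["halvings"],
                "stalled": info["stalled"],
            }
        )
        theta = theta_new
        summaries = collect(theta)
        if delta_param <= config.conv_tol:
            converged = True
            break

    agg = aggregate(summaries)
    # Covariance from the curvature of the penalized objective at the optimum;
    # pseudo-inverse so rank-deficient designs (ridge-rescued fits) stay finite.
    cov_beta = np.linalg.pinv(-agg.hess_beta, hermitian=True)
    cov_beta = 0.5 * (cov_beta + cov_beta.T)
    loglik_unpen = float(
        sum(
            site_loglik(
                s,
                theta,
                rule,
                lam=0.0,
                inner_tol=config.inner_tol,
                inner_max_iter=config.inner_max_iter,
            )
            for s in sites
        )
    )
    return FitResult(
        beta_hat=theta.beta.copy(),
        tau_hat=theta.tau,
        mu_hats=np.array([s.mu_hat for s in summaries]),
        cov_beta=cov_beta,
        loglik=loglik_unpen,
        lambda_opt=float(lam),
        rounds=rounds,
        converged=converged,
        trace=trace,
        n_total=int(sum(s.n_i for s in sites)),
        p=p,
        K=rule.K,
        method=config.method,
        max_ridge_delta=max_ridge,
    )


def run_federated_fit(
    sites: list[SiteData], config: FederationConfig, lam: float = 0.0
) -> FitResult:
    """Fit the mixed model by federated rounds over the simulated network.

    Every SiteSummary crosses a JSON round-trip before aggregation, exactly
    as it would cross the wire; since serialization is bit-faithful this
    changes nothing — the decomposition is loss-less.
    """
    return _fit(sites, config, lam, simulate_network=True)


def fit_pooled(
    sites: list[SiteData], config: FederationConfig, lam: float = 0.0
) -> FitResult:
    """Maximize the identical objective with all data in one place.

    Same per-site likelihood terms, same Newton driver, no message passing;
    agreement with :func:`run_federated_fit` to machine precision is the
    correctness property of the federated decomposition.
    """
    return _fit(sites, config, lam, simulate_network=False)


def _validation_score(fit: FitResult, valid_sites, config: FederationConfig, lam):
    """Score a fitted theta on held-out sites; larger is better."""
    rule = config.rule()
    theta = Theta(fit.beta_hat, fit.tau_hat)
    vll = float(sum(site_loglik(s, theta, rule, lam=0.0) for s in valid_sites))
    if config.criterion == "validloglik":
        return vll
    d = fit.p + 1
    n_valid = int(sum(s.n_i for s in valid_sites))
    if config.criterion == "aic":
        return -(-2.0 * vll + 2.0 * d)
    return -(-2.0 * vll + d * math.log(n_valid))


def lambda_sweep(
    train_sites: list[SiteData],
    valid_sites: list[SiteData],
    config: FederationConfig,
):
    """Sweep the L2 penalty grid; pick the lambda best on validation sites.

    Fits once per lambda on the training sites and scores each fitted theta
    on the validation sites by the configured criterion (validation
    log-likelihood by default, AIC or BIC on request).  Ties go to the
    smallest lambda.  Returns (lambda_opt, fit_at_lambda_opt, per-lambda
    score table).
    """
    _check_sites(train_sites)
    _check_sites(valid_sites)
    grid = sorted(set(float(l) for l in config.lambda_grid))
    best = None
    failures = {}
    table = []
    for lam in grid:
        try:
            fit = run_federated_fit(train_sites, config, lam=lam)
            score = _validation_score(fit, valid_sites, config, lam)
        except Exception as exc:  # noqa: BLE001 - per-lambda failures are collected
            failures[lam] = repr(exc)
            continue
        table.append({"lambda": lam, "score": score})
        if best is None or score > best[1]:
            best = (lam, score, fit)
    if best is None:
        raise _sweep_error(failures)
    lam_opt, _, fit_opt = best
    fit_opt = replace(fit_opt, lambda_opt=float(lam_opt))
    return lam_opt, fit_opt, table


def _sweep_error(failures):
    from .exceptions import SweepError

    lines = "; ".join(f"lambda={l}: {msg}" for l, msg in failures.items())
    return SweepError(f"every fit in the penalty sweep failed ({lines})", failures)
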