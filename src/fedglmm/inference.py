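"""Wald tests, information criteria and simulation-study evaluation metrics.

Significance of each fixed effect is judged by the Wald statistic
z_r = beta_hat_r / SE_r with SE_r from the inverse curvature of the fitted
objective, against the standard normal (two-sided).  Across simulation
replicates the rejection rate at level alpha is the empirical power for a
non-null coefficient and the empirical type-I error for a null one.
Significance calls against the generating truth give precision / recall /
accuracy; score-based classification quality is summarized by ROC/AUC, and
binomial proportions carry Wilson score intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint

from .exceptions import InferenceError, InputError
from .federation import FitResult

__all__ = [
    "CoefficientReport",
    "EvalReport",
    "wald_tests",
    "information_criteria",
    "significance_metrics",
    "power_curve",
    "roc_auc",
    "wilson_interval",
]


@dataclass(frozen=True)
class CoefficientReport:
    """Per-coefficient Wald inference at significance level alpha."""

    estimate: np.ndarray
    std_error: np.ndarray
    z: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    alpha: float

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "estimate": self.estimate.tolist(),
            "std_error": self.std_error.tolist(),
            "z": self.z.tolist(),
            "p_value": self.p_value.tolist(),
            "significant": [bool(s) for s in self.significant],
        }


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and derived rates of significance calls vs truth.

    precision is None (reported missing, not 0) when no positive call was
    made; F1 is None whenever precision or recall is undefined or their sum
    is zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float | None
    recall: float | None
    accuracy: float
    f1: float | None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "f1": self.f1,
        }


def wald_tests(fit: FitResult, alpha: float = 0.05) -> CoefficientReport:
    """Two-sided Wald z-tests for every fixed-effect coefficient.

    SE_r = sqrt(cov_beta[r, r]); p = 2 (1 - Phi(|z|)); a coefficient is
    called significant when p < alpha.
    """
    if not 0 < alpha < 1:
        raise InputError(f"alpha must be in (0, 1), got {alpha}")
    cov = np.asarray(fit.cov_beta, dtype=float)
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if not np.isfinite(cov).all() or eigmin < -1e-8 * max(1.0, float(np.abs(cov).max())):
        raise InferenceError("covariance of beta_hat is not positive semi-definite")
    var = np.clip(np.diag(cov), 0.0, None)
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, fit.beta_hat / se, 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    return CoefficientReport(
        estimate=fit.beta_hat.copy(),
        std_error=se,
        z=z,
        p_value=p,
        significant=p < alpha,
        alpha=float(alpha),
    )


def information_criteria(fit: FitResult) -> tuple[float, float]:
    """(AIC, BIC) with d = p + 1 parameters: the fixed effects plus tau.

    The site intercepts are integrated out of the marginal likelihood and do
    not count as parameters.  AIC = -2 loglik + 2 d; BIC = -2 loglik +
    d log N with N the total patient count.
    """
    if fit.n_total <= 0:
        raise InputError("information criteria need a positive total sample size")
    if not np.isfinite(fit.loglik):
        raise InputError("information criteria need a finite log-likelihood")
    d = fit.p + 1
    aic = -2.0 * fit.loglik + 2.0 * d
    bic = -2.0 * fit.loglik + d * math.log(fit.n_total)
    return aic, bic


def significance_metrics(calls, truth) -> EvalReport:
    """Precision / recall / accuracy of significance calls against truth."""
    calls = np.asarray(calls, dtype=bool).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if calls.shape != truth.shape:
        raise InputError(
            f"calls ({calls.shape[0]}) and truth ({truth.shape[0]}) differ in length"
        )
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    fn = int(np.sum(~calls & truth))
    tn = int(np.sum(~calls & ~truth))
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total else 0.0
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        precision=precision, recall=recall, accuracy=accuracy, f1=f1,
    )


def power_curve(replicate_reports: list[CoefficientReport]) -> np.ndarray:
    """Per-coefficient rejection rate across simulation replicates.

    For a truly non-null coefficient this is the empirical power at the
    reports' alpha; for a truly null one it is the empirical type-I error.
    """
    if not replicate_reports:
        raise InputError("power_curve needs at least one replicate report")
    calls = np.stack([r.significant for r in replicate_reports])
    return calls.mean(axis=0)


def roc_auc(scores, labels):
    """(AUC, ROC points) of continuous scores against binary labels.

    AUC is the probability that a random positive outscores a random
    negative, ties counted one half (the Mann-Whitney form).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if scores.shape != labels.shape:
        raise InputError("scores and labels differ in length")
    if labels.all() or not labels.any():
        raise InferenceError("AUC requires both classes present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, np.column_stack([fpr, tpr])


def wilson_interval(successes: int, n: int, level: float = 0.95):
    """Wilson score confidence interval for a binomial proportion."""
    if not 0 <= successes <= n or n <= 0:
        raise InputError(f"need 0 <= successes <= n with n > 0, got {successes}/{n}")
    if not 0 < level < 1:
        raise InputError(f"confidence level must be in (0, 1), got {level}")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="wilson")
    return float(lo), float(hi)
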