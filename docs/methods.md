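# Methods

## Model

`fedglmm` fits a logistic generalized linear mixed model with a single
Gaussian random intercept per site on horizontally partitioned data.  For
site i with n_i patients, design rows X_ij (column 1 the intercept) and
binary outcomes y_ij,

    y_ij | mu_i ~ Bernoulli(expit(X_ij beta + mu_i)),
    mu_i ~ Normal(0, tau),

where tau is the **variance** of the random-intercept distribution (the
lme4 reporting convention).  The marginal log-likelihood decomposes over
sites,

    l(theta) = sum_i log INT exp{ g(mu, theta) } dmu,
    g(mu, theta) = sum_j [ y_ij eta_ij - log(1 + e^{eta_ij}) ]
                   - mu^2/(2 tau) - log(2 pi tau)/2,

and each site integral is evaluated by adaptive Gauss-Hermite quadrature:
with mu_hat the inner mode of g, omega_hat = sqrt(-1/g_mumu(mu_hat)), and
(x_k, h_k) the K-point Gauss-Hermite rule for weight e^{-x^2},

    l_i = log(sqrt(2) omega_hat)
        + logsumexp_k [ log h_k + x_k^2 + g(mu_hat + sqrt(2) omega_hat x_k) ]
        - lambda ||beta||_2^2 .

K = 1 (node 0, weight sqrt(pi)) collapses exactly to the Laplace
approximation log(sqrt(2 pi) omega_hat) + g(mu_hat) - lambda ||beta||^2;
this identity is asserted in the test suite to 1e-10 and is the reason the
"LA" method is implemented as the K = 1 special case of the same code path.
The quadrature-term sum is always combined through a max-shifted
log-sum-exp, so the likelihood stays finite when individual exponents reach
magnitude 1e4 (a separated site with a large linear predictor produces
exactly this).

The optional ridge term penalizes every fixed effect including the
intercept by default (`penalize_intercept=False` excludes it).

## Federated algorithm

Because the objective is a sum over sites, each round of fitting exchanges
only aggregate statistics.  Every site transmits its penalized l_i, the
p-vector score dl_i/dbeta, the p x p Hessian d2l_i/dbeta2, the scalar
dl_i/dtau, its mode mu_hat_i and n_i.  The coordinator **sums** these
messages (for a sum-decomposable objective the sum is the exact aggregate;
averaging-then-rescaling in the FedAvg style yields the identical Newton
direction) and updates

* beta by a Newton step on the summed score/Hessian, with an adaptive
  ridge: the smallest delta in {0, 1e-6 * 10^t} for which -(H - delta I)
  admits a Cholesky factorization with condition estimate <= 1e10.  This is
  what survives rank-deficient designs (collinear covariates) and complete
  separation;
* tau by a backtracking gradient-ascent step on the log scale (the
  protocol carries only a first-order tau statistic, so no Newton step is
  available for the variance), with the proposed log-step clipped to +/-1;
* both jointly step-halved (at most 30 times) until the penalized total
  log-likelihood does not decrease.  If no halving achieves that the
  iterate is left unchanged, the stall is recorded in the trace, and the
  loop terminates on the parameter-change test.

Iteration starts at beta = 0, tau = 1 and stops when the largest absolute
change across all parameters (beta entries and log tau) is <= `conv_tol`
(default 1e-3), or after `max_rounds` (default 200; non-convergence is
reported in the result, not raised).

`run_federated_fit` pushes every site message through a JSON round-trip (a
simulated network; exact for all finite doubles), while `fit_pooled` runs
the identical arithmetic in-process.  Their agreement to machine precision
is the loss-less-decomposition property; the *independent* correctness
checks in the test suite are a BFGS optimizer run on the same objective
(agreement ~1e-6) and lme4's `glmer` on one problem (agreement ~1e-3, the
two implementations use different inner solvers and stopping rules).

### Score and Hessian of the profiled objective

mu_hat and omega_hat depend implicitly on (beta, tau).  The transmitted
score is analytic: from stationarity g_mu(mu_hat) = 0,

    d mu_hat / d beta = -g_mubeta / g_mumu,
    d omega_hat / d beta = omega_hat^3 (g_mumumu mu_hat_beta + g_mumubeta)/2,

(and analogously in tau), and the chain rule through the quadrature
abscissae gives dl_i/dbeta and dl_i/dtau with softmax weights over the
quadrature terms.  The beta-Hessian is built by central finite differences
of the analytic score (step 1e-5 * max(1, |beta_r|), inner solves
warm-started at the unperturbed mode, symmetrized).  The contract — every
transmitted derivative matches independent central finite differences of
`site_loglik` to relative error 1e-4 — is enforced in the tests; it holds
at ~1e-10 for the score and ~1e-5 for the Hessian.

The covariance of beta_hat is the pseudo-inverse of the negated summed
Hessian at the optimum (penalty curvature included).  The pseudo-inverse
rather than the inverse keeps rank-deficient (ridge-rescued) fits finite;
for full-rank problems the two coincide.

### Penalty sweep

`lambda_sweep` fits once per lambda on the grid (default 0..10 by 1) on the
training sites and scores each fitted theta on held-out validation sites.
The default criterion is the validation log-likelihood; AIC or BIC
(d = p + 1 parameters: beta plus tau, with the integrated-out mu_i not
counted) are selectable because both selection rules are sensible and they
can disagree.  Ties go to the smallest lambda.

## Inference

Wald z = beta_hat_r / SE_r against the standard normal, two-sided, with
significance at p < alpha (default 0.05, no multiplicity correction —
per-coefficient calls are the quantity of interest in the stress test).
AIC = -2 l + 2(p+1), BIC = -2 l + (p+1) log N.  Evaluation metrics:
precision/recall/accuracy of significance calls against the generating
truth (precision is reported as missing, never 0, when no positive call
exists), per-coefficient rejection rates across replicates (power for
non-null, type-I error for null coefficients), Mann-Whitney ROC/AUC, and
Wilson score intervals for proportions.

## Synthetic stress test

The generator emulates a multi-site binary-outcome study: per site,
4 binary covariates ~ Bernoulli(0.5), 6 continuous covariates ~
Uniform(-1, 1.5), an intercept, a site effect mu_i ~ Normal(0, tau_true),
outcomes from the logistic model, and a 7:3 train/validation split of each
site's rows.  Eight standard settings cross {2, 10} sites x {500, 30}
patients/site x tau in {small = 0.25, large = 2.0}, 20 replicates each.
The default truth beta_true = [-1, 0.8, 0, -0.5, 0, 0.8, 0, -0.5, 0, 0.8, 0]
mixes six non-null and five null coefficients so precision/recall and
type-I error are all observable.  The numeric values of beta_true and of
the small/large variances are this package's choices of realistic effect
sizes on the stated covariate scales; only the covariate ranges, counts,
site/sample sizes and the split ratio are fixed by the design.  Degenerate
replicates (a separated site under n = 30) are **kept** — surviving them is
the adaptive ridge's job — and a study is redrawn only if it is entirely
single-class, with the redraw count recorded.

What the generator does *not* emulate: covariate correlation, missing
data, site-level covariate shift, non-logistic outcome processes, or more
than one random effect.  Passing tests therefore demonstrate correctness
of the estimator and its calibration under the generating model, not
robustness to real-data misspecification.

## Numerical choices and defaults

| Parameter | Default | Why |
| --- | --- | --- |
| `conv_tol` | 1e-3 | largest parameter change between rounds; matches how steps are counted in the convergence reporting |
| inner mode tolerance | 1e-8 on &#124;g_mu&#124; | safeguarded Newton, <= 100 iterations, step-halving with a 1e-12 relative slack so rounding-level decreases do not destroy the final steps |
| quadrature order K | 2 (method "gh"), 1 ("la") | the comparison of interest is LA vs one extra degree |
| ridge schedule | 1e-6 x 10^t, cap 1e3 | smallest delta with PD Cholesky and condition <= 1e10 |
| Hessian FD step | 1e-5 x max(1, &#124;beta_r&#124;) | centered differences of the analytic score: truncation ~1e-10 relative, well inside the 1e-4 contract |
| tau parametrization | log scale internally | keeps tau > 0 without constraints; reported scores are on the tau scale |
| lambda grid | 0..10 by 1 | the standard sweep for this design |

Degenerate inputs: empty sites contribute l_i = 0 with zero scores (the
empty-site marginal likelihood is exactly 1, and the quadrature is exact
because g is then quadratic in mu); all-empty studies converge in one
round.  tau estimates can hit the boundary (tau -> 0) when between-site
variation is absent; the log-scale walk then slows, which is why the
convergence test includes log tau and the default tolerance is 1e-3.

## Known limitations

* One random intercept only; no random slopes or crossed effects.
* The tau update is first-order (protocol constraint), so fits with a
  strongly informative variance component take more rounds than a full
  Newton method would.
* Monte-Carlo checks of estimator bias on all 11 coefficients
  simultaneously at a +/-2 MC-SE band are noisy by construction (~43%
  chance of at least one exceedance for an exactly unbiased estimator at
  100 replicates); replicate batches at other seeds were used to confirm
  that observed marginal exceedances carry no systematic sign.
* The simulated network is a JSON round-trip; no transport, authentication,
  secure aggregation or differential privacy is provided or claimed.
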