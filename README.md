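# fedglmm

Federated fitting of logistic mixed-effects models on horizontally
partitioned data — for biostatisticians and health-informatics teams who
need one regression across several hospitals or registries whose
patient-level rows cannot leave their sites.

## The model and the method

Patients at site i follow a logistic regression with a site-specific
random intercept:

    y_ij | mu_i ~ Bernoulli(expit(X_ij' beta + mu_i)),   mu_i ~ N(0, tau).

The marginal log-likelihood integrates the mu_i out and decomposes into a
sum of per-site terms

    l(beta, tau) = sum_i log INT exp{ g_i(mu; beta, tau) } dmu,

each evaluated by adaptive Gauss–Hermite quadrature centred at the site's
inner mode (K = 1 is exactly the Laplace approximation).  Every fitting
round, each site transmits only aggregate statistics — its approximate
log-likelihood, score vector, Hessian and the mode — and the coordinator
takes a ridge-safeguarded Newton step.  Three numerical safeguards make
this work in practice:

* a **log-sum-exp shift** keeps the quadrature sum finite even when single
  exponents reach magnitude 1e4 (separated sites);
* an **adaptive ridge** (delta grown from 1e-6 until the negated Hessian is
  positive definite and well conditioned) survives collinear covariates
  and complete separation;
* an optional **L2 penalty** with a grid sweep over lambda in 0..10,
  selected on held-out validation sites.

Significance is judged by two-sided Wald tests; AIC/BIC, ROC/AUC and
Wilson intervals are available for model comparison and evaluation.
Because the decomposition is exact, the federated fit equals the pooled
(all data in one place) fit to machine precision — this is asserted in the
test suite, alongside independent cross-checks against a generic
quasi-Newton optimizer and lme4's `glmer`.

## Worked example

Simulate a 10-site study (500 patients per site, random-intercept variance
0.25), fit with second-order Gauss–Hermite quadrature, and read the Wald
table:

```
$ fedglmm simulate --setting 3 --seed 1 --out study/
wrote study/train.csv, valid.csv, manifest.json (seed=1)

$ fedglmm fit --data study/train.csv --method gh --gh-order 2 --out fit.json
config: method=gh gh_order=2 lambda=0 conv_tol=0.001 alpha=0.05 seed=0
converged=True rounds=55 loglik=-2012.9697 AIC=4049.94 BIC=4123.87 tau_hat=0.1063 lambda=0
  coef   estimate    std.err        z          p sig
    b0    -1.0017     0.1393   -7.192  6.400e-13 *
    b1     0.7188     0.0774    9.282  1.668e-20 *
    b2     0.1297     0.0769    1.687  9.156e-02
    b3    -0.5076     0.0771   -6.586  4.509e-11 *
    b4     0.0810     0.0767    1.056  2.912e-01
    b5     0.8567     0.0560   15.290  8.886e-53 *
    b6     0.0548     0.0527    1.041  2.981e-01
    b7    -0.4612     0.0538   -8.577  9.776e-18 *
    b8    -0.0211     0.0535   -0.394  6.936e-01
    b9     0.8062     0.0559   14.419  3.948e-47 *
   b10    -0.0561     0.0530   -1.059  2.897e-01
```

The generating truth for this design is beta = [-1, 0.8, 0, -0.5, 0, 0.8,
0, -0.5, 0, 0.8, 0] with tau = 0.25: every non-null coefficient is
recovered and flagged significant, and every null coefficient is correctly
not flagged.  The variance component is estimated low here (0.106 from one
draw of ten site intercepts — with m = 10 the sampling variability of
tau_hat is large), which is typical for this design.
`fedglmm evaluate --fit-json fit.json --manifest study/manifest.json`
scores the significance calls against the recorded truth
(`precision=1.0 recall=1.0 accuracy=1.000 (TP=6 FP=0 TN=5 FN=0)` for this
run), and
`fedglmm sweep` / `fedglmm reproduce-stress-test` run the penalty sweep
and the full settings-by-replicates experiment.

The same is available as a library:

```python
from fedglmm import FederationConfig, preset, generate_study, run_federated_fit, wald_tests

study = generate_study(preset(3, seed=1))
fit = run_federated_fit(study.train_sites, FederationConfig(method="gh", K=2))
print(fit.beta_hat, fit.tau_hat, wald_tests(fit).p_value)
```

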