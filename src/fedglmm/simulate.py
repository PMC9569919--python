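"""Synthetic multi-site study generator for the stress-test design.

Each study draws m sites; site i receives a random intercept
mu_i ~ Normal(0, tau_true) and n patients with 4 binary covariates
(Bernoulli(0.5)), 6 continuous covariates (Uniform on [-1, 1.5]) and an
all-ones intercept column, so p = 11 by default.  Outcomes are Bernoulli
with log-odds X beta_true + mu_i.  Rows are split 7:3 into train and
validation per site.  The eight standard settings cross
{2, 10} sites x {500, 30} patients/site x {small, large} random-intercept
variance; a batch runs 20 replicate studies per setting.

The generating coefficient vector mixes null and non-null entries so that
downstream significance calls have both positives and negatives to find:
beta_true = [-1, 0.8, 0, -0.5, 0, 0.8, 0, -0.5, 0, 0.8, 0].  The numeric
values of beta_true and of the small/large variances (0.25 / 2.0) are this
package's defaults, chosen to give realistic effect sizes on the stated
covariate ranges; only the covariate ranges, site counts, sample sizes and
the 7:3 split are fixed by the study design itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .exceptions import InputError
from .model_core import SiteData

__all__ = [
    "SimulationDesign",
    "SimulatedStudy",
    "TAU_SMALL",
    "TAU_LARGE",
    "DEFAULT_BETA",
    "generate_study",
    "generate_replicates",
    "preset",
]

TAU_SMALL = 0.25
TAU_LARGE = 2.0

DEFAULT_BETA = np.array([-1.0, 0.8, 0.0, -0.5, 0.0, 0.8, 0.0, -0.5, 0.0, 0.8, 0.0])

# setting id -> (number of sites, patients per site, random-intercept variance)
_PRESETS = {
    1: (2, 500, TAU_SMALL),
    2: (2, 500, TAU_LARGE),
    3: (10, 500, TAU_SMALL),
    4: (10, 500, TAU_LARGE),
    5: (2, 30, TAU_SMALL),
    6: (2, 30, TAU_LARGE),
    7: (10, 30, TAU_SMALL),
    8: (10, 30, TAU_LARGE),
}


@dataclass(frozen=True)
class SimulationDesign:
    """Full specification of one simulated multi-site study."""

    m: int = 10
    n_per_site: int = 500
    tau_true: float = TAU_SMALL
    beta_true: np.ndarray = field(default_factory=lambda: DEFAULT_BETA.copy())
    n_binary: int = 4
    n_continuous: int = 6
    replicates: int = 20
    split_ratio: float = 0.7
    seed: int = 0

    def __post_init__(self):
        beta = np.asarray(self.beta_true, dtype=float).ravel()
        object.__setattr__(self, "beta_true", beta)
        if self.m < 1 or self.n_per_site < 1:
            raise InputError("need at least one site and one patient per site")
        if self.tau_true <= 0:
            raise InputError(f"tau_true must be positive, got {self.tau_true}")
        if self.n_binary < 0 or self.n_continuous < 0:
            raise InputError("covariate counts must be non-negative")
        if beta.shape[0] != self.p:
            raise InputError(
                f"beta_true has length {beta.shape[0]}, expected p={self.p} "
                f"(intercept + {self.n_binary} binary + {self.n_continuous} continuous)"
            )
        if not 0 < self.split_ratio < 1:
            raise InputError("split_ratio must be in (0, 1)")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")

    @property
    def p(self) -> int:
        return 1 + self.n_binary + self.n_continuous


@dataclass(frozen=True)
class SimulatedStudy:
    """One generated replicate with its ground truth."""

    train_sites: list
    valid_sites: list
    full_sites: list
    truth: dict


def preset(setting_id: int, **overrides) -> SimulationDesign:
    """The standard stress-test setting 1..8.

    Settings cross sites {2, 10}, per-site size {500, 30} and variance
    {small=0.25, large=2.0}; keyword overrides adjust any other field.
    """
    if setting_id not in _PRESETS:
        raise InputError(f"setting_id must be 1..8, got {setting_id!r}")
    m, n, tau = _PRESETS[setting_id]
    return replace(SimulationDesign(m=m, n_per_site=n, tau_true=tau), **overrides)


def _draw_sites(design: SimulationDesign, rng: np.random.Generator):
    mu = rng.normal(0.0, np.sqrt(design.tau_true), size=design.m)
    sites, logodds = [], []
    for i in range(design.m):
        n = design.n_per_site
        Xb = rng.integers(0, 2, size=(n, design.n_binary)).astype(float)
        Xc = rng.uniform(-1.0, 1.5, size=(n, design.n_continuous))
        X = np.column_stack([np.ones(n), Xb, Xc])
        eta = X @ design.beta_true + mu[i]
        y = (rng.random(n) < expit(eta)).astype(float)
        sites.append(SiteData(site_id=f"site{i + 1}", X=X, y=y))
        logodds.append(eta)
    return sites, mu, logodds


def _split_site(site: SiteData, ratio: float, rng: np.random.Generator):
    n_train = int(round(ratio * site.n_i))
    n_train = min(max(n_train, 1), site.n_i - 1) if site.n_i > 1 else site.n_i
    perm = rng.permutation(site.n_i)
    tr, va = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    train = SiteData(site_id=site.site_id, X=site.X[tr], y=site.y[tr])
    valid = SiteData(site_id=site.site_id, X=site.X[va], y=site.y[va])
    return train, valid, tr, va


def generate_study(design: SimulationDesign, seed=None) -> SimulatedStudy:
    """Generate one replicate study, fully reproducible from the seed.

    Redraws (counting the attempts) only if the whole study is single-class,
    in which case the model is unidentifiable; individual separated sites
    are kept — surviving them is what the adaptive ridge is for.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    for attempt in range(100):
        sites, mu, logodds = _draw_sites(design, rng)
        rate = float(np.mean(np.concatenate([s.y for s in sites])))
        if 0.0 < rate < 1.0:
            break
    else:
        raise InputError(
            "could not draw a study with both outcome classes in 100 attempts"
        )

    train_sites, valid_sites, splits = [], [], []
    for site in sites:
        train, valid, tr, va = _split_site(site, design.split_ratio, rng)
        train_sites.append(train)
        valid_sites.append(valid)
        splits.append({"train_rows": tr.tolist(), "valid_rows": va.tolist()})

    truth = {
        "beta_true": design.beta_true.copy(),
        "tau_true": design.tau_true,
        "mu_true": mu,
        "log_odds": logodds,
        "nonnull": design.beta_true != 0.0,
        "outcome_rate": rate,
        "redraws": attempt,
        "splits": splits,
    }
    return SimulatedStudy(
        train_sites=train_sites, valid_sites=valid_sites, full_sites=sites, truth=truth
    )


def generate_replicates(design: SimulationDesign):
    """Yield ``design.replicates`` independent studies from the design seed.

    Child seeds are spawned from a single SeedSequence, so replicate r is
    reproducible on its own and the batch is reproducible as a whole.
    """
    children = np.random.SeedSequence(design.seed).spawn(design.replicates)
    for child in children:
        yield generate_study(design, seed=child)
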